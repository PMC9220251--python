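"""Competitive-inhibition analysis: apparent Km and KI estimation.

A purely competitive modulator raises the apparent Michaelis constant
without touching kcat:

    appKm(I) = Km0 * (1 + I / KI)

KI here is the inhibitor *dissociation* constant (molar): smaller KI means
tighter binding. Note the two-state allosteric module expresses site
affinities as *association* constants (M^-1); conversions between the two
conventions are always explicit (KI = 1/Ka).

KI is estimated from the slope of the (I, appKm) line, the classical
secondary-plot route: Km(I) = Km0 + (Km0/KI)*I, so KI = intercept/slope.
A nonlinear variant with multiplicative (log-scale) error is available for
strongly heteroscedastic Km series.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy.optimize import least_squares

__all__ = [
    "CompetitiveFit",
    "NoInhibitionError",
    "apparent_km",
    "estimate_ki",
    "fit_competitive_global",
    "fold_affinity_ratio",
]


class NoInhibitionError(ValueError):
    """Km does not increase with modulator concentration: no competitive inhibition."""


def _check_slope(slope: float, slope_se: float, min_slope_t: float) -> None:
    if slope <= 0:
        raise NoInhibitionError("non-positive Km-vs-I slope: no competitive inhibition detected")
    # a perfect (zero-residual) fit has SE 0: treat as infinitely significant
    if slope_se > 0 and slope / slope_se < min_slope_t:
        raise NoInhibitionError(
            f"Km-vs-I slope not significant (t = {slope / slope_se:.2f}): no competitive inhibition detected"
        )


@dataclass(frozen=True)
class CompetitiveFit:
    """Result of a competitive-inhibition (KI) estimation."""

    ki: float  # molar, dissociation constant
    km0: float  # molar, Km at I = 0
    ki_stderr: float
    km0_stderr: float
    slope: float  # d(appKm)/dI = Km0/KI, dimensionless (M per M)
    residual_norm: float
    n_points: int

    def __post_init__(self) -> None:
        if not (self.ki > 0 and self.km0 > 0):
            raise ValueError("KI and Km0 must be positive")

    @property
    def association_constant(self) -> float:
        """The equivalent association constant 1/KI in M^-1."""
        return 1.0 / self.ki


def apparent_km(km0: float, ki: float, modulator_conc) -> np.ndarray | float:
    """appKm = Km0*(1 + I/KI); nondecreasing in I. Vectorized over I."""
    if not (km0 > 0 and ki > 0):
        raise ValueError("Km0 and KI must be positive")
    i = np.asarray(modulator_conc, dtype=float)
    if np.any(i < 0):
        raise ValueError("modulator_conc must be >= 0")
    out = km0 * (1.0 + i / ki)
    return float(out) if out.ndim == 0 else out


def estimate_ki(
    modulator_conc,
    km_app,
    fixed_km0: float | None = None,
    method: str = "linear",
    min_slope_t: float = 2.0,
) -> CompetitiveFit:
    """Estimate KI from an apparent-Km series.

    Parameters
    ----------
    modulator_conc, km_app : arrays (molar)
    fixed_km0 : if given, Km0 is not estimated and KI = fixed_km0 / slope
    method : "linear" (default; OLS on the secondary plot) or "nonlinear"
        (fit of appKm = Km0*(1+I/KI) with log-scale residuals)
    min_slope_t : the Km-vs-I slope must be positive and exceed this many
        regression standard errors, otherwise the series is declared
        non-inhibitory (guards against noise on a flat series)

    The standard error of KI = Km0/slope is propagated from the regression
    covariance by the delta method.
    """
    i = np.asarray(modulator_conc, dtype=float)
    k = np.asarray(km_app, dtype=float)
    if i.shape != k.shape or i.ndim != 1:
        raise ValueError("modulator_conc and km_app must be 1-D arrays of equal length")
    min_pts = 2 if fixed_km0 is not None else 3
    if np.unique(i).size < min_pts:
        raise ValueError(f"need >= {min_pts} distinct modulator concentrations")
    if np.any(k <= 0):
        raise ValueError("apparent Km values must be positive")

    if method == "nonlinear":
        return _estimate_ki_nonlinear(i, k, fixed_km0)
    if method != "linear":
        raise ValueError(f"unknown method: {method!r}")

    if fixed_km0 is not None:
        # regression through the fixed intercept
        x = i[:, None]
        res = sm.OLS(k - fixed_km0, x).fit()
        slope = float(res.params[0])
        slope_se = float(res.bse[0])
        km0, km0_se = float(fixed_km0), 0.0
        _check_slope(slope, slope_se, min_slope_t)
        ki = km0 / slope
        ki_se = ki * slope_se / slope
    else:
        x = sm.add_constant(i)
        res = sm.OLS(k, x).fit()
        km0, slope = float(res.params[0]), float(res.params[1])
        _check_slope(slope, float(res.bse[1]), min_slope_t)
        if km0 <= 0:
            raise ValueError("regression intercept (Km0) is non-positive")
        cov = np.asarray(res.cov_params())
        km0_se = math.sqrt(cov[0, 0])
        ki = km0 / slope
        # delta method for KI = b0/b1 including the covariance term
        g = np.array([1.0 / slope, -km0 / slope**2])
        ki_var = float(g @ cov @ g)
        ki_se = math.sqrt(max(ki_var, 0.0))
    resid = k - (km0 + slope * i)
    return CompetitiveFit(
        ki=ki,
        km0=km0,
        ki_stderr=ki_se,
        km0_stderr=km0_se,
        slope=slope,
        residual_norm=float(np.linalg.norm(resid)),
        n_points=int(i.size),
    )


def _estimate_ki_nonlinear(i: np.ndarray, k: np.ndarray, fixed_km0: float | None) -> CompetitiveFit:
    lin = None
    try:
        lin = estimate_ki(i, k, fixed_km0=fixed_km0, method="linear")
        km0_0, ki_0 = lin.km0, lin.ki
    except (NoInhibitionError, ValueError):
        km0_0 = fixed_km0 if fixed_km0 is not None else float(k[np.argmin(i)])
        ki_0 = max(float(i[i > 0].min()) if np.any(i > 0) else 1e-6, 1e-12)

    if fixed_km0 is not None:

        def resid(p):
            return np.log(apparent_km(fixed_km0, 10.0 ** p[0], i)) - np.log(k)

        sol = least_squares(resid, x0=[math.log10(ki_0)])
        ki = 10.0 ** float(sol.x[0])
        km0 = float(fixed_km0)
    else:

        def resid(p):
            return np.log(apparent_km(10.0 ** p[0], 10.0 ** p[1], i)) - np.log(k)

        sol = least_squares(resid, x0=[math.log10(km0_0), math.log10(ki_0)])
        km0, ki = 10.0 ** float(sol.x[0]), 10.0 ** float(sol.x[1])
    slope = km0 / ki
    # flat or decreasing series converge to an absurdly large KI
    if np.ptp(k) == 0 or slope * float(i.max() - i.min()) < 1e-6 * km0:
        raise NoInhibitionError("apparent Km does not increase with I: no competitive inhibition detected")
    return CompetitiveFit(
        ki=ki,
        km0=km0,
        ki_stderr=float("nan"),
        km0_stderr=float("nan") if fixed_km0 is None else 0.0,
        slope=slope,
        residual_norm=float(np.linalg.norm(k - apparent_km(km0, ki, i))),
        n_points=int(i.size),
    )


def fit_competitive_global(
    velocity,
    substrate_conc,
    modulator_conc,
    enzyme_conc,
    min_aicc_gain: float = 2.0,
) -> CompetitiveFit:
    """Estimate KI by a global fit of the competitive rate law to raw rates.

    Fits v = kcat*E0*S / (Km0*(1 + I/KI) + S) with log-scale residuals over
    all wells simultaneously. This avoids the instability of per-modulator
    Km estimates when the apparent Km grows far beyond the largest assayed
    substrate concentration, where the Michaelis hyperbola degenerates to a
    straight line and Km becomes unidentifiable point-by-point.

    Raises NoInhibitionError when the competitive term does not improve the
    corrected information criterion over the plain Michaelis–Menten model
    by at least ``min_aicc_gain``.
    """
    v = np.asarray(velocity, dtype=float)
    s = np.asarray(substrate_conc, dtype=float)
    i = np.asarray(modulator_conc, dtype=float)
    e0 = np.asarray(enzyme_conc, dtype=float)
    if not (v.shape == s.shape == i.shape == e0.shape) or v.ndim != 1:
        raise ValueError("all inputs must be 1-D arrays of equal length")
    ok = (v > 0) & (s > 0)
    if ok.sum() < 4:
        raise ValueError("need at least 4 wells with positive velocity and substrate")
    v, s, i, e0 = v[ok], s[ok], i[ok], e0[ok]
    n = v.size
    log_v = np.log(v)

    kcat0 = 2.0 * float(np.max(v / e0))
    km00 = float(np.median(s))

    def resid_null(x):
        kcat, km0 = 10.0 ** x
        return np.log(kcat * e0 * s / (km0 + s)) - log_v

    def resid_comp(x):
        kcat, km0, ki = 10.0 ** x
        return np.log(kcat * e0 * s / (km0 * (1.0 + i / ki) + s)) - log_v

    ki0 = float(np.median(i[i > 0])) if np.any(i > 0) else 1e-6
    sol0 = least_squares(resid_null, [math.log10(kcat0), math.log10(km00)])
    sol1 = least_squares(resid_comp, [math.log10(kcat0), math.log10(km00), math.log10(ki0)])

    def aicc(rss, k):
        k = k + 1
        val = n * math.log(max(rss, 1e-300) / n) + 2 * k
        return val + 2 * k * (k + 1) / (n - k - 1)

    gain = aicc(2 * sol0.cost, 2) - aicc(2 * sol1.cost, 3)
    if gain < min_aicc_gain:
        raise NoInhibitionError(
            f"competitive term does not improve the fit (criterion gain {gain:.2f}): "
            "no competitive inhibition detected"
        )
    kcat, km0, ki = (10.0 ** float(x) for x in sol1.x)
    rss = float(2 * sol1.cost)
    se = [float("nan")] * 3
    dof = n - 3
    if dof > 0:
        try:
            cov = np.linalg.inv(sol1.jac.T @ sol1.jac) * (rss / dof)
            se_log10 = np.sqrt(np.clip(np.diag(cov), 0, None))
            se = [math.log(10.0) * val * float(sl) for val, sl in zip((kcat, km0, ki), se_log10)]
        except np.linalg.LinAlgError:
            pass
    return CompetitiveFit(
        ki=ki,
        km0=km0,
        ki_stderr=se[2],
        km0_stderr=se[1],
        slope=km0 / ki,
        residual_norm=math.sqrt(rss),
        n_points=int(n),
    )


def fold_affinity_ratio(ki_a: float, ki_b: float) -> tuple[float, int]:
    """Ratio of two dissociation constants and its nearest-integer fold.

    ``fold_affinity_ratio(ki_weak, ki_tight)`` > 1 means the second compound
    binds tighter (smaller KI) by that factor.
    """
    if not (ki_a > 0 and ki_b > 0):
        raise ValueError("both KI values must be positive")
    ratio = ki_a / ki_b
    return ratio, int(round(ratio))
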