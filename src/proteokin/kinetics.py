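"""Michaelis–Menten core: forward model, initial-rate extraction, Km/kcat fitting.

The fluorogenic assay this package analyzes reads AMC fluorescence released
by proteolytic cleavage of Suc-LLVY-AMC. Under initial-rate conditions the
observed velocity follows

    v = kcat * E0 * S / (Km + S)

with E0 the enzyme (20S core particle) concentration, S the substrate
concentration, Km the Michaelis constant and kcat the turnover number.
Rates may be estimated either by a direct nonlinear fit of this hyperbola or
by ordinary least squares on the double-reciprocal (Lineweaver–Burk) form

    E0 / v = (Km / kcat) * (1 / S) + 1 / kcat

which is retained as a diagnostic; the direct fit is the default for noisy
data. On noiseless data the two are algebraically equivalent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import statsmodels.api as sm
from lmfit import Model

__all__ = [
    "ProgressCurve",
    "RateObservation",
    "ExtractedRate",
    "MMParameters",
    "mm_velocity",
    "extract_initial_rate",
    "fit_mm",
    "KineticsError",
]


class KineticsError(ValueError):
    """Raised on invalid kinetic inputs (bad design, degenerate data)."""


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise KineticsError(msg)


@dataclass(frozen=True)
class ProgressCurve:
    """A single well's fluorescence (or product) time trace.

    Parameters
    ----------
    times : array, seconds, strictly increasing
    signal : array, fluorescence (arbitrary units) or molar product,
        same length as ``times``; interpretation declared by ``signal_unit``
    substrate_conc, modulator_conc, enzyme_conc : molar
    replicate_id : label
    calibration : signal units per molar AMC (converts slopes to molar/s);
        defaults to 1.0, i.e. rates are reported on the signal scale
    """

    times: np.ndarray
    signal: np.ndarray
    substrate_conc: float
    modulator_conc: float
    enzyme_conc: float
    replicate_id: str = "r1"
    calibration: float = 1.0
    signal_unit: Literal["fluorescence", "molar"] = "fluorescence"

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        y = np.asarray(self.signal, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "signal", y)
        _require(t.ndim == 1 and y.shape == t.shape, "times and signal must be 1-D and equal length")
        _require(np.all(np.diff(t) > 0), "times must be strictly increasing")
        _require(
            self.substrate_conc >= 0 and self.modulator_conc >= 0 and self.enzyme_conc >= 0,
            "concentrations must be nonnegative",
        )
        _require(self.calibration > 0, "calibration must be positive")


@dataclass(frozen=True)
class RateObservation:
    """One measured initial velocity with its assay context.

    velocity is in molar/second (or signal-units/second when the source
    trace was uncalibrated fluorescence).
    """

    velocity: float
    substrate_conc: float
    modulator_conc: float
    enzyme_conc: float
    replicate_id: str = "r1"

    def __post_init__(self) -> None:
        _require(math.isfinite(self.velocity) and self.velocity >= 0, "velocity must be finite and >= 0")
        _require(self.substrate_conc >= 0, "substrate_conc must be >= 0")
        _require(self.modulator_conc >= 0, "modulator_conc must be >= 0")
        _require(self.enzyme_conc > 0, "enzyme_conc must be > 0")


@dataclass(frozen=True)
class ExtractedRate(RateObservation):
    """RateObservation plus linear-fit diagnostics from the source trace."""

    r_squared: float = float("nan")
    window: tuple[float, float] = (float("nan"), float("nan"))
    n_points: int = 0
    slope_signal_per_s: float = float("nan")


@dataclass(frozen=True)
class MMParameters:
    """Fitted Michaelis–Menten parameters with uncertainties."""

    kcat: float  # per second
    km: float  # molar
    kcat_stderr: float = float("nan")
    km_stderr: float = float("nan")
    r_squared: float = float("nan")

    def __post_init__(self) -> None:
        _require(self.kcat > 0 and math.isfinite(self.kcat), "kcat must be positive and finite")
        _require(self.km > 0 and math.isfinite(self.km), "Km must be positive and finite")

    @property
    def efficiency(self) -> float:
        """Catalytic efficiency kcat/Km in M^-1 s^-1."""
        return self.kcat / self.km


def mm_velocity(params: MMParameters, substrate_conc, enzyme_conc) -> np.ndarray | float:
    """Michaelis–Menten velocity v = kcat*E0*S/(Km+S), vectorized over S."""
    s = np.asarray(substrate_conc, dtype=float)
    e0 = np.asarray(enzyme_conc, dtype=float)
    if not (np.all(np.isfinite(s)) and np.all(s >= 0)):
        raise KineticsError("substrate_conc must be finite and >= 0")
    if not (np.all(np.isfinite(e0)) and np.all(e0 > 0)):
        raise KineticsError("enzyme_conc must be finite and > 0")
    v = params.kcat * e0 * s / (params.km + s)
    return float(v) if v.ndim == 0 else v


def _linear_fit(t: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """OLS slope, intercept, R^2; R^2 is nan for zero-variance signal."""
    x = sm.add_constant(t)
    res = sm.OLS(y, x).fit()
    r2 = float(res.rsquared) if np.var(y) > 0 else float("nan")
    return float(res.params[1]), float(res.params[0]), r2


def extract_initial_rate(
    curve: ProgressCurve,
    window_policy: Literal["full", "adaptive"] = "full",
    r2_threshold: float = 0.995,
    min_points: int = 5,
) -> ExtractedRate:
    """Estimate the initial velocity from a progress curve.

    ``window_policy="full"`` regresses over the whole trace (appropriate
    when linearity holds over the read, as in a 45-min read of a slow
    assay); ``"adaptive"`` keeps the longest prefix whose linear fit has
    R^2 >= ``r2_threshold`` (at least ``min_points`` points), for traces
    that curve late. The slope is converted to molar/s through the curve's
    calibration constant.
    """
    t, y = curve.times, curve.signal
    _require(t.size >= min_points, f"need at least {min_points} time points")

    if np.var(y) == 0:
        return ExtractedRate(
            velocity=0.0,
            substrate_conc=curve.substrate_conc,
            modulator_conc=curve.modulator_conc,
            enzyme_conc=curve.enzyme_conc,
            replicate_id=curve.replicate_id,
            r_squared=float("nan"),
            window=(float(t[0]), float(t[-1])),
            n_points=int(t.size),
            slope_signal_per_s=0.0,
        )

    if window_policy == "full":
        end = t.size
    elif window_policy == "adaptive":
        end = t.size
        while end > min_points:
            _, _, r2 = _linear_fit(t[:end], y[:end])
            if np.isnan(r2) or r2 >= r2_threshold:
                break
            end -= 1
    else:
        raise KineticsError(f"unknown window policy: {window_policy!r}")

    slope, _, r2 = _linear_fit(t[:end], y[:end])
    velocity = slope / curve.calibration if curve.signal_unit == "fluorescence" else slope
    return ExtractedRate(
        velocity=max(velocity, 0.0),
        substrate_conc=curve.substrate_conc,
        modulator_conc=curve.modulator_conc,
        enzyme_conc=curve.enzyme_conc,
        replicate_id=curve.replicate_id,
        r_squared=r2,
        window=(float(t[0]), float(t[end - 1])),
        n_points=int(end),
        slope_signal_per_s=slope,
    )


def _fit_double_reciprocal(s: np.ndarray, v: np.ndarray, e0: float) -> tuple[float, float]:
    """Lineweaver–Burk OLS on (1/S, E0/v) -> (kcat, Km). Drops S=0 or v=0 rows."""
    ok = (s > 0) & (v > 0)
    _require(np.unique(s[ok]).size >= 3, "need >= 3 distinct positive substrate concentrations")
    x = 1.0 / s[ok]
    y = e0 / v[ok]
    slope, intercept, _ = _linear_fit(x, y)
    _require(intercept > 0 and slope > 0, "double-reciprocal fit gave non-positive Km or kcat")
    kcat = 1.0 / intercept
    km = slope * kcat
    return kcat, km


def fit_mm(
    observations: Sequence[RateObservation],
    method: Literal["direct", "double_reciprocal"] = "direct",
) -> MMParameters:
    """Fit kcat and Km to initial rates collected at one modulator concentration.

    The direct method (default) fits the hyperbola by nonlinear least
    squares, initialized from the double-reciprocal estimate; the
    ``double_reciprocal`` method returns the Lineweaver–Burk OLS estimate
    itself (diagnostic, unweighted).
    """
    obs = list(observations)
    _require(len(obs) >= 3, "need at least 3 observations")
    e0s = {o.enzyme_conc for o in obs}
    _require(len(e0s) == 1, "all observations must share one enzyme concentration")
    mods = {o.modulator_conc for o in obs}
    _require(len(mods) == 1, "all observations must come from a single modulator concentration")
    e0 = e0s.pop()
    s = np.array([o.substrate_conc for o in obs], dtype=float)
    v = np.array([o.velocity for o in obs], dtype=float)
    _require(np.unique(s).size >= 3, "need >= 3 distinct substrate concentrations")
    _require(np.any(v > 0), "all velocities are zero")

    try:
        kcat0, km0 = _fit_double_reciprocal(s, v, e0)
        lb_failed = False
    except KineticsError:
        # near-linear regime (Km >> S_max) can push the reciprocal intercept
        # through zero; seed the direct fit heuristically instead
        kcat0 = 2.0 * float(np.max(v)) / e0
        km0 = float(np.median(s[s > 0]))
        lb_failed = True
    if method == "double_reciprocal":
        if lb_failed:
            raise KineticsError("double-reciprocal fit gave non-positive Km or kcat")
        pred = kcat0 * e0 * s / (km0 + s)
        ss_res = float(np.sum((v - pred) ** 2))
        ss_tot = float(np.sum((v - v.mean()) ** 2))
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
        return MMParameters(kcat=kcat0, km=km0, r_squared=r2)
    if method != "direct":
        raise KineticsError(f"unknown method: {method!r}")

    def hyperbola(S, kcat, km):
        return kcat * e0 * S / (km + S)

    model = Model(hyperbola, independent_vars=["S"])
    pars = model.make_params(kcat=dict(value=kcat0, min=0), km=dict(value=km0, min=0))
    out = model.fit(v, pars, S=s)
    kcat = float(out.params["kcat"].value)
    km = float(out.params["km"].value)
    se_kcat = out.params["kcat"].stderr
    se_km = out.params["km"].stderr
    ss_tot = float(np.sum((v - v.mean()) ** 2))
    r2 = 1.0 - float(out.chisqr) / ss_tot if ss_tot > 0 else float("nan")
    return MMParameters(
        kcat=kcat,
        km=km,
        kcat_stderr=float(se_kcat) if se_kcat is not None else float("nan"),
        km_stderr=float(se_km) if se_km is not None else float("nan"),
        r_squared=r2,
    )
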