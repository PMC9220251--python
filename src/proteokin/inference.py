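"""Fitting and model selection for the two-state allosteric framework.

Dose–response series (obs_kcat, obs_Km, optionally efficiency) are fitted
by nonlinear least squares on *relative* (log-scale) residuals, because the
three observables span different units and decades. All positive
parameters are optimized in log10 space with box bounds, and the
multimodal surface is handled by seeded multi-start. The number of
concerted sites n and competitive sites m is selected as the smallest
(n, m), in lexicographic order, whose small-sample corrected information
criterion is within a margin of the best candidate — the "minimal model
that accounts for the data" rule. Mechanism classification compares nested
models (no modulation, competitive-only, two-state, two-state plus
competitive site) and applies shape rules for the biphasic phenotype.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .inhibition import CompetitiveFit, NoInhibitionError, apparent_km, estimate_ki
from .twostate import DoseResponse, TwoStateParameters, efficiency_obs, kcat_obs, km_obs

__all__ = [
    "FitResult",
    "SelectionResult",
    "MechanismLabel",
    "SHARED_PARAMETERS",
    "fit_two_state",
    "select_site_numbers",
    "classify_mechanism",
    "UnderdeterminedError",
]

#: Parameter names in canonical order.
_PARAM_NAMES = (
    "kcat_a",
    "kcat_b",
    "km_a",
    "km_b",
    "l_u",
    "l_l",
    "k_au",
    "k_al",
    "k_bu",
    "k_bl",
    "k_ai",
    "k_bi",
)

#: The substrate-linked, modulator-independent parameters that the
#: shared-parameter fitting protocol holds fixed across compounds.
SHARED_PARAMETERS = ("kcat_a", "kcat_b", "km_a", "km_b", "l_u", "l_l")

#: Mechanism taxonomy.
MechanismLabel = str
NONE = "NONE"
COMPETITIVE = "COMPETITIVE"
ALLOSTERIC_ACTIVATOR = "ALLOSTERIC_ACTIVATOR"
ALLOSTERIC_INHIBITOR = "ALLOSTERIC_INHIBITOR"
BIPHASIC = "BIPHASIC_ACTIVATOR_COMPETITIVE"

#: numeric floor on the residual sum of squares, representing convergence
#: noise of the optimizer on log-scale residuals (per-point level 1e-8).
_RSS_FLOOR_PER_POINT = 1e-16


class UnderdeterminedError(ValueError):
    """More free parameters than the data can constrain."""


@dataclass(frozen=True)
class FitResult:
    """Result of one two-state fit."""

    params: TwoStateParameters
    stderr: dict
    fixed: tuple
    free: tuple
    rss: float
    aicc: float
    n_obs: int
    success: bool
    message: str

    def __post_init__(self) -> None:
        if self.rss < 0:
            raise ValueError("RSS must be nonnegative")


@dataclass(frozen=True)
class SelectionResult:
    """Outcome of site-number selection / mechanism classification."""

    n_sites: int
    m_sites: int
    table: pd.DataFrame
    label: MechanismLabel
    best_fit: FitResult | None = None
    warnings: tuple = ()


def _aicc(rss: float, n_obs: int, n_free: int) -> float:
    rss = max(rss, n_obs * _RSS_FLOOR_PER_POINT)
    k = n_free + 1  # + residual variance
    aic = n_obs * math.log(rss / n_obs) + 2 * k
    denom = n_obs - k - 1
    return aic + (2 * k * (k + 1) / denom if denom > 0 else math.inf)


def _series(data: DoseResponse, include_efficiency: bool) -> list[tuple[str, np.ndarray]]:
    out = [("kcat", data.kcat), ("km", data.km)]
    if include_efficiency:
        out.append(("efficiency", data.efficiency))
    for name, arr in out:
        if np.any(arr <= 0) or not np.all(np.isfinite(arr)):
            raise ValueError(f"{name} series must be positive and finite for log-scale fitting")
    return out


def _predict(p: TwoStateParameters, grid: np.ndarray, include_efficiency: bool) -> list[np.ndarray]:
    preds = [np.asarray(kcat_obs(p, grid)), np.asarray(km_obs(p, grid))]
    if include_efficiency:
        preds.append(np.asarray(efficiency_obs(p, grid)))
    return preds


def fit_two_state(
    data: DoseResponse,
    init: TwoStateParameters,
    n_sites: int | None = None,
    m_sites: int | None = None,
    fixed: Sequence[str] = SHARED_PARAMETERS,
    detailed_balance: bool = True,
    include_efficiency: bool = False,
    n_starts: int = 16,
    seed: int = 0,
    bounds_decades: float = 3.0,
) -> FitResult:
    """Fit the two-state model to a dose response.

    Parameters
    ----------
    data : DoseResponse with positive observed series
    init : initial/fixed parameter values; its site numbers are used unless
        ``n_sites``/``m_sites`` override them
    fixed : names of parameters held at their ``init`` values (default: the
        shared-parameter protocol, fixing the substrate-linked constants)
    detailed_balance : tie km_b = km_a * l_u / l_l (km_b is then never free)
    include_efficiency : also fit the efficiency series (default: kcat and
        Km only, leaving efficiency as a held-out check)
    n_starts : multi-start count; log-uniform draws within
        ``bounds_decades`` decades of ``init``, deterministic given ``seed``
    """
    n = init.n_sites if n_sites is None else int(n_sites)
    m = init.m_sites if m_sites is None else int(m_sites)
    base = replace(
        init,
        n_sites=n,
        m_sites=m,
        k_ai=init.k_ai if (m == 0 or init.k_ai > 0) else 1e6,
        k_bi=init.k_bi if (m == 0 or init.k_bi > 0) else 1e6,
    )
    if detailed_balance:
        base = base.with_detailed_balance()

    fixed = tuple(fixed)
    unknown = set(fixed) - set(_PARAM_NAMES)
    if unknown:
        raise ValueError(f"unknown fixed parameters: {sorted(unknown)}")
    free = [name for name in _PARAM_NAMES if name not in fixed]
    if detailed_balance and "km_b" in free:
        free.remove("km_b")
    if n == 0:
        free = [f for f in free if f not in ("k_au", "k_al", "k_bu", "k_bl")]
    if m == 0:
        free = [f for f in free if f not in ("k_ai", "k_bi")]
    if not free:
        raise ValueError("no free parameters")

    grid = data.modulator_grid
    series = _series(data, include_efficiency)
    n_obs = sum(arr.size for _, arr in series)
    if grid.size < len(free) + 2:
        raise UnderdeterminedError(
            f"{len(free)} free parameters need at least {len(free) + 2} grid points, got {grid.size}"
        )
    log_obs = np.concatenate([np.log(arr) for _, arr in series])

    x0 = np.array([math.log10(getattr(base, name)) for name in free])
    lo, hi = x0 - bounds_decades, x0 + bounds_decades

    def build(x: np.ndarray) -> TwoStateParameters:
        p = base
        for name, xv in zip(free, x):
            p = replace(p, **{name: 10.0**xv})
        if detailed_balance:
            p = p.with_detailed_balance()
        return p

    def resid(x: np.ndarray) -> np.ndarray:
        p = build(x)
        return np.concatenate([np.log(pr) for pr in _predict(p, grid, include_efficiency)]) - log_obs

    rng = np.random.default_rng(seed)
    starts = [x0] + [rng.uniform(lo, hi) for _ in range(max(n_starts - 1, 0))]
    best = None
    for s in starts:
        sol = least_squares(resid, s, bounds=(lo, hi), method="trf", xtol=1e-14, ftol=1e-14, gtol=1e-14)
        if best is None or sol.cost < best.cost:
            best = sol
    assert best is not None
    rss = float(2 * best.cost)
    p_hat = build(best.x)

    # delta-method standard errors from the log10-space Jacobian
    stderr: dict = {name: float("nan") for name in free}
    dof = n_obs - len(free)
    if dof > 0:
        jac = best.jac
        try:
            cov = np.linalg.inv(jac.T @ jac) * (rss / dof)
            se_log10 = np.sqrt(np.clip(np.diag(cov), 0, None))
            for name, se in zip(free, se_log10):
                stderr[name] = math.log(10.0) * getattr(p_hat, name) * float(se)
        except np.linalg.LinAlgError:
            pass

    return FitResult(
        params=p_hat,
        stderr=stderr,
        fixed=fixed,
        free=tuple(free),
        rss=rss,
        aicc=_aicc(rss, n_obs, len(free)),
        n_obs=n_obs,
        success=bool(best.success),
        message=str(best.message),
    )


def _is_flat(data: DoseResponse, tol: float) -> bool:
    rel = lambda a: float(np.ptp(a) / np.median(a))
    return rel(data.kcat) < tol and rel(data.km) < tol


def label_from_shape(data: DoseResponse, tol: float = 0.02) -> MechanismLabel:
    """Assign the mechanism taxonomy from the shape of the observed series.

    The biphasic label requires the efficiency to rise above its I=0 value
    and subsequently fall below it within the grid.
    """
    if _is_flat(data, tol):
        return NONE
    eff = data.efficiency
    eff0 = eff[0]
    peak = int(np.argmax(eff))
    rises = eff[peak] > eff0 * (1 + tol)
    falls_after = rises and np.any(eff[peak:] < eff0 * (1 - tol))
    kcat_flat = float(np.ptp(data.kcat) / np.median(data.kcat)) < tol
    km_up = bool(data.km[-1] > data.km[0] * (1 + tol))
    if rises and falls_after:
        return BIPHASIC
    if kcat_flat and km_up:
        return COMPETITIVE
    if eff[-1] > eff0 * (1 + tol):
        return ALLOSTERIC_ACTIVATOR
    if eff[-1] < eff0 * (1 - tol):
        return ALLOSTERIC_INHIBITOR
    return NONE


def select_site_numbers(
    data: DoseResponse,
    n_candidates: Iterable[int] = (1, 2, 3, 4),
    m_candidates: Iterable[int] = (0, 1, 2),
    base: TwoStateParameters | None = None,
    fixed: Sequence[str] = SHARED_PARAMETERS,
    margin: float = 2.0,
    criterion: str = "aicc",
    rss_tolerance: float = 0.05,
    **fit_kwargs,
) -> SelectionResult:
    """Select the minimal (n, m) that accounts for a dose response.

    Every candidate pair is fitted; the smallest pair (lexicographic in
    (n, m)) whose criterion is not worse than the best by more than
    ``margin`` (for ``criterion="aicc"``) or whose RSS is within
    ``rss_tolerance`` relative of the best (``criterion="rss"``) is
    selected — the minimal-model rule.
    """
    n_candidates = sorted(set(int(v) for v in n_candidates))
    m_candidates = sorted(set(int(v) for v in m_candidates))
    if not n_candidates or not m_candidates:
        raise ValueError("candidate sets must be nonempty")
    warnings: list[str] = []
    if base is None:
        base = _generic_init(data)
        fixed = ()

    rows = []
    fits: dict[tuple[int, int], FitResult] = {}
    for n in n_candidates:
        for m in m_candidates:
            try:
                fit = fit_two_state(data, base, n_sites=n, m_sites=m, fixed=fixed, **fit_kwargs)
            except (UnderdeterminedError, ValueError) as exc:
                warnings.append(f"(n={n}, m={m}) failed: {exc}")
                continue
            fits[(n, m)] = fit
            rows.append({"n": n, "m": m, "rss": fit.rss, "aicc": fit.aicc, "n_free": len(fit.free)})
    if not fits:
        raise RuntimeError("all candidate fits failed: " + "; ".join(warnings))
    table = pd.DataFrame(rows).sort_values(["n", "m"]).reset_index(drop=True)

    if criterion == "aicc":
        best_val = table["aicc"].min()
        ok = table[table["aicc"] <= best_val + margin]
    elif criterion == "rss":
        best_val = table["rss"].min()
        floor = len(data.modulator_grid) * 2 * _RSS_FLOOR_PER_POINT
        ok = table[table["rss"] <= max(best_val, floor) * (1 + rss_tolerance)]
    else:
        raise ValueError(f"unknown criterion: {criterion!r}")
    sel = ok.sort_values(["n", "m"]).iloc[0]
    n_sel, m_sel = int(sel["n"]), int(sel["m"])

    label = label_from_shape(data)
    if label == NONE:
        warnings.append("observables are flat over the grid: degenerate selection")
    return SelectionResult(
        n_sites=n_sel,
        m_sites=m_sel,
        table=table,
        label=label,
        best_fit=fits[(n_sel, m_sel)],
        warnings=tuple(warnings),
    )


def _generic_init(data: DoseResponse) -> TwoStateParameters:
    """Data-driven generic starting point when no base parameters are given."""
    kcat0 = float(data.kcat[0])
    km0 = float(data.km[0])
    return TwoStateParameters(
        kcat_a=kcat0,
        kcat_b=kcat0,
        km_a=km0,
        km_b=km0,
        l_u=0.1,
        l_l=0.1,
        k_au=1e6,
        k_al=1e6,
        k_bu=1e6,
        k_bl=1e6,
        k_ai=1e6,
        k_bi=1e6,
        n_sites=1,
        m_sites=0,
    )


def _fit_constant(data: DoseResponse) -> tuple[float, float, float]:
    """Null model: geometric-mean kcat and Km; returns (rss, kcat, km)."""
    lk, lm = np.log(data.kcat), np.log(data.km)
    rss = float(np.sum((lk - lk.mean()) ** 2) + np.sum((lm - lm.mean()) ** 2))
    return rss, float(np.exp(lk.mean())), float(np.exp(lm.mean()))


def _fit_competitive_model(data: DoseResponse) -> tuple[float, CompetitiveFit | None]:
    """Competitive-only model: constant kcat, appKm = Km0*(1+I/KI)."""
    lk = np.log(data.kcat)
    rss_kcat = float(np.sum((lk - lk.mean()) ** 2))
    try:
        cf = estimate_ki(data.modulator_grid, data.km, method="nonlinear")
    except (NoInhibitionError, ValueError):
        return math.inf, None
    pred = apparent_km(cf.km0, cf.ki, data.modulator_grid)
    rss_km = float(np.sum((np.log(pred) - np.log(data.km)) ** 2))
    return rss_kcat + rss_km, cf


def classify_mechanism(
    data: DoseResponse,
    base: TwoStateParameters | None = None,
    n_candidates: Iterable[int] = (1, 2, 3),
    margin: float = 2.0,
    shape_tol: float = 0.02,
    n_starts: int = 8,
    seed: int = 0,
) -> SelectionResult:
    """Classify the modulation mechanism of one compound.

    Fits the nested model ladder — no modulation, competitive-only,
    two-state (m=0), two-state plus competitive site (m=1) — compares them
    by the corrected information criterion, and labels the winner. The
    biphasic label additionally requires the observed efficiency to rise
    above its I=0 value and later fall below it within the grid.
    """
    n_obs = 2 * data.modulator_grid.size
    rows = []
    rss_null, _, _ = _fit_constant(data)
    rows.append({"model": "null", "n": 0, "m": 0, "rss": rss_null, "aicc": _aicc(rss_null, n_obs, 2)})
    rss_comp, comp_fit = _fit_competitive_model(data)
    if comp_fit is not None:
        rows.append({"model": "competitive", "n": 0, "m": 1, "rss": rss_comp, "aicc": _aicc(rss_comp, n_obs, 3)})

    fits: dict[str, FitResult] = {}
    init = base if base is not None else _generic_init(data)
    fixed = SHARED_PARAMETERS if base is not None else ()
    for m, name in ((0, "twostate"), (1, "twostate_competitive")):
        best: FitResult | None = None
        for n in n_candidates:
            try:
                fit = fit_two_state(
                    data, init, n_sites=n, m_sites=m, fixed=fixed, n_starts=n_starts, seed=seed
                )
            except (UnderdeterminedError, ValueError):
                continue
            if best is None or fit.aicc < best.aicc:
                best = fit
        if best is not None:
            fits[name] = best
            rows.append(
                {
                    "model": name,
                    "n": best.params.n_sites,
                    "m": m,
                    "rss": best.rss,
                    "aicc": best.aicc,
                }
            )
    table = pd.DataFrame(rows)
    best_aicc = table["aicc"].min()
    # prefer the simplest model within the margin, in ladder order
    within = table[table["aicc"] <= best_aicc + margin]
    winner = within.iloc[0]["model"]

    shape = label_from_shape(data, tol=shape_tol)
    if winner == "null" or shape == NONE:
        label = NONE
    elif winner == "competitive":
        label = COMPETITIVE
    else:
        label = shape if shape != COMPETITIVE else COMPETITIVE
    win_row = table[table["model"] == winner].iloc[0]
    return SelectionResult(
        n_sites=int(win_row["n"]),
        m_sites=int(win_row["m"]),
        table=table,
        label=label,
        best_fit=fits.get(winner),
        warnings=(),
    )
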