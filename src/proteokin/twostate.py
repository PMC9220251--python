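"""Two-state concerted (MWC-type) allosteric model of 20S modulation.

The enzyme equilibrates between two functional states A and B, with
allosteric constants L_U = [B]/[A] for the substrate-unbound enzyme and
L_L for the substrate-bound enzyme. A modulator (e.g. a cationic
porphyrinoid) binds n equivalent concerted allosteric sites, with
association constants K_AU, K_AL (state A, substrate-unbound/-bound) and
K_BU, K_BL (state B), and m competitive sites at the substrate gate with
association constants K_AI, K_BI. All binding constants are association
constants in M^-1; free modulator is identified with total modulator
because the enzyme (≈2 nM) is vastly sub-stoichiometric to the modulator
(≥0.1 µM).

Observed catalytic parameters as functions of modulator concentration I:

    obs_kcat(I) = [kcatA (1+K_AL I)^n + L_L kcatB (1+K_BL I)^n]
                  / [(1+K_AL I)^n + L_L (1+K_BL I)^n]

    obs_Km(I)   = KmA [(1+K_AI I)^m (1+K_AU I)^n + L_U (1+K_BI I)^m (1+K_BU I)^n]
                  / [(1+K_AL I)^n + L_L (1+K_BL I)^n]

Catalytic efficiency defaults to the ratio obs_kcat/obs_Km, which is the
internally consistent form. A historically printed closed form for the
efficiency (mode="literal") places the competitive factors in its numerator
and uses the substrate-unbound state weights in its denominator; it is NOT
algebraically equal to the ratio whenever m ≥ 1 or the U/L binding
constants differ, and is retained only so the discrepancy can be
quantified (``efficiency_consistency_check``).

In the competitive-only limit (all six binding constants equal to k,
L_U = L_L, m = 1) obs_Km reduces exactly to the classical competitive form
Km0*(1 + I/KI) with KI = 1/k.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Literal

import numpy as np
import pandas as pd

__all__ = [
    "TwoStateParameters",
    "InteractionRatios",
    "DoseResponse",
    "kcat_obs",
    "km_obs",
    "efficiency_obs",
    "interaction_ratios",
    "state_populations",
    "efficiency_consistency_check",
    "dose_response",
]


@dataclass(frozen=True)
class TwoStateParameters:
    """Full parameter set of the two-state concerted model.

    kcat_a, kcat_b : s^-1, turnover numbers of states A and B
    km_a, km_b : M, Michaelis constants of states A and B
    l_u, l_l : dimensionless allosteric constants [B]/[A], substrate-unbound
        and substrate-bound
    k_au, k_al, k_bu, k_bl : M^-1, association constants of the n concerted
        allosteric sites (state x ligation)
    k_ai, k_bi : M^-1, association constants of the m competitive sites
    n_sites : number of concerted allosteric sites (n)
    m_sites : number of competitive sites (m)
    """

    kcat_a: float
    kcat_b: float
    km_a: float
    km_b: float
    l_u: float
    l_l: float
    k_au: float
    k_al: float
    k_bu: float
    k_bl: float
    k_ai: float = 0.0
    k_bi: float = 0.0
    n_sites: int = 1
    m_sites: int = 0

    def __post_init__(self) -> None:
        for name in ("kcat_a", "kcat_b", "km_a", "km_b", "l_u", "l_l", "k_au", "k_al", "k_bu", "k_bl"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be positive and finite, got {v}")
        for name in ("k_ai", "k_bi"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v >= 0):
                raise ValueError(f"{name} must be nonnegative and finite, got {v}")
        if not (isinstance(self.n_sites, (int, np.integer)) and self.n_sites >= 0):
            raise ValueError("n_sites must be a nonnegative integer")
        if not (isinstance(self.m_sites, (int, np.integer)) and self.m_sites >= 0):
            raise ValueError("m_sites must be a nonnegative integer")
        if self.m_sites > 0 and self.k_ai <= 0 and self.k_bi <= 0:
            raise ValueError("m_sites > 0 requires a positive competitive association constant")

    def with_detailed_balance(self) -> "TwoStateParameters":
        """Return a copy with km_b tied to km_a * l_u / l_l.

        This is the thermodynamic linkage between the two allosteric
        constants and the two substrate affinities around the A/B cycle.
        """
        return replace(self, km_b=self.km_a * self.l_u / self.l_l)

    @property
    def detailed_balance_satisfied(self) -> bool:
        return math.isclose(self.km_b, self.km_a * self.l_u / self.l_l, rel_tol=1e-9)


@dataclass(frozen=True)
class InteractionRatios:
    """Thermodynamic linkage ratios of the allosteric binding constants.

    alpha = K_AU/K_AL, beta = K_BU/K_BL, gamma = K_BU/K_AU,
    delta = K_BL/K_AL. They satisfy alpha/beta = delta/gamma identically.
    """

    alpha: float
    beta: float
    gamma: float
    delta: float


@dataclass(frozen=True)
class DoseResponse:
    """Observed catalytic parameters on a modulator-concentration grid."""

    modulator_grid: np.ndarray  # molar, strictly increasing, >= 0
    kcat: np.ndarray  # s^-1
    km: np.ndarray  # molar
    efficiency: np.ndarray  # M^-1 s^-1
    kcat_stderr: np.ndarray | None = None
    km_stderr: np.ndarray | None = None

    def __post_init__(self) -> None:
        g = np.asarray(self.modulator_grid, dtype=float)
        object.__setattr__(self, "modulator_grid", g)
        for name in ("kcat", "km", "efficiency"):
            a = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, a)
            if a.shape != g.shape:
                raise ValueError(f"{name} must match the grid length")
        if g.ndim != 1 or np.any(g < 0) or np.any(np.diff(g) <= 0):
            raise ValueError("modulator_grid must be 1-D, nonnegative, strictly increasing")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "modulator_M": self.modulator_grid,
                "kcat_obs_per_s": self.kcat,
                "Km_obs_M": self.km,
                "efficiency_per_M_per_s": self.efficiency,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "DoseResponse":
        return cls(
            modulator_grid=df["modulator_M"].to_numpy(float),
            kcat=df["kcat_obs_per_s"].to_numpy(float),
            km=df["Km_obs_M"].to_numpy(float),
            efficiency=df["efficiency_per_M_per_s"].to_numpy(float),
        )


def _check_conc(i) -> np.ndarray:
    arr = np.asarray(i, dtype=float)
    if np.any(arr < 0) or not np.all(np.isfinite(arr)):
        raise ValueError("modulator concentration must be finite and >= 0")
    return arr


def _state_weights(p: TwoStateParameters, i: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Substrate-bound state weights wA = (1+K_AL I)^n, wB = L_L (1+K_BL I)^n."""
    return (1.0 + p.k_al * i) ** p.n_sites, p.l_l * (1.0 + p.k_bl * i) ** p.n_sites


def kcat_obs(params: TwoStateParameters, modulator_conc) -> np.ndarray | float:
    """Observed turnover number; a convex mix of kcat_a and kcat_b."""
    i = _check_conc(modulator_conc)
    wa, wb = _state_weights(params, i)
    out = (params.kcat_a * wa + params.kcat_b * wb) / (wa + wb)
    return float(out) if out.ndim == 0 else out


def km_obs(params: TwoStateParameters, modulator_conc) -> np.ndarray | float:
    """Observed Michaelis constant, including competitive-site inflation."""
    p = params
    i = _check_conc(modulator_conc)
    wa, wb = _state_weights(p, i)
    comp_a = (1.0 + p.k_ai * i) ** p.m_sites
    comp_b = (1.0 + p.k_bi * i) ** p.m_sites
    num = comp_a * (1.0 + p.k_au * i) ** p.n_sites + p.l_u * comp_b * (1.0 + p.k_bu * i) ** p.n_sites
    out = p.km_a * num / (wa + wb)
    return float(out) if out.ndim == 0 else out


def efficiency_obs(
    params: TwoStateParameters,
    modulator_conc,
    mode: Literal["ratio", "literal"] = "ratio",
) -> np.ndarray | float:
    """Observed catalytic efficiency kcat/Km in M^-1 s^-1.

    mode="ratio" (default) evaluates kcat_obs/km_obs. mode="literal"
    evaluates the printed closed form, which disagrees with the ratio
    whenever the competitive sites are active or the U/L binding constants
    differ; see module docstring.
    """
    p = params
    i = _check_conc(modulator_conc)
    if mode == "ratio":
        out = np.asarray(kcat_obs(p, i)) / np.asarray(km_obs(p, i))
    elif mode == "literal":
        comp_a = (1.0 + p.k_ai * i) ** p.m_sites
        comp_b = (1.0 + p.k_bi * i) ** p.m_sites
        ua = (1.0 + p.k_au * i) ** p.n_sites
        ub = (1.0 + p.k_bu * i) ** p.n_sites
        num = (p.kcat_a / p.km_a) * comp_a * ua + p.l_u * (p.kcat_b / p.km_b) * comp_b * ub
        out = num / (ua + p.l_u * ub)
    else:
        raise ValueError(f"unknown mode: {mode!r}")
    return float(out) if out.ndim == 0 else out


def interaction_ratios(params: TwoStateParameters) -> InteractionRatios:
    """alpha = K_AU/K_AL, beta = K_BU/K_BL, gamma = K_BU/K_AU, delta = K_BL/K_AL."""
    p = params
    return InteractionRatios(
        alpha=p.k_au / p.k_al,
        beta=p.k_bu / p.k_bl,
        gamma=p.k_bu / p.k_au,
        delta=p.k_bl / p.k_al,
    )


def state_populations(
    params: TwoStateParameters,
    modulator_conc,
    substrate_bound: bool,
) -> np.ndarray | float:
    """Fraction of enzyme in the B state at modulator concentration I.

    Substrate-bound: L_L (1+K_BL I)^n / [(1+K_AL I)^n + L_L (1+K_BL I)^n].
    Substrate-unbound: the same with L_U, K_BU, K_AU, and the competitive
    factors (1+K_xI I)^m included in each state's weight.
    """
    p = params
    i = _check_conc(modulator_conc)
    if substrate_bound:
        wa, wb = _state_weights(p, i)
    else:
        wa = (1.0 + p.k_ai * i) ** p.m_sites * (1.0 + p.k_au * i) ** p.n_sites
        wb = p.l_u * (1.0 + p.k_bi * i) ** p.m_sites * (1.0 + p.k_bu * i) ** p.n_sites
    out = wb / (wa + wb)
    return float(out) if out.ndim == 0 else out


def efficiency_consistency_check(params: TwoStateParameters, grid) -> float:
    """Maximum relative discrepancy between literal and ratio efficiency.

    Zero (to roundoff) in the degenerate limit m = 0, K_AL = K_AU,
    K_BL = K_BU with detailed balance; strictly positive when competitive
    sites are active, quantifying the internal inconsistency of the
    printed efficiency closed form.
    """
    g = _check_conc(grid)
    if g.size == 0:
        raise ValueError("grid must be nonempty")
    lit = np.asarray(efficiency_obs(params, g, mode="literal"))
    rat = np.asarray(efficiency_obs(params, g, mode="ratio"))
    return float(np.max(np.abs(lit - rat) / rat))


def dose_response(params: TwoStateParameters, grid) -> DoseResponse:
    """Noiseless forward evaluation of all three observables on a grid."""
    g = _check_conc(grid)
    return DoseResponse(
        modulator_grid=g,
        kcat=np.asarray(kcat_obs(params, g), dtype=float),
        km=np.asarray(km_obs(params, g), dtype=float),
        efficiency=np.asarray(efficiency_obs(params, g), dtype=float),
    )
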