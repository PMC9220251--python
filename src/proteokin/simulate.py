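"""Synthetic fluorogenic-assay generator.

Emulates the plate design of the 20S chymotrypsin-like assay: 2 nM enzyme,
Suc-LLVY-AMC at 5–100 µM, modulator at 0 and 0.1–10 µM (log-spaced),
three replicates per well, 45-minute linear reads. True velocities come
from the Michaelis–Menten law with mechanism-modified kcat/Km (none,
competitive, or two-state allosteric); replicates are perturbed by
multiplicative lognormal noise with a configurable coefficient of
variation, which keeps velocities positive and matches the
heteroscedasticity typical of plate fluorimetry.

Random streams are derived per well from a hash of (seed, S, I, replicate),
so subsetting a plate never changes the remaining wells.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from . import reference
from .inhibition import apparent_km
from .kinetics import MMParameters, mm_velocity
from .twostate import DoseResponse, TwoStateParameters, dose_response

__all__ = [
    "AssayDesign",
    "CompetitiveMechanism",
    "Mechanism",
    "simulate_dose_response",
    "simulate_assay",
    "simulate_progress_curves",
    "generate_fixture_suite",
    "default_modulator_grid",
]


def default_modulator_grid(n_points: int = 9, include_zero: bool = True) -> np.ndarray:
    """Log-spaced modulator grid 0.1–10 µM, optionally prefixed with 0."""
    grid = np.logspace(-7, -5, n_points)
    return np.concatenate([[0.0], grid]) if include_zero else grid


@dataclass(frozen=True)
class AssayDesign:
    """Plate layout and noise model of the synthetic assay."""

    substrate_grid_M: tuple = (5e-6, 1e-5, 2.5e-5, 5e-5, 1e-4)
    modulator_grid_M: tuple = tuple(default_modulator_grid())
    enzyme_conc_M: float = reference.ENZYME_CONC_M
    replicates: int = 3
    read_duration_s: float = 2700.0
    noise_cv: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        s = np.asarray(self.substrate_grid_M, dtype=float)
        m = np.asarray(self.modulator_grid_M, dtype=float)
        if np.any(s <= 0) or np.any(np.diff(s) <= 0):
            raise ValueError("substrate grid must be positive and strictly increasing")
        if np.any(m < 0) or np.any(np.diff(m) <= 0):
            raise ValueError("modulator grid must be nonnegative and strictly increasing")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if self.enzyme_conc_M <= 0:
            raise ValueError("enzyme_conc_M must be positive")


@dataclass(frozen=True)
class CompetitiveMechanism:
    """Competitive modulation: appKm = km0*(1 + I/ki), kcat unchanged."""

    kcat: float = reference.BASELINE_KCAT_PER_S
    km0: float = reference.BASELINE_KM_M
    ki: float = reference.KI_H2T4_M

    def __post_init__(self) -> None:
        if not (self.kcat > 0 and self.km0 > 0 and self.ki > 0):
            raise ValueError("kcat, km0 and ki must be positive")


#: A mechanism is None (no modulation), a CompetitiveMechanism, or a full
#: two-state parameter set.
Mechanism = Union[None, CompetitiveMechanism, TwoStateParameters]


def _effective_mm(mechanism: Mechanism, modulator_conc: float) -> MMParameters:
    """kcat/Km seen by the substrate at one modulator concentration."""
    from .twostate import kcat_obs, km_obs  # local import avoids cycle at module load

    if mechanism is None:
        return MMParameters(kcat=reference.BASELINE_KCAT_PER_S, km=reference.BASELINE_KM_M)
    if isinstance(mechanism, CompetitiveMechanism):
        return MMParameters(kcat=mechanism.kcat, km=apparent_km(mechanism.km0, mechanism.ki, modulator_conc))
    if isinstance(mechanism, TwoStateParameters):
        return MMParameters(kcat=float(kcat_obs(mechanism, modulator_conc)), km=float(km_obs(mechanism, modulator_conc)))
    raise TypeError(f"unsupported mechanism: {mechanism!r}")


def simulate_dose_response(params: TwoStateParameters, grid) -> DoseResponse:
    """Noiseless forward evaluation of the two-state observables on a grid."""
    return dose_response(params, grid)


def _well_rng(seed: int, s: float, i: float, rep: int) -> np.random.Generator:
    key = f"{seed}|{s:.12e}|{i:.12e}|{rep}".encode()
    digest = hashlib.blake2s(key, digest_size=8).digest()
    return np.random.default_rng(int.from_bytes(digest, "little"))


def _lognormal_factor(rng: np.random.Generator, cv: float) -> float:
    if cv == 0:
        return 1.0
    sigma = math.sqrt(math.log1p(cv * cv))
    return float(rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma))


def simulate_assay(design: AssayDesign, mechanism: Mechanism = None) -> pd.DataFrame:
    """Simulate one plate of initial-rate observations.

    Returns a long-format table with columns
    ``velocity_M_per_s, substrate_M, modulator_M, enzyme_M, replicate``
    (the rate-table CSV dialect), fully reproducible from ``design.seed``.
    """
    rows = []
    for i_conc in design.modulator_grid_M:
        mm = _effective_mm(mechanism, float(i_conc))
        for s_conc in design.substrate_grid_M:
            v_true = mm_velocity(mm, float(s_conc), design.enzyme_conc_M)
            for rep in range(1, design.replicates + 1):
                rng = _well_rng(design.seed, float(s_conc), float(i_conc), rep)
                rows.append(
                    {
                        "velocity_M_per_s": v_true * _lognormal_factor(rng, design.noise_cv),
                        "substrate_M": float(s_conc),
                        "modulator_M": float(i_conc),
                        "enzyme_M": design.enzyme_conc_M,
                        "replicate": f"r{rep}",
                    }
                )
    return pd.DataFrame(rows)


def simulate_progress_curves(
    design: AssayDesign,
    mechanism: Mechanism = None,
    sampling_interval_s: float = 60.0,
    calibration: float = 1.0,
) -> pd.DataFrame:
    """Linear progress curves whose slopes match the simulated rates.

    Returns the progress-curve CSV dialect: long format with columns
    ``time_s, signal, substrate_M, modulator_M, enzyme_M, replicate``.
    Signal is calibration * velocity * t (zero intercept).
    """
    rates = simulate_assay(design, mechanism)
    times = np.arange(0.0, design.read_duration_s + sampling_interval_s / 2, sampling_interval_s)
    frames = []
    for _, row in rates.iterrows():
        frames.append(
            pd.DataFrame(
                {
                    "time_s": times,
                    "signal": calibration * row["velocity_M_per_s"] * times,
                    "substrate_M": row["substrate_M"],
                    "modulator_M": row["modulator_M"],
                    "enzyme_M": row["enzyme_M"],
                    "replicate": row["replicate"],
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def _fixture_mechanisms() -> dict[str, Mechanism]:
    return {
        "H2T4-like": CompetitiveMechanism(ki=reference.KI_H2T4_M),
        "MTPyApi-like": CompetitiveMechanism(ki=reference.KI_MTPYAPI_M),
        "TMPC-like": reference.TMPC_LIKE,
        "TrisT4-like": reference.TRIS_T4_LIKE,
        "null": None,
    }


def generate_fixture_suite(seed: int, out_dir: str | Path | None = None) -> dict:
    """Generate the five canonical synthetic datasets (plus a manifest).

    Returns ``{"datasets": {name: DataFrame}, "manifest": dict}``; when
    ``out_dir`` is given, writes ``<name>.csv`` for each dataset and
    ``manifest.json`` recording the generating parameters and seed.
    """
    from . import __version__

    design = AssayDesign(seed=seed)
    datasets = {}
    manifest: dict = {"seed": seed, "package_version": __version__, "design": asdict(design), "datasets": {}}
    for name, mech in _fixture_mechanisms().items():
        datasets[name] = simulate_assay(design, mech)
        if mech is None:
            desc: dict = {"mechanism": "none"}
        elif isinstance(mech, CompetitiveMechanism):
            desc = {"mechanism": "competitive", "parameters": asdict(mech)}
        else:
            desc = {"mechanism": "twostate", "parameters": asdict(mech)}
        desc["note"] = "synthetic dataset; parameters are generator inputs, not measurements"
        manifest["datasets"][name] = desc
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, df in datasets.items():
            df.to_csv(out / f"{name}.csv", index=False)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return {"datasets": datasets, "manifest": manifest}
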