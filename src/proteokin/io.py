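"""CSV dialects, parameter configs, and the analysis pipeline.

All concentrations are serialized in molar with explicit ``_M`` suffixes in
the column and key names; there is no unit auto-detection.

Rate tables:      velocity_M_per_s, substrate_M, modulator_M, enzyme_M, replicate
Progress curves:  time_s, signal, substrate_M, modulator_M, enzyme_M, replicate
Dose responses:   modulator_M, kcat_obs_per_s, Km_obs_M, efficiency_per_M_per_s
Parameter config: flat YAML key-value with units in key names
                  (kcatA_per_s, KmA_M, KAU_per_M, ..., LU, LL, n, m)
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import inference, reference, simulate
from .inhibition import NoInhibitionError, fit_competitive_global
from .kinetics import KineticsError, ProgressCurve, RateObservation, fit_mm
from .twostate import DoseResponse, TwoStateParameters

__all__ = [
    "read_rate_table",
    "write_rate_table",
    "rate_table_to_observations",
    "read_progress_curves",
    "read_dose_response",
    "write_dose_response",
    "read_params_config",
    "write_params_config",
    "dose_response_from_rates",
    "RunReport",
    "run_pipeline",
    "ValidationError",
]

RATE_COLUMNS = ["velocity_M_per_s", "substrate_M", "modulator_M", "enzyme_M", "replicate"]
CURVE_COLUMNS = ["time_s", "signal", "substrate_M", "modulator_M", "enzyme_M", "replicate"]

_CONFIG_KEYS = {
    "kcatA_per_s": "kcat_a",
    "kcatB_per_s": "kcat_b",
    "KmA_M": "km_a",
    "KmB_M": "km_b",
    "LU": "l_u",
    "LL": "l_l",
    "KAU_per_M": "k_au",
    "KAL_per_M": "k_al",
    "KBU_per_M": "k_bu",
    "KBL_per_M": "k_bl",
    "KAI_per_M": "k_ai",
    "KBI_per_M": "k_bi",
    "n": "n_sites",
    "m": "m_sites",
}


class ValidationError(ValueError):
    """Raised when an input file fails schema or value validation."""


def _check_columns(df: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing column(s) {missing}")


def _check_numeric(df: pd.DataFrame, cols: list[str], path) -> pd.DataFrame:
    for col in cols:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[converted.isna()]
        if len(bad):
            raise ValidationError(f"{path}: non-numeric value in column {col!r}, row {int(bad[0])}")
        df[col] = converted
    return df


def read_rate_table(path) -> pd.DataFrame:
    """Read and validate a rate-table CSV."""
    df = pd.read_csv(path, float_precision="round_trip")
    if df.empty:
        raise ValidationError(f"{path}: empty table")
    _check_columns(df, RATE_COLUMNS, path)
    df = _check_numeric(df, RATE_COLUMNS[:4], path)
    neg = df.index[df["velocity_M_per_s"] < 0]
    if len(neg):
        raise ValidationError(f"{path}: negative velocity at row {int(neg[0])}")
    for col in ("substrate_M", "modulator_M"):
        neg = df.index[df[col] < 0]
        if len(neg):
            raise ValidationError(f"{path}: negative {col} at row {int(neg[0])}")
    if (df["enzyme_M"] <= 0).any():
        raise ValidationError(f"{path}: enzyme_M must be positive")
    dup = df.duplicated(subset=["substrate_M", "modulator_M", "replicate"])
    if dup.any():
        raise ValidationError(f"{path}: duplicate (substrate_M, modulator_M, replicate) at row {int(df.index[dup][0])}")
    return df[RATE_COLUMNS]


def write_rate_table(df: pd.DataFrame, path) -> None:
    df[RATE_COLUMNS].to_csv(path, index=False)


def rate_table_to_observations(df: pd.DataFrame) -> list[RateObservation]:
    return [
        RateObservation(
            velocity=row.velocity_M_per_s,
            substrate_conc=row.substrate_M,
            modulator_conc=row.modulator_M,
            enzyme_conc=row.enzyme_M,
            replicate_id=str(row.replicate),
        )
        for row in df.itertuples()
    ]


def read_progress_curves(path, calibration: float = 1.0) -> list[ProgressCurve]:
    """Read a long-format progress-curve CSV into per-well ProgressCurve objects."""
    df = pd.read_csv(path, float_precision="round_trip")
    if df.empty:
        raise ValidationError(f"{path}: empty table")
    _check_columns(df, CURVE_COLUMNS, path)
    df = _check_numeric(df, CURVE_COLUMNS[:5], path)
    curves = []
    for (s, i, e, rep), g in df.groupby(["substrate_M", "modulator_M", "enzyme_M", "replicate"], sort=True):
        g = g.sort_values("time_s")
        curves.append(
            ProgressCurve(
                times=g["time_s"].to_numpy(float),
                signal=g["signal"].to_numpy(float),
                substrate_conc=float(s),
                modulator_conc=float(i),
                enzyme_conc=float(e),
                replicate_id=str(rep),
                calibration=calibration,
            )
        )
    return curves


def read_dose_response(path) -> DoseResponse:
    df = pd.read_csv(path, float_precision="round_trip")
    _check_columns(df, ["modulator_M", "kcat_obs_per_s", "Km_obs_M", "efficiency_per_M_per_s"], path)
    return DoseResponse.from_frame(df)


def write_dose_response(dr: DoseResponse, path) -> None:
    dr.to_frame().to_csv(path, index=False)


def read_params_config(path) -> TwoStateParameters:
    """Read a two-state parameter set from a flat YAML key-value file."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ValidationError(f"{path}: expected a flat key-value mapping")
    unknown = set(raw) - set(_CONFIG_KEYS)
    if unknown:
        raise ValidationError(f"{path}: unknown key(s) {sorted(unknown)}")
    missing = set(_CONFIG_KEYS) - set(raw)
    if missing:
        raise ValidationError(f"{path}: missing key(s) {sorted(missing)}")
    kwargs = {}
    for key, attr in _CONFIG_KEYS.items():
        v = raw[key]
        kwargs[attr] = int(v) if attr in ("n_sites", "m_sites") else float(v)
    return TwoStateParameters(**kwargs)


def write_params_config(params: TwoStateParameters, path) -> None:
    out = {key: getattr(params, attr) for key, attr in _CONFIG_KEYS.items()}
    Path(path).write_text(yaml.safe_dump(out, sort_keys=False))


def dose_response_from_rates(df: pd.DataFrame, method: str = "direct") -> DoseResponse:
    """Per-modulator Michaelis–Menten fits assembled into a DoseResponse."""
    rows = []
    for i_conc, group in df.groupby("modulator_M", sort=True):
        obs = rate_table_to_observations(group)
        mm = fit_mm(obs, method=method)
        rows.append((float(i_conc), mm))
    rows.sort(key=lambda r: r[0])
    grid = np.array([r[0] for r in rows])
    kcat = np.array([r[1].kcat for r in rows])
    km = np.array([r[1].km for r in rows])
    return DoseResponse(
        modulator_grid=grid,
        kcat=kcat,
        km=km,
        efficiency=kcat / km,
        kcat_stderr=np.array([r[1].kcat_stderr for r in rows]),
        km_stderr=np.array([r[1].km_stderr for r in rows]),
    )


@dataclass(frozen=True)
class RunReport:
    """Structured, reproducible record of one pipeline run."""

    input_digest: str
    config: dict
    seed: int
    results: dict
    warnings: tuple
    package_version: str

    def to_json(self, path=None) -> str:
        payload = dataclasses.asdict(self)
        payload["warnings"] = list(payload["warnings"])
        text = json.dumps(payload, indent=2, default=_json_default)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, text: str) -> "RunReport":
        d = json.loads(text)
        d["warnings"] = tuple(d["warnings"])
        return cls(**d)


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if dataclasses.is_dataclass(obj):
        return dataclasses.asdict(obj)
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="records")
    raise TypeError(f"not JSON serializable: {type(obj)}")


_STAGES = ("fit_mm", "competitive", "allosteric", "select_sites", "classify")


def run_pipeline(config: dict) -> RunReport:
    """Run the staged analysis described by ``config``.

    Config keys: ``input`` (rate-table CSV path) or ``fixture`` (name of a
    synthetic dataset), ``seed``, ``stages`` (ordered subset of
    fit_mm -> competitive -> allosteric -> select_sites -> classify), and
    optional per-stage sections (``allosteric: {n, m, params}``,
    ``select_sites: {n: [...], m: [...]}``).
    """
    from . import __version__

    stages = list(config.get("stages", []))
    if not stages:
        raise ValidationError("config lists no stages")
    bad = [s for s in stages if s not in _STAGES]
    if bad:
        raise ValidationError(f"unknown stage(s): {bad}")
    seed = int(config.get("seed", 0))

    if "input" in config:
        path = config["input"]
        rates = read_rate_table(path)
        digest = hashlib.sha256(Path(path).read_bytes()).hexdigest()
    elif "fixture" in config:
        name = config["fixture"]
        suite = simulate.generate_fixture_suite(seed)
        if name not in suite["datasets"]:
            raise ValidationError(f"unknown fixture {name!r}; choose from {sorted(suite['datasets'])}")
        rates = suite["datasets"][name]
        digest = hashlib.sha256(rates.to_csv(index=False).encode()).hexdigest()
    else:
        raise ValidationError("config needs 'input' or 'fixture'")

    results: dict = {}
    warnings: list[str] = []
    dr: DoseResponse | None = None
    for stage in stages:
        try:
            if stage == "fit_mm":
                dr = dose_response_from_rates(rates)
                results["fit_mm"] = {"dose_response": dr.to_frame()}
            else:
                if dr is None:
                    dr = dose_response_from_rates(rates)
                if stage == "competitive":
                    try:
                        cf = fit_competitive_global(
                            rates["velocity_M_per_s"],
                            rates["substrate_M"],
                            rates["modulator_M"],
                            rates["enzyme_M"],
                        )
                        results["competitive"] = dataclasses.asdict(cf)
                    except NoInhibitionError as exc:
                        results["competitive"] = {"no_inhibition": str(exc)}
                        warnings.append(f"competitive: {exc}")
                elif stage == "allosteric":
                    opts = config.get("allosteric", {})
                    base = read_params_config(opts["params"]) if "params" in opts else None
                    init = base if base is not None else inference._generic_init(dr)
                    fixed = inference.SHARED_PARAMETERS if base is not None else ()
                    fit = inference.fit_two_state(
                        dr,
                        init,
                        n_sites=int(opts.get("n", 3)),
                        m_sites=int(opts.get("m", 1)),
                        fixed=tuple(opts.get("fix", fixed)),
                        seed=seed,
                    )
                    results["allosteric"] = {
                        "params": dataclasses.asdict(fit.params),
                        "stderr": fit.stderr,
                        "rss": fit.rss,
                        "aicc": fit.aicc,
                        "free": list(fit.free),
                    }
                elif stage == "select_sites":
                    opts = config.get("select_sites", {})
                    base = read_params_config(opts["params"]) if "params" in opts else None
                    sel = inference.select_site_numbers(
                        dr,
                        n_candidates=opts.get("n", (1, 2, 3, 4)),
                        m_candidates=opts.get("m", (0, 1)),
                        base=base,
                        seed=seed,
                    )
                    results["select_sites"] = {
                        "n": sel.n_sites,
                        "m": sel.m_sites,
                        "label": sel.label,
                        "table": sel.table,
                    }
                    warnings.extend(sel.warnings)
                elif stage == "classify":
                    cls = inference.classify_mechanism(dr, seed=seed)
                    results["classify"] = {
                        "label": cls.label,
                        "n": cls.n_sites,
                        "m": cls.m_sites,
                        "table": cls.table,
                    }
        except (KineticsError, ValidationError, ValueError, RuntimeError) as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    return RunReport(
        input_digest=digest,
        config=config,
        seed=seed,
        results=results,
        warnings=tuple(warnings),
        package_version=__version__,
    )
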