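"""CSV dialects, run configuration and report assembly.

All tables are long-format UTF-8 CSV with decimal points.  Dialects:

* residue:   soil_id, application, day, replicate, recovery_percent
* sorption:  soil_id, c_initial, c_aq, soil_mass_g, solution_volume_ml
* qPCR:      sample_id, group, target, ct_1, ct_2, ct_3
* standards: target, concentration, ct

Every written artifact embeds the seed and a hash of the configuration
that produced it, so runs are auditable and reruns byte-comparable.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .growth_model import ApplicationSchedule, ResidueObservations
from .qpcr import (GeneQuantResult, compare_groups, fit_standard_curve,
                   percent_community, quantify)
from .sorption import BatchPoint

__all__ = [
    "RunConfig",
    "FormatError",
    "ConfigError",
    "RESIDUE_COLUMNS",
    "read_residue_csv",
    "write_residue_csv",
    "read_sorption_csv",
    "read_qpcr_csvs",
    "quantify_qpcr_tables",
    "validate_config",
    "write_report",
]

log = logging.getLogger("atrakin")

RESIDUE_COLUMNS = ("soil_id", "application", "day", "replicate",
                   "recovery_percent")
SORPTION_COLUMNS = ("soil_id", "c_initial", "c_aq", "soil_mass_g",
                    "solution_volume_ml")
QPCR_COLUMNS = ("sample_id", "group", "target", "ct_1", "ct_2", "ct_3")
STANDARD_COLUMNS = ("target", "concentration", "ct")


class FormatError(ValueError):
    """Malformed input table (bad header or cell values)."""


class ConfigError(ValueError):
    """Invalid or contradictory run configuration."""


_CONFIG_DEFAULTS = {
    "step": 0.01,
    "application_days": [0.0, 60.0, 88.0],
    "dose_percent": None,
    "seed": 0,
    "model": "auto",           # sfo | dfop | auto
    "n_starts": 32,
    "bounds": None,
    "noise_cv": 0.07,
    "log_level": "INFO",
}


@dataclass
class RunConfig:
    step: float = 0.01
    application_days: tuple = (0.0, 60.0, 88.0)
    dose_percent: tuple = None
    seed: int = 0
    model: str = "auto"
    n_starts: int = 32
    bounds: dict = None
    noise_cv: float = 0.07
    log_level: str = "INFO"

    @property
    def schedule(self) -> ApplicationSchedule:
        return ApplicationSchedule(self.application_days, self.dose_percent)

    def to_dict(self) -> dict:
        return {
            "step": self.step,
            "application_days": list(self.application_days),
            "dose_percent": None if self.dose_percent is None
            else list(self.dose_percent),
            "seed": self.seed, "model": self.model,
            "n_starts": self.n_starts, "bounds": self.bounds,
            "noise_cv": self.noise_cv, "log_level": self.log_level,
        }

    @property
    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


def validate_config(raw: dict | None) -> RunConfig:
    """Apply defaults and reject unknown keys or contradictory values."""
    raw = dict(raw or {})
    unknown = set(raw) - set(_CONFIG_DEFAULTS)
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    merged = {**_CONFIG_DEFAULTS, **raw}
    if not (isinstance(merged["step"], (int, float))
            and 0 < merged["step"] <= 1):
        raise ConfigError(f"step must be in (0, 1], got {merged['step']!r}")
    days = [float(d) for d in merged["application_days"]]
    if len(set(days)) != len(days):
        raise ConfigError("application_days contains duplicates")
    if merged["model"] not in ("sfo", "dfop", "auto"):
        raise ConfigError(f"unknown model {merged['model']!r}")
    if merged["n_starts"] < 1:
        raise ConfigError("n_starts must be >= 1")
    if merged["noise_cv"] < 0:
        raise ConfigError("noise_cv must be >= 0")
    try:
        ApplicationSchedule(days, merged["dose_percent"])
    except ValueError as e:
        raise ConfigError(str(e)) from e
    cfg = RunConfig(step=float(merged["step"]), application_days=tuple(days),
                    dose_percent=None if merged["dose_percent"] is None
                    else tuple(merged["dose_percent"]),
                    seed=int(merged["seed"]), model=merged["model"],
                    n_starts=int(merged["n_starts"]), bounds=merged["bounds"],
                    noise_cv=float(merged["noise_cv"]),
                    log_level=str(merged["log_level"]))
    return cfg


def _check_header(df: pd.DataFrame, required, path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")


def read_residue_csv(path) -> ResidueObservations:
    """Read a long-format residue table; censored recoveries may be blank."""
    df = pd.read_csv(path)
    _check_header(df, RESIDUE_COLUMNS, path)
    rec = pd.to_numeric(df["recovery_percent"], errors="coerce")
    bad = df.index[np.isfinite(rec) & (rec < 0)]
    if len(bad):
        raise FormatError(
            f"{path}: negative recovery in row(s) {[int(i) + 2 for i in bad]}")
    missing = df.index[df["recovery_percent"].notna() & rec.isna()]
    if len(missing):
        raise FormatError(
            f"{path}: non-numeric recovery in row(s) "
            f"{[int(i) + 2 for i in missing]}")
    return ResidueObservations(
        df["soil_id"].to_numpy(), df["application"].to_numpy(dtype=int),
        df["day"].to_numpy(dtype=float), df["replicate"].to_numpy(),
        rec.to_numpy(dtype=float))


def write_residue_csv(obs: ResidueObservations, path) -> None:
    pd.DataFrame({
        "soil_id": obs.soil_id, "application": obs.application,
        "day": obs.day, "replicate": obs.replicate,
        "recovery_percent": obs.recovery,
    }).to_csv(path, index=False)


def read_sorption_csv(path) -> dict:
    """Read batch points grouped by soil: ``{soil_id: [BatchPoint, ...]}``."""
    df = pd.read_csv(path)
    _check_header(df, SORPTION_COLUMNS, path)
    out = {}
    for _, r in df.iterrows():
        out.setdefault(r["soil_id"], []).append(BatchPoint(
            c_initial=float(r["c_initial"]), c_aq=float(r["c_aq"]),
            soil_mass=float(r["soil_mass_g"]),
            solution_volume=float(r["solution_volume_ml"])))
    return out


def read_qpcr_csvs(samples_path, standards_path) -> tuple:
    samples = pd.read_csv(samples_path)
    _check_header(samples, QPCR_COLUMNS, samples_path)
    standards = pd.read_csv(standards_path)
    _check_header(standards, STANDARD_COLUMNS, standards_path)
    return samples, standards


def quantify_qpcr_tables(samples: pd.DataFrame, standards: pd.DataFrame,
                         *, welch: bool = False) -> tuple:
    """Full qPCR analysis: curves, per-sample percentages, group t-test.

    Below-detection samples (NaN trzN Cts) carry NaN percentages and are
    excluded from the group comparison.

    Returns (results DataFrame, group-test dict).
    """
    curves = {t: fit_standard_curve(
        list(zip(g["concentration"], g["ct"])))
        for t, g in standards.groupby("target")}
    results = []
    for sid, g in samples.groupby("sample_id", sort=False):
        by_target = {r["target"]: [r["ct_1"], r["ct_2"], r["ct_3"]]
                     for _, r in g.iterrows()}
        group = g["group"].iloc[0]
        s16 = quantify(by_target["16S"], curves["16S"])
        trzn_cts = by_target["trzN"]
        if any(math.isnan(float(c)) for c in trzn_cts):
            trzn, pct = math.nan, math.nan
        else:
            trzn = quantify(trzn_cts, curves["trzN"])
            pct = percent_community(trzn, s16)
        results.append(GeneQuantResult(sample_id=sid, group=group,
                                       trzn_conc=trzn, s16_conc=s16,
                                       percent_trzn=pct))
    df = pd.DataFrame([r.__dict__ for r in results])
    ok = df["percent_trzn"].notna()
    treated = df.loc[ok & (df["group"] == "treated"), "percent_trzn"]
    control = df.loc[ok & (df["group"] == "control"), "percent_trzn"]
    test = None
    if len(treated) >= 2 and len(control) >= 2:
        t, dof, p = compare_groups(treated, control, welch=welch)
        test = {"t": t, "df": dof, "p": p,
                "mean_treated": float(treated.mean()),
                "mean_control": float(control.mean())}
    return df, test


def write_report(endpoints: pd.DataFrame, output_dir, *,
                 growth_fit=None, config: RunConfig | None = None) -> dict:
    """Write the endpoints CSV plus a JSON metadata sidecar.

    Returns the paths written.  Overwrites idempotently; the CSV is
    byte-stable across reruns with identical inputs.
    """
    if endpoints is None or len(endpoints) == 0:
        raise ValueError("no fits to report")
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = config or RunConfig()
    csv_path = out / "endpoints.csv"
    endpoints.to_csv(csv_path, float_format="%.6g")
    meta = {"seed": cfg.seed, "config_hash": cfg.config_hash,
            "config": cfg.to_dict(), "n_rows": int(len(endpoints))}
    if growth_fit is not None:
        p = growth_fit.params
        meta["growth_fit"] = {
            "k1": p.k1, "Y": p.Y, "N0": p.N0, "mu": p.mu, "V": p.V,
            "Ks": p.Ks, "sse": growth_fit.sse,
            "converged": growth_fit.converged,
            "n_starts": growth_fit.n_starts}
    json_path = out / "report.json"
    json_path.write_text(json.dumps(meta, indent=2, sort_keys=True))
    log.info("wrote %s and %s (seed=%s, config=%s)", csv_path, json_path,
             cfg.seed, cfg.config_hash)
    return {"endpoints_csv": csv_path, "report_json": json_path}
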