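"""Synthetic-data generators emulating the study design.

Every pipeline input can be generated here with the statistical structure
the analysis assumes: residue time series over three applications (6 ug/g
at days 0/60/88; sampling 0,1,3,7,14,28,45,60 days after the first and
0,1,3,7,14,28 after later applications), batch sorption points on the
0.02-2.0 ug/mL nominal grid, and qPCR plates with tenfold dilution
standards and triplicate Cts.  All generators are deterministic given a
seed.

Default replicate noise is multiplicative with CV 7% — a panel-level
default chosen to emulate the replicate scatter typical of soil residue
studies; real soils additionally show day-to-day extraction-efficiency
drifts that these generators do not model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .growth_model import (ApplicationSchedule, GrowthLinkedParams,
                           ResidueObservations, SimulationSettings,
                           simulate_growth_linked)
from .qpcr import AMPLICON_LEN_16S, AMPLICON_LEN_TRZN
from .sorption import BatchPoint, FreundlichFit

__all__ = [
    "SoilScenario",
    "NoiseModel",
    "DEFAULT_SAMPLING_DAYS",
    "PANEL_PARAMETER_RANGES",
    "LOD_PERCENT",
    "generate_dissipation",
    "generate_soil_panel",
    "generate_sorption_batch",
    "generate_qpcr",
]

#: days-since-application sampling grids: richer after the first application
DEFAULT_SAMPLING_DAYS = {
    1: (0, 1, 3, 7, 14, 28, 45, 60),
    2: (0, 1, 3, 7, 14, 28),
    3: (0, 1, 3, 7, 14, 28),
}

#: fitted parameter ranges of the adapting soils; N0 spans three orders of
#: magnitude and is drawn log-uniformly; Ks is 75 throughout.
PANEL_PARAMETER_RANGES = {
    "k1": (0.06, 0.18),
    "Y": (30.0, 65.0),
    "mu": (0.155, 0.225),
    "V": (0.6, 0.7),
    "N0": (5e-5, 0.03),
}

#: residue reporting limit, % of dose (0.02 ug/mL analytical LOD on the
#: 6 ug/g dose scale); generated recoveries below it are censored to NaN.
LOD_PERCENT = 0.33


@dataclass(frozen=True)
class NoiseModel:
    kind: str = "multiplicative-normal"   # or "additive-normal"
    cv: float = 0.07
    sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("multiplicative-normal", "additive-normal"):
            raise ValueError(f"unknown noise kind {self.kind!r}")
        if self.cv < 0 or self.sd < 0:
            raise ValueError("noise parameters must be >= 0")

    def apply(self, values: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        v = np.asarray(values, dtype=float)
        if self.kind == "multiplicative-normal":
            if self.cv == 0:
                return v.copy()
            out = v * rng.normal(1.0, self.cv, size=v.shape)
        else:
            if self.sd == 0:
                return v.copy()
            out = v + rng.normal(0.0, self.sd, size=v.shape)
        return np.maximum(out, 0.0)


@dataclass(frozen=True)
class SoilScenario:
    soil_id: str
    growth_params: GrowthLinkedParams
    adapting: bool = True
    replicate_cv: float = 0.07
    n_replicates: int = 4

    def __post_init__(self) -> None:
        if self.replicate_cv < 0:
            raise ValueError("replicate_cv must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if not self.adapting and self.growth_params.N0 != 0:
            raise ValueError("non-adapting scenarios must have N0 = 0")


def generate_dissipation(
    scenario: SoilScenario,
    schedule: ApplicationSchedule = ApplicationSchedule(),
    sampling_days: dict | None = None,
    noise: NoiseModel | None = None,
    step: float = 0.01,
    censor_below_lod: bool = True,
) -> ResidueObservations:
    """Simulate the scenario, sample the grid and add replicate noise.

    Recoveries below the reporting limit (0.33% of dose) are censored to
    NaN; fitters drop censored values.
    """
    sampling_days = dict(DEFAULT_SAMPLING_DAYS if sampling_days is None
                         else sampling_days)
    noise = noise if noise is not None else NoiseModel(cv=scenario.replicate_cv)
    app_days = schedule.application_days
    horizon = 0.0
    for a, days in sampling_days.items():
        if not 1 <= a <= schedule.n_applications:
            raise ValueError(f"sampling grid references application {a} "
                             f"outside the {schedule.n_applications}-application schedule")
        horizon = max(horizon, app_days[a - 1] + max(days))
    series = simulate_growth_linked(
        scenario.growth_params, schedule,
        SimulationSettings(step=step, horizon=horizon + step))

    rng = np.random.default_rng(noise.seed)
    soil, app, day, rep, rec = [], [], [], [], []
    for a in sorted(sampling_days):
        for d in sampling_days[a]:
            t_abs = app_days[a - 1] + d
            if d > 0 and t_abs in app_days:
                # sample drawn just before the next dose goes on
                t_abs -= 1e-9
            true_val = float(series.interp_atr(t_abs))
            vals = noise.apply(np.full(scenario.n_replicates, true_val), rng)
            for r, v in enumerate(vals, start=1):
                soil.append(scenario.soil_id)
                app.append(a)
                day.append(float(d))
                rep.append(f"R{r}")
                rec.append(math.nan if (censor_below_lod and v < LOD_PERCENT)
                           else float(v))
    return ResidueObservations(np.array(soil), np.array(app), np.array(day),
                               np.array(rep), np.array(rec))


def generate_soil_panel(
    n_adapting: int = 8,
    n_nonadapting: int = 1,
    ranges: dict | None = None,
    seed: int = 0,
    Ks: float = 75.0,
    replicate_cv: float = 0.07,
    n_replicates: int = 4,
    schedule: ApplicationSchedule = ApplicationSchedule(),
    step: float = 0.01,
) -> list:
    """Draw a panel of soil scenarios and their residue observations.

    Adapting soils draw (k1, Y, mu, V) uniformly and N0 log-uniformly from
    the panel ranges; non-adapting soils draw the same chemistry but have no
    growth-capable degraders (N0 = 0), which reproduces residue accumulation
    over repeated applications.  Returns ``[(SoilScenario,
    ResidueObservations), ...]``; reproducible by seed.
    """
    if n_adapting < 0 or n_nonadapting < 0:
        raise ValueError("panel counts must be >= 0")
    ranges = dict(PANEL_PARAMETER_RANGES, **(ranges or {}))
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n_adapting + n_nonadapting):
        adapting = i < n_adapting
        k1 = rng.uniform(*ranges["k1"])
        Y = rng.uniform(*ranges["Y"])
        mu = rng.uniform(*ranges["mu"])
        V = rng.uniform(*ranges["V"])
        lo, hi = ranges["N0"]
        n0 = math.exp(rng.uniform(math.log(lo), math.log(hi))) if adapting else 0.0
        label = f"SYN_A{i + 1}" if adapting else f"SYN_N{i - n_adapting + 1}"
        scenario = SoilScenario(
            soil_id=label,
            growth_params=GrowthLinkedParams(k1=k1, Y=Y, N0=n0,
                                             mu=mu if adapting else 0.0,
                                             V=V, Ks=Ks),
            adapting=adapting, replicate_cv=replicate_cv,
            n_replicates=n_replicates)
        obs = generate_dissipation(
            scenario, schedule,
            noise=NoiseModel(cv=replicate_cv,
                             seed=int(rng.integers(0, 2**31 - 1))),
            step=step)
        out.append((scenario, obs))
    return out


def generate_sorption_batch(
    fit: FreundlichFit,
    c_initial=(0.02, 0.08, 0.20, 0.80, 2.0),
    soil_mass: float = 5.0,
    solution_volume: float = 25.0,
    noise_cv: float = 0.0,
    seed: int = 0,
    n_replicates: int = 2,
) -> list:
    """Generate batch points consistent with a known isotherm.

    For each nominal c_initial the equilibrium c_aq solves the mass balance
        c_initial*V = c_aq*V + m * kf * c_aq^{1/n}
    by bracketed root-finding on [0, c_initial]; measurement noise is then
    applied to c_aq (multiplicative, clamped to [0, c_initial]).  Duplicate
    tubes are independent points.
    """
    rng = np.random.default_rng(seed)
    m, V = soil_mass, solution_volume
    points = []
    for c0 in c_initial:
        def f(c, c0=c0):
            return c * V + m * fit.kf * c ** fit.inv_n - c0 * V
        if fit.kf == 0:
            caq_true = c0
        else:
            caq_true = brentq(f, 0.0, c0, xtol=1e-14, rtol=1e-14)
        for _ in range(n_replicates):
            caq = caq_true
            if noise_cv > 0:
                caq = float(np.clip(caq_true * rng.normal(1.0, noise_cv),
                                    0.0, c0))
            points.append(BatchPoint(c_initial=c0, c_aq=caq,
                                     soil_mass=m, solution_volume=V))
    return points


def generate_qpcr(
    true_percent: dict,
    curves: dict | None = None,
    triplicate_sd: float = 0.0,
    seed: int = 0,
    s16_base_conc: float = 0.1,
) -> tuple:
    """Generate qPCR sample and standard tables from true community percentages.

    Parameters
    ----------
    true_percent : dict
        ``{sample_id: (group, percent)}`` with group "treated" or "control".
        A percent of 0 is below detection: the trzN Cts are emitted as NaN.
    curves : dict, optional
        ``{target: (slope, intercept)}``; defaults to perfect-efficiency
        curves (slope -log2(10)... i.e. -3.32193) with distinct intercepts.
    triplicate_sd : float
        Gaussian Ct noise per technical replicate (cycles).

    Returns
    -------
    (samples, standards) : two DataFrames in the qPCR CSV dialect —
    samples: sample_id, group, target, ct_1..ct_3; standards: target,
    concentration, ct (tenfold dilution series, 5 points for trzN and 6
    for 16S).
    """
    if curves is None:
        curves = {"trzN": (-3.32193, 24.0), "16S": (-3.32193, 16.0)}
    rng = np.random.default_rng(seed)

    def ct_of(target, conc):
        slope, intercept = curves[target]
        return slope * math.log10(conc) + intercept

    std_rows = []
    for target, n_dils in (("trzN", 5), ("16S", 6)):
        for j in range(n_dils):          # tenfold serial dilutions
            conc = 10.0 ** (-j)
            std_rows.append({"target": target, "concentration": conc,
                             "ct": ct_of(target, conc)})
    standards = pd.DataFrame(std_rows)

    sample_rows = []
    for sample_id, (group, pct) in true_percent.items():
        if pct < 0:
            raise ValueError("true_percent must be >= 0")
        s16 = s16_base_conc
        cts = {"16S": ct_of("16S", s16)}
        if pct == 0:
            cts["trzN"] = math.nan     # below detection
        else:
            trzn = pct / 100.0 * s16 * AMPLICON_LEN_TRZN / AMPLICON_LEN_16S
            cts["trzN"] = ct_of("trzN", trzn)
        for target in ("trzN", "16S"):
            base = cts[target]
            trip = [base if math.isnan(base)
                    else base + (rng.normal(0.0, triplicate_sd)
                                 if triplicate_sd > 0 else 0.0)
                    for _ in range(3)]
            sample_rows.append({"sample_id": sample_id, "group": group,
                                "target": target, "ct_1": trip[0],
                                "ct_2": trip[1], "ct_3": trip[2]})
    samples = pd.DataFrame(sample_rows)
    return samples, standards
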