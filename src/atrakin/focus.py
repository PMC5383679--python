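"""Regulatory-style dissipation kinetics: SFO and DFOP fits per application,
DT50/DT90 endpoints, the FOCUS chi-square error statistic, parameter t-tests
and the SFO-vs-biphasic model-selection rule used to assemble endpoint tables.

Fits are performed on per-day replicate means within a single application
window, on day-since-application time, with C0 estimated rather than fixed
at 100 (day-0 recoveries vary).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import brentq, curve_fit

from .growth_model import ResidueObservations, UnderDeterminedError

__all__ = [
    "SFOFit",
    "DFOPFit",
    "ModelSelection",
    "fit_sfo",
    "fit_dfop",
    "chi2_error_percent",
    "parameter_t_test",
    "runs_test_pvalue",
    "select_model",
    "endpoint_table",
    "CHI2_THRESHOLD_PERCENT",
]

#: FOCUS acceptability threshold for the chi-square error statistic.
CHI2_THRESHOLD_PERCENT = 15.0

LN2 = math.log(2.0)
LN10 = math.log(10.0)


@dataclass
class SFOFit:
    """Single first-order fit C(t) = C0 * exp(-k t)."""

    C0: float
    k: float
    se_C0: float
    se_k: float
    chi2_err: float
    dt50: float
    dt90: float
    n_obs: int
    converged: bool
    days: np.ndarray = field(default=None, repr=False)
    observed: np.ndarray = field(default=None, repr=False)
    n_params: int = 2

    @property
    def residuals(self) -> np.ndarray:
        return self.observed - self.C0 * np.exp(-self.k * self.days)

    def predict(self, t):
        return self.C0 * np.exp(-self.k * np.asarray(t, dtype=float))

    def parameter_estimates(self) -> dict:
        return {"C0": (self.C0, self.se_C0), "k": (self.k, self.se_k)}

    @property
    def rate_parameters(self) -> tuple:
        return ("k",)


@dataclass
class DFOPFit:
    """Double first-order in parallel: C(t) = C0*(g e^{-kf t} + (1-g) e^{-ks t})."""

    C0: float
    g: float
    k_fast: float
    k_slow: float
    se_C0: float
    se_g: float
    se_k_fast: float
    se_k_slow: float
    chi2_err: float
    dt50: float
    dt90: float
    n_obs: int
    converged: bool
    sfo_equivalent: bool
    days: np.ndarray = field(default=None, repr=False)
    observed: np.ndarray = field(default=None, repr=False)
    n_params: int = 4

    @property
    def residuals(self) -> np.ndarray:
        return self.observed - self.predict(self.days)

    def predict(self, t):
        t = np.asarray(t, dtype=float)
        return self.C0 * (self.g * np.exp(-self.k_fast * t)
                          + (1 - self.g) * np.exp(-self.k_slow * t))

    def parameter_estimates(self) -> dict:
        return {"C0": (self.C0, self.se_C0), "g": (self.g, self.se_g),
                "k_fast": (self.k_fast, self.se_k_fast),
                "k_slow": (self.k_slow, self.se_k_slow)}

    @property
    def rate_parameters(self) -> tuple:
        return ("k_fast", "k_slow")


@dataclass
class ModelSelection:
    chosen: str                  # "SFO" | "DFOP" | "none"
    reasons: list
    sfo: SFOFit = None
    dfop: DFOPFit = None

    @property
    def fit(self):
        return {"SFO": self.sfo, "DFOP": self.dfop}.get(self.chosen)


def chi2_error_percent(observed_means, predicted, n_params: int) -> float:
    """FOCUS chi-square error statistic in percent.

    The smallest relative error (as % of the mean observation) at which the
    chi-square test on the day-mean residuals would still pass at alpha=0.05:

        err% = 100/mean(obs) * sqrt( sum((obs-pred)^2) / chi2_crit(0.05, m-p) )
    """
    obs = np.asarray(observed_means, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape:
        raise ValueError("observed and predicted must have equal length")
    m = len(obs)
    if m <= n_params:
        raise ValueError(f"need more day-means ({m}) than parameters ({n_params})")
    crit = stats.chi2.ppf(0.95, df=m - n_params)
    return float(100.0 / obs.mean() * math.sqrt(np.sum((obs - pred) ** 2) / crit))


def _window_day_means(obs: ResidueObservations, application_index: int):
    days, means = obs.day_means(application_index)
    return days, means


def fit_sfo(obs: ResidueObservations, application_index: int = 1) -> SFOFit:
    """Nonlinear least-squares SFO fit on replicate day-means.

    DT50 = ln2/k, DT90 = ln10/k.  A fit with k at the zero boundary (no
    detectable decay) is flagged not-converged and carries infinite DT50.
    """
    days, means = _window_day_means(obs, application_index)
    if len(days) < 3:
        raise UnderDeterminedError(
            f"SFO needs >= 3 distinct sampling days, got {len(days)}")

    def model(t, c0, k):
        return c0 * np.exp(-k * t)

    c0_guess = means[days == days.min()][0] if len(means) else 100.0
    k_guess = 0.1
    try:
        popt, pcov = curve_fit(model, days, means, p0=[c0_guess, k_guess],
                               bounds=([0, 0], [np.inf, np.inf]), maxfev=10000)
        c0, k = popt
        perr = np.sqrt(np.diag(pcov))
        ok = True
    except RuntimeError:
        c0, k = c0_guess, 0.0
        perr = np.array([np.nan, np.nan])
        ok = False
    no_decay = k < 1e-6  # boundary fit: no resolvable decay on any real scale
    chi2 = chi2_error_percent(means, model(days, c0, k), 2)
    dt50 = LN2 / k if not no_decay else math.inf
    dt90 = LN10 / k if not no_decay else math.inf
    return SFOFit(C0=float(c0), k=float(k), se_C0=float(perr[0]),
                  se_k=float(perr[1]), chi2_err=chi2, dt50=dt50, dt90=dt90,
                  n_obs=len(days), converged=ok and not no_decay,
                  days=days, observed=means)


def _dfop_curve(t, c0, g, kf, ks):
    return c0 * (g * np.exp(-kf * t) + (1 - g) * np.exp(-ks * t))


def _dfop_dtx(c0, g, kf, ks, frac: float) -> float:
    """Time at which the DFOP curve reaches ``frac`` of C0, by bracketed
    root-finding between the pure-fast and pure-slow half-lives."""
    target = frac * c0

    def f(t):
        return _dfop_curve(t, c0, g, kf, ks) - target

    t_lo = -math.log(frac) / kf   # fastest possible
    t_hi = -math.log(frac) / ks   # slowest possible
    if f(t_lo) <= 0:
        return t_lo
    if f(t_hi) >= 0:
        return t_hi
    return brentq(f, t_lo, t_hi, xtol=1e-10)


def fit_dfop(obs: ResidueObservations, application_index: int = 1) -> DFOPFit:
    """Least-squares DFOP fit; DT50/DT90 solved numerically on the fitted
    curve.  Rate constants are sorted so k_fast >= k_slow; a rate ratio
    below 1.01 is flagged SFO-equivalent."""
    days, means = _window_day_means(obs, application_index)
    if len(days) < 5:
        raise UnderDeterminedError(
            f"DFOP needs >= 5 distinct sampling days, got {len(days)}")

    c0_guess = means[days == days.min()][0] if len(means) else 100.0
    try:
        popt, pcov = curve_fit(
            _dfop_curve, days, means,
            p0=[c0_guess, 0.6, 0.3, 0.01],
            bounds=([0, 0, 1e-8, 1e-8], [np.inf, 1, 50, 50]), maxfev=20000)
        perr = np.sqrt(np.diag(pcov))
        ok = True
    except RuntimeError:
        popt = np.array([c0_guess, 1.0, 1e-8, 1e-8])
        perr = np.full(4, np.nan)
        ok = False
    c0, g, kf, ks = popt
    se_c0, se_g, se_kf, se_ks = perr
    if kf < ks:  # swap pools so the fast one is first
        kf, ks = ks, kf
        se_kf, se_ks = se_ks, se_kf
        g = 1 - g
    sfo_equiv = ks > 0 and kf / ks < 1.01
    chi2 = chi2_error_percent(means, _dfop_curve(days, c0, g, kf, ks), 4)
    dt50 = _dfop_dtx(c0, g, kf, ks, 0.5) if ok else math.inf
    dt90 = _dfop_dtx(c0, g, kf, ks, 0.1) if ok else math.inf
    return DFOPFit(C0=float(c0), g=float(g), k_fast=float(kf), k_slow=float(ks),
                   se_C0=float(se_c0), se_g=float(se_g), se_k_fast=float(se_kf),
                   se_k_slow=float(se_ks), chi2_err=chi2, dt50=dt50, dt90=dt90,
                   n_obs=len(days), converged=ok, sfo_equivalent=bool(sfo_equiv),
                   days=days, observed=means)


def parameter_t_test(fit) -> dict:
    """One-sided t-test per parameter (estimate/SE against zero), FOCUS style.

    df = number of day-means minus number of fitted parameters.  A parameter
    with zero or non-finite SE yields a NaN p-value (undefined test).
    """
    df = fit.n_obs - fit.n_params
    if df <= 0:
        raise ValueError("no degrees of freedom for the t-test")
    out = {}
    for name, (est, se) in fit.parameter_estimates().items():
        if not (se and math.isfinite(se)) or se <= 0:
            out[name] = math.nan
        else:
            out[name] = float(stats.t.sf(est / se, df))
    return out


def runs_test_pvalue(residuals) -> float:
    """Wald-Wolfowitz runs test on residual signs (one-sided, too-few-runs).

    A small p-value flags systematic residual structure — the automated
    stand-in for the visual-fit judgement of regulatory kinetics guidance.
    """
    r = np.asarray(residuals, dtype=float)
    signs = np.sign(r[r != 0])
    n1 = int(np.sum(signs > 0))
    n2 = int(np.sum(signs < 0))
    if n1 == 0 or n2 == 0:
        return 1.0
    runs = 1 + int(np.sum(signs[1:] != signs[:-1]))
    n = n1 + n2
    mean = 1 + 2 * n1 * n2 / n
    var = 2 * n1 * n2 * (2 * n1 * n2 - n) / (n ** 2 * (n - 1))
    if var <= 0:
        return 1.0
    z = (runs - mean) / math.sqrt(var)
    return float(stats.norm.cdf(z))


def _t_tests_ok(fit, alpha: float) -> bool:
    """All-parameter t-test pass/fail for model selection.  Undefined tests
    (zero SE) arise from an essentially perfect fit and are accepted only
    when the residuals really are negligible."""
    if not fit.converged:
        return False
    pvals = parameter_t_test(fit)
    finite = [p for p in pvals.values() if not math.isnan(p)]
    ok = all(p < alpha for p in finite)
    if len(finite) < len(pvals):
        resid = np.max(np.abs(fit.residuals)) if len(fit.residuals) else 0.0
        scale = float(np.mean(np.abs(fit.observed))) or 1.0
        ok = ok and resid < 1e-9 * scale
    return ok


def select_model(sfo: SFOFit, dfop: DFOPFit | None = None, *,
                 chi2_threshold: float = CHI2_THRESHOLD_PERCENT,
                 alpha: float = 0.05) -> ModelSelection:
    """SFO-first model selection.

    SFO is retained unless it is inadequate (chi-square error above the
    threshold, or systematic residual sign-runs) AND the biphasic candidate
    is itself acceptable (chi-square below threshold and all parameters pass
    the t-test).  If SFO is inadequate and no acceptable DFOP exists, the
    result is flagged "none" (no acceptable fit) with both fits recorded.
    """
    reasons = []
    sfo_chi_ok = sfo.chi2_err < chi2_threshold
    reasons.append(f"SFO chi2 {sfo.chi2_err:.2f}% "
                   f"{'<' if sfo_chi_ok else '>='} {chi2_threshold}%")
    sfo_t_ok = _t_tests_ok(sfo, alpha)
    reasons.append(f"SFO t-tests {'pass' if sfo_t_ok else 'fail'}")
    runs_p = runs_test_pvalue(sfo.residuals)
    runs_ok = runs_p >= alpha
    reasons.append(f"SFO residual runs test p={runs_p:.3f} "
                   f"({'no pattern' if runs_ok else 'systematic pattern'})")

    sfo_adequate = sfo.converged and sfo_chi_ok and sfo_t_ok and runs_ok
    if sfo_adequate or dfop is None:
        if sfo_adequate:
            reasons.append("SFO retained")
            return ModelSelection("SFO", reasons, sfo, dfop)
        reasons.append("SFO inadequate and no biphasic candidate")
        return ModelSelection("none", reasons, sfo, dfop)

    dfop_chi_ok = dfop.chi2_err < chi2_threshold
    reasons.append(f"DFOP chi2 {dfop.chi2_err:.2f}% "
                   f"{'<' if dfop_chi_ok else '>='} {chi2_threshold}%")
    dfop_t_ok = _t_tests_ok(dfop, alpha)
    reasons.append(f"DFOP t-tests {'pass' if dfop_t_ok else 'fail'}")
    if dfop.converged and dfop_chi_ok and dfop_t_ok and not dfop.sfo_equivalent:
        reasons.append("DFOP chosen (SFO inadequate, DFOP acceptable)")
        return ModelSelection("DFOP", reasons, sfo, dfop)
    reasons.append("no acceptable fit")
    return ModelSelection("none", reasons, sfo, dfop)


def endpoint_table(fits: dict) -> pd.DataFrame:
    """Assemble a soil x application endpoint table with adaptation ratios.

    Parameters
    ----------
    fits : dict
        ``{(soil_id, application_index): fit}`` where each fit exposes
        ``dt50`` and ``chi2_err`` (SFOFit or DFOPFit); missing combinations
        simply leave blank cells.

    Returns
    -------
    DataFrame indexed by soil with per-application ``dt50_<i>`` and
    ``chi2_<i>`` columns plus, where computable:

    * ``fold_reduction_1_2`` — DT50(app1)/DT50(app2), the accelerated-
      degradation signal;
    * ``persistence_ratio_<i>`` — this soil's DT50 divided by the largest
      DT50 among the *other* soils at the same application (how much more
      persistent the residue is here than anywhere else).
    """
    if not fits:
        raise ValueError("need at least one fit")
    soils = list(dict.fromkeys(s for s, _ in fits))
    apps = sorted({a for _, a in fits})
    rows = {}
    for s in soils:
        row = {}
        for a in apps:
            f = fits.get((s, a))
            row[f"dt50_{a}"] = getattr(f, "dt50", np.nan) if f else np.nan
            row[f"chi2_{a}"] = getattr(f, "chi2_err", np.nan) if f else np.nan
        rows[s] = row
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "soil_id"
    if {1, 2} <= set(apps):
        df["fold_reduction_1_2"] = df["dt50_1"] / df["dt50_2"]
    if len(soils) > 1:
        for a in apps:
            col = df[f"dt50_{a}"]
            others_max = np.array([col.drop(index=s).max() for s in df.index])
            df[f"persistence_ratio_{a}"] = col / others_max
    return df
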