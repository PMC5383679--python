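"""Batch-sorption mass balance and Freundlich isotherm fitting (OECD-106 style).

A batch point equilibrates a soil mass with a spiked solution; everything
that leaves the aqueous phase is assumed sorbed, so the sorbed concentration
follows from the mass balance.  The isotherm Cs = Kf * Caq^(1/n) is fitted
by untransformed least squares, matching the spreadsheet-solver practice of
sorption studies (a log-log regression is available for comparison).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit
from scipy.stats import linregress

from .growth_model import UnderDeterminedError

__all__ = [
    "BatchPoint",
    "FreundlichFit",
    "sorbed_concentration",
    "fit_freundlich",
    "predict_isotherm",
]


class MassBalanceError(ValueError):
    """Equilibrium aqueous concentration exceeds the initial concentration."""


@dataclass(frozen=True)
class BatchPoint:
    """One batch equilibrium tube.

    c_initial, c_aq in ug/mL; soil_mass in g; solution_volume in mL.
    The study design is 5 g soil : 25 mL solution (1:5) at nominal
    concentrations 0.02-2.0 ug/mL.
    """

    c_initial: float
    c_aq: float
    soil_mass: float = 5.0
    solution_volume: float = 25.0

    def __post_init__(self) -> None:
        if self.soil_mass <= 0 or self.solution_volume <= 0:
            raise ValueError("soil mass and solution volume must be > 0")
        if self.c_aq < 0 or self.c_initial < 0:
            raise ValueError("concentrations must be >= 0")
        if self.c_aq > self.c_initial * (1 + 1e-9):
            raise MassBalanceError(
                f"c_aq={self.c_aq} exceeds c_initial={self.c_initial}")


@dataclass
class FreundlichFit:
    """Freundlich coefficients: Cs = kf * Caq^{inv_n}."""

    kf: float
    inv_n: float
    sse: float
    n_points: int

    def __post_init__(self) -> None:
        if self.kf < 0 or self.inv_n <= 0:
            raise ValueError("kf must be >= 0 and 1/n > 0")


def sorbed_concentration(point: BatchPoint) -> float:
    """Sorbed concentration Cs = (c_initial - c_aq) * V / m, in ug/g."""
    return (point.c_initial - point.c_aq) * point.solution_volume / point.soil_mass


def fit_freundlich(points, *, log_log: bool = False) -> FreundlichFit:
    """Fit Cs = kf * Caq^{1/n} to (c_aq, c_s) pairs.

    Default: untransformed least squares (deterministic multi-start over a
    small 1/n grid).  ``log_log=True`` instead regresses log Cs on log Caq,
    which weights low concentrations more heavily.
    """
    pts = [(float(c), float(s)) for c, s in points]
    caq = np.array([c for c, _ in pts])
    cs = np.array([s for _, s in pts])
    if len(np.unique(caq[caq > 0])) < 3:
        raise UnderDeterminedError(
            "need >= 3 points with distinct positive c_aq")

    if log_log:
        pos = (caq > 0) & (cs > 0)
        res = linregress(np.log(caq[pos]), np.log(cs[pos]))
        kf, inv_n = math.exp(res.intercept), res.slope
        sse = float(np.sum((cs - kf * caq ** inv_n) ** 2))
        return FreundlichFit(kf=kf, inv_n=inv_n, sse=sse, n_points=len(pts))

    def model(c, kf, inv_n):
        return kf * np.power(c, inv_n)

    best = None
    # kd-style kf guess from the largest point; multi-start over curvature
    kf0 = cs[np.argmax(caq)] / max(caq.max(), 1e-12)
    for inv_n0 in (0.5, 0.8, 1.0, 1.3):
        try:
            popt, _ = curve_fit(model, caq, cs, p0=[max(kf0, 1e-6), inv_n0],
                                bounds=([0, 1e-6], [np.inf, 10]), maxfev=20000)
        except RuntimeError:
            continue
        sse = float(np.sum((cs - model(caq, *popt)) ** 2))
        if best is None or sse < best[0]:
            best = (sse, popt)
    if best is None:
        raise RuntimeError("Freundlich fit failed from all starts")
    sse, (kf, inv_n) = best
    return FreundlichFit(kf=float(kf), inv_n=float(inv_n), sse=sse,
                         n_points=len(pts))


def predict_isotherm(fit: FreundlichFit, c_aq) -> float:
    """Predicted sorbed concentration kf * c_aq^{1/n} (ug/g)."""
    c = np.asarray(c_aq, dtype=float)
    if np.any(c < 0):
        raise ValueError("c_aq must be >= 0")
    out = fit.kf * np.power(c, fit.inv_n)
    return float(out) if out.ndim == 0 else out
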