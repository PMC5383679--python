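"""Real-time PCR standard-curve calibration and relative quantification of
the fraction of the bacterial community carrying the trzN atrazine
chlorohydrolase gene, normalised against the 16S rRNA gene.

Concentrations are relative (in the units of the dilution series); the
community percentage corrects for the different amplicon lengths of the two
assays (16S: 161 bp, trzN: 70 bp) because mass-quantified standards carry
amplicon-length-proportional mass per copy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .growth_model import UnderDeterminedError

__all__ = [
    "StandardCurve",
    "GeneQuantResult",
    "fit_standard_curve",
    "quantify",
    "percent_community",
    "compare_groups",
    "AMPLICON_LEN_16S",
    "AMPLICON_LEN_TRZN",
]

AMPLICON_LEN_16S = 161   # bp, 16S qPCR product
AMPLICON_LEN_TRZN = 70   # bp, trzN qPCR product


@dataclass
class StandardCurve:
    """Linear calibration Ct = slope * log10(concentration) + intercept."""

    slope: float
    intercept: float
    r2: float
    efficiency: float          # %, from slope; 100% at slope -3.3219
    dilution_points: list

    @property
    def valid(self) -> bool:
        return self.slope < 0


@dataclass
class GeneQuantResult:
    sample_id: str
    group: str                 # "treated" | "control"
    trzn_conc: float
    s16_conc: float
    percent_trzn: float


def fit_standard_curve(dilutions) -> StandardCurve:
    """OLS of Ct on log10(concentration) over a dilution series.

    Amplification efficiency = (10^(-1/slope) - 1) * 100; a perfect
    doubling per cycle gives slope -3.3219 and efficiency 100%.
    """
    pts = [(float(c), float(ct)) for c, ct in dilutions]
    conc = np.array([c for c, _ in pts])
    ct = np.array([y for _, y in pts])
    if np.any(conc <= 0):
        raise ValueError("standard concentrations must be > 0")
    if len(np.unique(conc)) < 3:
        raise UnderDeterminedError("need >= 3 distinct standard concentrations")
    res = stats.linregress(np.log10(conc), ct)
    slope = float(res.slope)
    eff = (10 ** (-1.0 / slope) - 1.0) * 100.0 if slope != 0 else math.nan
    return StandardCurve(slope=slope, intercept=float(res.intercept),
                         r2=float(res.rvalue ** 2), efficiency=float(eff),
                         dilution_points=pts)


def quantify(ct, curve: StandardCurve) -> float:
    """Invert the standard curve: concentration = 10^((Ct - intercept)/slope).

    ``ct`` may be a scalar Ct or an iterable of triplicate Cts, which are
    averaged on the Ct scale before inversion.
    """
    if curve.slope == 0:
        raise ZeroDivisionError("curve slope is zero; inversion undefined")
    ct_mean = float(np.mean(ct))
    return float(10 ** ((ct_mean - curve.intercept) / curve.slope))


def percent_community(trzn_conc: float, s16_conc: float,
                      len_16s: float = AMPLICON_LEN_16S,
                      len_trzn: float = AMPLICON_LEN_TRZN) -> float:
    """Percentage of the bacterial community carrying trzN:

        trzN_conc / 16S_conc * (len_16S / len_trzN) * 100
    """
    if s16_conc <= 0:
        raise ValueError("16S concentration must be > 0")
    if trzn_conc < 0 or len_16s <= 0 or len_trzn <= 0:
        raise ValueError("concentrations and amplicon lengths must be valid")
    return trzn_conc / s16_conc * (len_16s / len_trzn) * 100.0


def compare_groups(treated, control, *, welch: bool = False):
    """Unpaired two-sided t-test of treated vs control percentages.

    Student's equal-variance test by default; ``welch=True`` drops the
    equal-variance assumption.  Returns (t, df, p).  Two identical
    zero-variance groups return p = 1 by convention.
    """
    a = np.asarray(treated, dtype=float)
    b = np.asarray(control, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise UnderDeterminedError("need >= 2 values per group")
    if np.ptp(a) == 0 and np.ptp(b) == 0 and a[0] == b[0]:
        df = len(a) + len(b) - 2
        return 0.0, float(df), 1.0
    res = stats.ttest_ind(a, b, equal_var=not welch)
    if welch:
        # Welch-Satterthwaite df
        va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
        df = (va + vb) ** 2 / (va ** 2 / (len(a) - 1) + vb ** 2 / (len(b) - 1))
    else:
        df = len(a) + len(b) - 2
    return float(res.statistic), float(df), float(res.pvalue)
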