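"""Published reference endpoints used for worked examples and cross-checks.

``reference_endpoints()`` returns the SFO DT50 / chi-square endpoint table
of a nine-soil UK microcosm study of accelerated atrazine degradation
(three applications of 6 ug/g at days 0/60/88), plus the four pH-amendment
treatments from the same study.  Eight of the nine soils adapted; GRS (the
low-pH Grange set-aside soil) did not and stayed persistent throughout.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["reference_endpoints", "ADAPTING_SOILS", "NON_ADAPTING_SOIL"]

# soil_id: (dt50_1, chi2_1, dt50_2, chi2_2, dt50_3, chi2_3); None = not run
_MAIN_PANEL = {
    "GS_2012": (21.49, 10.26, 1.76, 9.16, 1.53, 22.24),
    "GA_2012": (20.18, 11.85, 1.08, 6.73, 1.01, 16.37),
    "CS":      (32.34, 5.72, 2.93, 12.42, 0.98, 12.8),
    "CA":      (30.23, 8.2, 1.03, 10.08, 1.32, 6.9),
    "MS":      (19.81, 11.09, 1.59, 17.15, 0.9, 18.8),
    "MA":      (19.58, 7.84, 2.72, 5.57, 0.97, 12.13),
    "GRS":     (48.14, 6.58, 57.88, 5.66, 48.62, 5.06),
    "GRA":     (20.38, 10.39, 1.39, 16.73, 1.32, 18.61),
    "GA":      (37.1, 0.94, 1.13, 15.04, 1.89, 12.26),
}

_PH_PANEL = {
    "GRS_pH": (46.08, 3.81, 32.61, 9.45, None, None),
    "GRSa":   (18.25, 9.78, 1.05, 13.94, None, None),
    "GRA_pH": (18.04, 11.77, 1.54, 6.64, None, None),
    "GRAa":   (30.02, 10.83, 21.29, 7.36, None, None),
}

ADAPTING_SOILS = ("GS_2012", "GA_2012", "CS", "CA", "MS", "MA", "GRA", "GA")
NON_ADAPTING_SOIL = "GRS"


def reference_endpoints(include_ph_panel: bool = False) -> pd.DataFrame:
    """DT50 (days) and chi-square error (%) per soil and application."""
    data = dict(_MAIN_PANEL)
    if include_ph_panel:
        data.update(_PH_PANEL)
    df = pd.DataFrame.from_dict(
        data, orient="index",
        columns=["dt50_1", "chi2_1", "dt50_2", "chi2_2", "dt50_3", "chi2_3"])
    df.index.name = "soil_id"
    return df.astype(float)
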