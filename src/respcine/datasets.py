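"""Built-in reference tables.

``pediatric_chd_cohort`` is the characteristics table of a 12-subject
pediatric study population — six patients with chronic right-ventricular
volume overload (sinus venosus atrial septal defect, repaired tetralogy of
Fallot with pulmonary regurgitation, partial anomalous venous drainage) and
six controls with normal cardiac MRI — used throughout the worked examples
and the acceptance checks.  RV-EDVi values come from conventional
breath-hold volumetry at end-expiration.
"""

from __future__ import annotations

import io

import numpy as np
import pandas as pd

__all__ = [
    "pediatric_chd_cohort",
    "default_percentile_table",
    "default_calibration_table",
    "RV_OVERLOAD",
    "CONTROL",
]

RV_OVERLOAD = "rv_overload"
CONTROL = "control"

_COHORT_CSV = """\
id,age_years,sex,weight_kg,height_cm,heart_rate_bpm,resp_rate_bpm,rv_edvi,group
1,7,F,24,130,100,26,199,rv_overload
2,10,M,27,130,86,18,122,rv_overload
3,9,M,29,133,84,24,144,rv_overload
4,5,F,20,116,77,25,88,rv_overload
5,9,M,32,135,83,16,88,rv_overload
6,12,F,46,155,84,18,87,rv_overload
7,13,F,43,153,83,17,67,control
8,16,M,48,165,109,20,84,control
9,17,F,67,163,92,17,80,control
10,15,M,58,181,75,18,78,control
11,15,F,78,172,60,19,71,control
12,13,M,40,156,83,12,82,control
"""

#: Slices acquired per subject in the same study (order matches the cohort).
COHORT_SLICE_COUNTS = {
    RV_OVERLOAD: [11, 11, 11, 11, 12, 12],
    CONTROL: [10, 11, 11, 12, 12, 12],
}


def pediatric_chd_cohort() -> pd.DataFrame:
    """Demographics of the 12-subject pediatric cohort (see module docstring)."""
    return pd.read_csv(io.StringIO(_COHORT_CSV))


def default_percentile_table() -> pd.DataFrame:
    """Synthetic single-row age-related 90th-percentile RV-EDVi reference.

    A stand-in reference table (threshold 110 ml/m^2 for all pediatric ages)
    for demonstrations; clinical use requires published age-resolved
    normal values supplied as CSV (age_min, age_max, rv_edvi_p90).
    """
    return pd.DataFrame({"age_min": [0.0], "age_max": [18.0], "rv_edvi_p90": [110.0]})


def default_calibration_table(
    slope_ml_per_mm: float = 40.0, max_displacement_mm: float = 15.0, n: int = 16
) -> pd.DataFrame:
    """Synthetic displacement -> tidal-volume calibration table.

    A noise-free line with the phantom's default planted slope, standing in
    for a volunteer spirometry calibration study.
    """
    d = np.linspace(0.0, max_displacement_mm, n)
    return pd.DataFrame({"displacement_mm": d, "tidal_volume_ml": slope_ml_per_mm * d})
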