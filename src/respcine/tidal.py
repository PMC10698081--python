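"""Displacement -> tidal-volume calibration and per-class estimates.

Absolute lung volumes are not measured during a free-breathing real-time
examination, so tidal volumes are estimated through a linear calibration
between respiratory cardiac/diaphragm displacement and spirometric tidal
volume, established separately in volunteers.  The calibration converts a
subject's gated surrogate range into ml; dividing by body height yields the
height-indexed tidal volume (TVi, ml/cm) that makes subjects of different
size comparable.  The subject's typical tidal volume indexed to height
(TTVi) — the mean gated breath depth per cm — is the unit in which
respiratory-induced volume changes are reported.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateSignalError, InsufficientDataError
from .resp_signal import INSPIRATION, RespTrace

__all__ = [
    "CalibrationModel",
    "fit_calibration",
    "load_calibration_table",
    "fallback_calibration",
    "estimate_class_tidal_volume",
    "class_tidal_volumes",
    "typical_tidal_volume",
    "DEPTH_BAND_MIDPOINTS",
]

#: Midpoints of the four equal-width depth bands of the normalized range.
DEPTH_BAND_MIDPOINTS = (0.125, 0.375, 0.625, 0.875)

#: Quiet-breathing full-range tidal volume per cm body height (ml/cm) used
#: when no calibration table is supplied.
DEFAULT_TVI_FULL_RANGE = 2.7


@dataclass(frozen=True)
class CalibrationModel:
    """Linear map from displacement (mm, or normalized units) to ml."""

    slope: float
    intercept: float
    r2: float
    residual_sd: float
    n: int
    units: str = "mm"

    def predict(self, displacement: float | np.ndarray) -> float | np.ndarray:
        return self.intercept + self.slope * np.asarray(displacement, dtype=float)


def fit_calibration(
    displacements_mm: np.ndarray, tidal_volumes_ml: np.ndarray, units: str = "mm"
) -> CalibrationModel:
    """Ordinary least-squares calibration line through paired observations."""
    d = np.asarray(displacements_mm, dtype=float)
    v = np.asarray(tidal_volumes_ml, dtype=float)
    if d.size != v.size:
        raise ValueError("displacement and volume arrays differ in length")
    if d.size < 3:
        raise InsufficientDataError("calibration needs at least 3 paired observations")
    if np.var(d) <= 0:
        raise DegenerateSignalError("zero displacement variance: cannot calibrate")
    fit = stats.linregress(d, v)
    resid = v - (fit.intercept + fit.slope * d)
    return CalibrationModel(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r2=float(fit.rvalue) ** 2,
        residual_sd=float(np.std(resid, ddof=2)) if d.size > 2 else 0.0,
        n=int(d.size),
        units=units,
    )


def load_calibration_table(path: str | Path) -> CalibrationModel:
    """Fit the calibration from a CSV with columns displacement_mm,
    tidal_volume_ml."""
    table = pd.read_csv(path)
    return fit_calibration(
        table["displacement_mm"].to_numpy(), table["tidal_volume_ml"].to_numpy()
    )


def fallback_calibration(
    gated_range_mm: float, height_cm: float, tvi_full_range: float = DEFAULT_TVI_FULL_RANGE
) -> CalibrationModel:
    """Built-in quiet-breathing calibration used when no table is supplied:
    the full gated range maps to ``tvi_full_range`` ml per cm of height."""
    if gated_range_mm <= 0 or height_cm <= 0:
        raise ValueError("gated range and height must be positive")
    slope = tvi_full_range * height_cm / gated_range_mm
    return CalibrationModel(slope=slope, intercept=0.0, r2=1.0, residual_sd=0.0, n=0)


def estimate_class_tidal_volume(
    band_midpoint: float,
    model: CalibrationModel,
    gated_range_mm: float,
    height_cm: float,
) -> dict:
    """Estimated tidal volume of one depth band.

    The band midpoint of the normalized [0, 1] depth is mapped through the
    subject's gated displacement range and the calibration line to ml, then
    indexed to body height.  Negative estimates (possible with a fitted
    intercept) are clipped to zero and flagged.
    """
    if height_cm <= 0:
        raise ValueError("height must be positive")
    tv = float(model.predict(band_midpoint * gated_range_mm))
    clipped = tv < 0
    tv = max(tv, 0.0)
    return {
        "band_midpoint": band_midpoint,
        "tv_ml": tv,
        "tvi_ml_per_cm": tv / height_cm,
        "clipped": clipped,
    }


def class_tidal_volumes(
    model: CalibrationModel,
    gated_range_mm: float,
    height_cm: float,
    n_bands: int = 4,
) -> pd.DataFrame:
    """Per-depth-band tidal volume estimates (bands 1..n, shallow to deep)."""
    mids = (np.arange(n_bands) + 0.5) / n_bands
    rows = [
        {"band": b + 1, **estimate_class_tidal_volume(m, model, gated_range_mm, height_cm)}
        for b, m in enumerate(mids)
    ]
    return pd.DataFrame(rows)


def typical_tidal_volume(
    trace: RespTrace,
    model: CalibrationModel,
    gated_range_mm: float,
    height_cm: float,
) -> float:
    """TTVi (ml/cm): mean gated per-breath depth converted to ml / height.

    A breath's gated depth is the maximum normalized depth reached between
    consecutive inspiration onsets among valid frames.
    """
    if trace.n_cycles < 1:
        raise InsufficientDataError("no complete respiratory cycle in the gated trace")
    phase = trace.phase[trace.valid]
    depth = trace.normalized[trace.valid]
    onsets = np.nonzero((phase[1:] == INSPIRATION) & (phase[:-1] != INSPIRATION))[0] + 1
    peaks = [
        float(np.nanmax(depth[a:b]))
        for a, b in zip(onsets[:-1], onsets[1:])
        if b > a
    ]
    if not peaks:
        raise InsufficientDataError("no complete respiratory cycle in the gated trace")
    tv = model.predict(np.asarray(peaks) * gated_range_mm)
    return float(np.mean(tv)) / height_cm
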