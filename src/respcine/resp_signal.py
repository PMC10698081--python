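"""Image-based respiratory surrogate extraction.

The respiratory state of every real-time frame is read off the image itself:
the median signal intensity of a region of interest (ROI) placed over the
diaphragm falls as the dark lung descends into the ROI during inspiration.
A centered moving median (previous and subsequent ten frames by default)
smooths the raw trace; the sign of its first difference labels each frame
inspiration (derivative <= 0) or expiration (derivative > 0).  Robust
percentile rescaling maps the typical tidal range to [0, 1] and gates out
outlier breaths (frames beyond the percentile range, i.e. deep sighs toward
inspiratory reserve or drops toward functional residual capacity).

By convention the normalized value is a *depth*: 0 = end-expiration,
1 = deepest gated inspiration.  If an ROI is placed such that intensity
rises during inspiration, pass ``invert=True``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DegenerateSignalError, InsufficientDataError
from .series import FrameSeries

__all__ = [
    "RoiSpec",
    "RespTrace",
    "extract_roi_signal",
    "smooth_moving_median",
    "label_phases",
    "rescale_and_gate",
    "build_resp_trace",
    "load_rois",
]

INSPIRATION = "inspiration"
EXPIRATION = "expiration"

MIN_CYCLES = 5  # below this the gated trace is flagged as poorly sampled


@dataclass(frozen=True)
class RoiSpec:
    """Rectangle or polygon ROI on one slice (0-based row/col coordinates).

    A rectangle is (r0, r1, c0, c1) with half-open extents; a polygon is a
    sequence of >= 3 (row, col) vertices.
    """

    slice_index: int
    rect: tuple[int, int, int, int] | None = None
    polygon: tuple[tuple[float, float], ...] | None = None

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        if self.rect is not None:
            r0, r1, c0, c1 = self.rect
            if not (0 <= r0 < r1 <= shape[0] and 0 <= c0 < c1 <= shape[1]):
                raise ValueError(f"ROI rectangle {self.rect} outside image {shape}")
            m = np.zeros(shape, dtype=bool)
            m[r0:r1, c0:c1] = True
            return m
        if self.polygon is not None and len(self.polygon) >= 3:
            from skimage.draw import polygon as sk_polygon

            rows = [p[0] for p in self.polygon]
            cols = [p[1] for p in self.polygon]
            if min(rows) < 0 or min(cols) < 0 or max(rows) >= shape[0] or max(cols) >= shape[1]:
                raise ValueError("ROI polygon outside image bounds")
            rr, cc = sk_polygon(rows, cols, shape=shape)
            m = np.zeros(shape, dtype=bool)
            m[rr, cc] = True
            if not m.any():
                raise ValueError("ROI polygon encloses no pixels")
            return m
        raise ValueError("RoiSpec needs a rectangle or a >=3-vertex polygon")


@dataclass
class RespTrace:
    """Per-frame respiratory surrogate of one slice."""

    raw: np.ndarray
    smoothed: np.ndarray
    derivative: np.ndarray
    phase: np.ndarray          # INSPIRATION / EXPIRATION per frame
    normalized: np.ndarray     # depth in [0, 1], NaN where invalid
    valid: np.ndarray          # bool per frame
    n_cycles: int
    low_cycle_warning: bool
    acq_time_ms: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "raw": self.raw,
                "smoothed": self.smoothed,
                "derivative": self.derivative,
                "phase": self.phase,
                "normalized": self.normalized,
                "valid": self.valid,
            }
        )


def extract_roi_signal(series: FrameSeries, roi: RoiSpec) -> np.ndarray:
    """Median ROI intensity per frame."""
    mask = roi.mask(series.images.shape[1:])
    if not mask.any():
        raise ValueError("empty ROI")
    return np.median(series.images[:, mask], axis=1)


def smooth_moving_median(trace: np.ndarray, halfwidth: int = 10) -> np.ndarray:
    """Centered moving median over [i - halfwidth, i + halfwidth].

    Windows are truncated at the series edges rather than padded, so the
    output has the input's length and no invented samples.
    """
    trace = np.asarray(trace, dtype=float)
    if halfwidth < 1:
        raise ValueError("halfwidth must be >= 1")
    if trace.size <= 2 * halfwidth:
        raise InsufficientDataError(
            f"trace of {trace.size} frames is too short for halfwidth {halfwidth}"
        )
    return (
        pd.Series(trace)
        .rolling(window=2 * halfwidth + 1, center=True, min_periods=1)
        .median()
        .to_numpy()
    )


def label_phases(smoothed: np.ndarray, invert: bool = False) -> np.ndarray:
    """Respiratory phase per frame from the sign of the first difference.

    With the default polarity (intensity falls in inspiration) a
    non-positive derivative means inspiration; the first frame inherits the
    second frame's label.
    """
    smoothed = np.asarray(smoothed, dtype=float)
    if smoothed.size < 2:
        raise InsufficientDataError("need at least two frames to label phases")
    d = np.diff(smoothed)
    falling = d <= 0
    if invert:
        falling = ~falling
    labels = np.where(falling, INSPIRATION, EXPIRATION)
    return np.concatenate([labels[:1], labels])


def _count_cycles(phase: np.ndarray, valid: np.ndarray) -> int:
    """Complete respiratory cycles = intervals between successive
    inspiration onsets among valid frames."""
    p = phase[valid]
    if p.size < 2:
        return 0
    onsets = np.nonzero((p[1:] == INSPIRATION) & (p[:-1] == EXPIRATION))[0]
    return max(len(onsets) - 1, 0)


def rescale_and_gate(
    smoothed: np.ndarray,
    phase: np.ndarray,
    raw: np.ndarray | None = None,
    lower_pct: float = 5.0,
    upper_pct: float = 95.0,
    invert: bool = False,
    acq_time_ms: np.ndarray | None = None,
) -> RespTrace:
    """Map the [lower_pct, upper_pct] intensity range to a [0, 1] depth and
    gate out outlier frames.

    Frames outside the percentile range (outlier breaths reaching into
    inspiratory reserve or below functional residual capacity) are flagged
    invalid and carry NaN depth.  The trace is flagged when fewer than
    five complete cycles survive gating.
    """
    smoothed = np.asarray(smoothed, dtype=float)
    lo, hi = np.percentile(smoothed, [lower_pct, upper_pct])
    if hi - lo <= 1e-12:
        raise DegenerateSignalError("flat surrogate signal: percentile range is zero")
    valid = (smoothed >= lo) & (smoothed <= hi)
    if invert:
        normalized = (smoothed - lo) / (hi - lo)
    else:
        normalized = (hi - smoothed) / (hi - lo)
    normalized = np.where(valid, normalized, np.nan)
    d = np.diff(smoothed)
    derivative = np.concatenate([d[:1], d])
    n_cycles = _count_cycles(np.asarray(phase), valid)
    return RespTrace(
        raw=np.asarray(raw, dtype=float) if raw is not None else smoothed.copy(),
        smoothed=smoothed,
        derivative=derivative,
        phase=np.asarray(phase),
        normalized=normalized,
        valid=valid,
        n_cycles=n_cycles,
        low_cycle_warning=n_cycles < MIN_CYCLES,
        acq_time_ms=acq_time_ms,
    )


def build_resp_trace(
    series: FrameSeries,
    roi: RoiSpec,
    halfwidth: int = 10,
    lower_pct: float = 5.0,
    upper_pct: float = 95.0,
    invert: bool = False,
) -> RespTrace:
    """ROI median -> moving median -> phase labels -> rescaled gated trace."""
    raw = extract_roi_signal(series, roi)
    smoothed = smooth_moving_median(raw, halfwidth)
    phase = label_phases(smoothed, invert=invert)
    return rescale_and_gate(
        smoothed,
        phase,
        raw=raw,
        lower_pct=lower_pct,
        upper_pct=upper_pct,
        invert=invert,
        acq_time_ms=series.acq_time_ms,
    )


def load_rois(path: str | Path) -> dict[int, RoiSpec]:
    """Read ROIs from JSON: {"<slice>": {"rect": [r0, r1, c0, c1]}} or
    {"<slice>": {"polygon": [[r, c], ...]}}."""
    data = json.loads(Path(path).read_text())
    rois: dict[int, RoiSpec] = {}
    for key, spec in data.items():
        idx = int(key)
        if "rect" in spec:
            rois[idx] = RoiSpec(slice_index=idx, rect=tuple(spec["rect"]))
        elif "polygon" in spec:
            rois[idx] = RoiSpec(
                slice_index=idx, polygon=tuple(tuple(v) for v in spec["polygon"])
            )
        else:
            raise ValueError(f"ROI entry for slice {key} has neither rect nor polygon")
    return rois
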