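"""Synthetic cardiorespiratory short-axis phantom.

Generates a b-SSFP-like real-time short-axis series (one image volume per
slice, 900 frames of 33 ms by default) with fully known ground truth so every
downstream stage — respiratory surrogate extraction, binning, tidal-volume
calibration, volumetry and Frank-Starling regression — can be tested without
scanner data.

The phantom plants three couplings that the pipeline must recover:

* a breath-by-breath respiratory waveform with variable depth (truncated
  normal per-breath tidal volume), driving a diaphragm (dark lung band over
  a bright liver band) whose displacement is exactly proportional to the
  instantaneous tidal volume — the ground-truth calibration line;
* a smooth raised-cosine cardiac contraction between end-diastole and
  end-systole for both ventricles;
* a linear preload coupling: EDV = EDV0 + preload_gain * tidal_volume and
  SV = SV0 + starling_slope * (EDV - EDV0).  The RV preload gain is positive
  (RV fills in inspiration), the LV gain negative (LV fills in expiration).

Ventricular cavities are rendered as bright ellipse cross-sections whose
areas, summed over the slice stack with an elliptical base-to-apex taper,
voxelize to the requested instantaneous volume.  The whole heart additionally
translates cranio-caudally with the diaphragm, which is what makes the
overfilled-bin phase-correlation filter meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError, GeometryError, InvalidPhysiologyError
from .series import FrameSeries, write_series

__all__ = [
    "PhantomConfig",
    "GroundTruth",
    "SimulatedSubject",
    "cardiac_volume_waveform",
    "respiratory_waveform",
    "couple_starling",
    "render_frame",
    "simulate_subject",
    "default_roi",
    "write_subject",
]

# Geometry as fractions of the (square) image matrix.  At the default
# 200 px / 1.6 mm these give a 320 mm field of view with the heart in the
# upper two thirds and a lung/liver band in the lower third.
_LV_COL = 0.31
_RV_COL = 0.62
_HEART_ROW = 0.39
_RV_ASPECT = 1.7          # RV cross-section is wider than tall
_LUNG_TOP = 0.575
_DIAPHRAGM_ROW0 = 0.70    # boundary row at zero displacement
_BODY_BOTTOM = 0.925
_EDGE_SOFT_PX = 3.0       # sigmoid width of the lung/liver transition
_HEART_MOTION_FRACTION = 0.5  # heart moves at half the diaphragm excursion

_I_BACKGROUND = 0.15
_I_LUNG = 0.05
_I_LIVER = 0.75
_I_MYOCARDIUM = 0.45
_I_BLOOD = 1.0


@dataclass(frozen=True)
class PhantomConfig:
    """All knobs of one simulated subject.

    Volumes in ml, rates in bpm / breaths per min, lengths in mm, times in
    ms.  ``preload_gain_*`` is ml of end-diastolic volume per ml of tidal
    volume (positive for the RV, negative for the LV);
    ``starling_slope_*`` is the dimensionless planted dSV/dEDV ratio.
    ``calibration_slope`` is the planted ml tidal volume per mm of diaphragm
    displacement.
    """

    n_slices: int = 11
    frames_per_slice: int = 900
    frame_interval_ms: float = 33.0
    heart_rate: float = 85.0
    resp_rate: float = 18.0
    breath_depth_mean: float = 400.0
    breath_depth_cv: float = 0.25
    edv0_rv: float = 120.0
    esv0_rv: float = 50.0
    edv0_lv: float = 100.0
    esv0_lv: float = 42.0
    starling_slope_rv: float = 0.92
    starling_slope_lv: float = 1.05
    preload_gain_rv: float = 0.05
    preload_gain_lv: float = -0.02
    calibration_slope: float = 40.0
    systole_fraction: float = 0.35
    matrix: int = 200
    pixel_spacing: float = 1.6
    slice_thickness: float = 8.0
    noise_sd: float = 0.02
    rr_jitter_ms: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.edv0_rv <= self.esv0_rv or self.esv0_rv <= 0:
            raise InvalidPhysiologyError("require EDV0 > ESV0 > 0 for the RV")
        if self.edv0_lv <= self.esv0_lv or self.esv0_lv <= 0:
            raise InvalidPhysiologyError("require EDV0 > ESV0 > 0 for the LV")
        if self.frame_interval_ms <= 0:
            raise ConfigurationError("frame_interval_ms must be positive")
        if self.breath_depth_mean <= 0:
            raise ConfigurationError("breath_depth_mean must be positive")
        if not 0 < self.systole_fraction < 1:
            raise ConfigurationError("systole_fraction must lie in (0, 1)")
        if self.heart_rate <= 0 or self.resp_rate <= 0:
            raise ConfigurationError("heart_rate and resp_rate must be positive")
        if self.n_slices < 1:
            raise ConfigurationError("need at least one slice")

    @property
    def rr_interval_ms(self) -> float:
        return 60000.0 / self.heart_rate

    @property
    def breath_period_ms(self) -> float:
        return 60000.0 / self.resp_rate


@dataclass
class GroundTruth:
    """Per-frame truth table plus the planted subject-level parameters.

    ``frames`` has one row per (slice, frame) with columns: slice, frame,
    t_ms, trigger_ms, cardiac_fraction, tidal_volume_ml, resp_phase,
    displacement_mm, rv_volume_ml, lv_volume_ml, rv_edv_ml, rv_sv_ml,
    lv_edv_ml, lv_sv_ml.
    """

    frames: pd.DataFrame
    calibration_slope: float
    starling_slope_rv: float
    starling_slope_lv: float
    seed: int
    breath_depths_ml: np.ndarray = field(default_factory=lambda: np.empty(0))


@dataclass
class SimulatedSubject:
    config: PhantomConfig
    series: list[FrameSeries]
    truth: GroundTruth
    demographics: dict


def cardiac_volume_waveform(
    f: float | np.ndarray, edv: float, esv: float, systole_fraction: float = 0.35
) -> float | np.ndarray:
    """Instantaneous cavity volume at cardiac phase fraction ``f`` in [0, 1).

    Raised-cosine contraction from EDV at f=0 down to ESV at
    f=systole_fraction, then raised-cosine relaxation back towards EDV.
    """
    if edv <= esv:
        raise InvalidPhysiologyError(f"EDV ({edv}) must exceed ESV ({esv})")
    if not 0 < systole_fraction < 1:
        raise ConfigurationError("systole_fraction must lie in (0, 1)")
    f = np.asarray(f, dtype=float)
    if np.any((f < 0) | (f >= 1)):
        raise ValueError("cardiac phase fraction must lie in [0, 1)")
    w = np.where(
        f < systole_fraction,
        0.5 * (1.0 - np.cos(np.pi * f / systole_fraction)),
        0.5 * (1.0 + np.cos(np.pi * (f - systole_fraction) / (1.0 - systole_fraction))),
    )
    out = edv - (edv - esv) * w
    return float(out) if out.ndim == 0 else out


def respiratory_waveform(
    t_ms: float | np.ndarray, resp_rate: float, depth_sequence_ml: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Tidal volume (ml) and respiratory phase label at times ``t_ms``.

    Each breath is a raised-cosine excursion from 0 ml at end-expiration to
    that breath's depth at end-inspiration and back; the first half of each
    breath is inspiration, the second expiration.
    """
    if resp_rate <= 0:
        raise ConfigurationError("resp_rate must be positive")
    depths = np.asarray(depth_sequence_ml, dtype=float)
    if np.any(depths <= 0):
        raise ConfigurationError("breath depths must be positive")
    t = np.atleast_1d(np.asarray(t_ms, dtype=float))
    period = 60000.0 / resp_rate
    k = np.floor(t / period).astype(int)
    if np.any(k < 0) or np.any(k >= len(depths)):
        raise ConfigurationError("depth_sequence_ml does not cover the requested times")
    u = t / period - k
    tv = depths[k] * 0.5 * (1.0 - np.cos(2.0 * np.pi * u))
    phase = np.where(u < 0.5, "inspiration", "expiration")
    return tv, phase


def couple_starling(
    tidal_volume_ml: float,
    edv0: float,
    sv0: float,
    preload_gain: float,
    slope: float,
) -> tuple[float, float]:
    """Plant the preload coupling: returns (EDV, SV) at a given tidal volume.

    EDV = EDV0 + preload_gain * TV and SV = SV0 + slope * (EDV - EDV0), so a
    regression of SV on EDV across respiratory states recovers ``slope``.
    """
    if edv0 <= sv0 or sv0 < 0:
        raise InvalidPhysiologyError("require EDV0 > SV0 >= 0")
    edv = edv0 + preload_gain * tidal_volume_ml
    sv = sv0 + slope * (edv - edv0)
    if sv >= edv or sv < 0 or edv <= 0:
        raise ConfigurationError(
            f"coupling produced impossible volumes (EDV={edv:.1f}, SV={sv:.1f})"
        )
    return edv, sv


def _slice_weights(n_slices: int) -> np.ndarray:
    """Elliptical base-to-apex taper of cavity cross-section area."""
    z = (np.arange(n_slices) - (n_slices - 1) / 2.0) / ((n_slices + 1) / 2.0)
    return np.sqrt(np.clip(1.0 - z * z, 0.0, None))


def _cavity_axes_px(
    volume_ml: float, slice_index: int, config: PhantomConfig, aspect: float
) -> tuple[float, float]:
    """Semi-axes (row, col) in px of one cavity's cross-section in a slice."""
    w = _slice_weights(config.n_slices)
    area_mm2 = (
        volume_ml * 1000.0 * w[slice_index] / (w.sum() * config.slice_thickness)
    )
    area_px = area_mm2 / config.pixel_spacing**2
    a = np.sqrt(area_px / (np.pi * aspect))
    return a, aspect * a


def _coverage(rr: np.ndarray, cc: np.ndarray, r0: float, c0: float, a: float, b: float) -> np.ndarray:
    """Approximate per-pixel area coverage of an ellipse (anti-aliased edge)."""
    if a <= 0 or b <= 0:
        return np.zeros_like(rr)
    g = np.sqrt(((rr - r0) / a) ** 2 + ((cc - c0) / b) ** 2)
    # signed distance to the boundary, approximated along the minor axis
    d = (1.0 - g) * min(a, b)
    return np.clip(0.5 + d, 0.0, 1.0)


_GRID_CACHE: dict[int, tuple[np.ndarray, np.ndarray]] = {}


def _pixel_grid(n: int) -> tuple[np.ndarray, np.ndarray]:
    if n not in _GRID_CACHE:
        _GRID_CACHE[n] = np.meshgrid(
            np.arange(n, dtype=float), np.arange(n, dtype=float), indexing="ij"
        )
    return _GRID_CACHE[n]


def render_frame(
    rv_volume_ml: float,
    lv_volume_ml: float,
    diaphragm_displacement_mm: float,
    config: PhantomConfig,
    slice_index: int | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Render one short-axis frame.

    ``slice_index`` defaults to the mid-ventricular slice.  Noise is added
    only when ``rng`` is given and ``config.noise_sd`` > 0.
    """
    if rv_volume_ml < 0 or lv_volume_ml < 0:
        raise InvalidPhysiologyError("cavity volumes must be non-negative")
    n = config.matrix
    if slice_index is None:
        slice_index = config.n_slices // 2
    rr, cc = _pixel_grid(n)

    img = np.full((n, n), _I_BACKGROUND, dtype=np.float64)

    # Lung (dark) over liver (bright); the boundary descends with diaphragm
    # displacement through a smooth sigmoid edge so that the ROI median is a
    # continuous monotone surrogate of displacement.
    disp_px = diaphragm_displacement_mm / config.pixel_spacing
    boundary = _DIAPHRAGM_ROW0 * n + disp_px
    lung_top = _LUNG_TOP * n
    body_bottom = _BODY_BOTTOM * n
    band = (rr >= lung_top) & (rr < body_bottom)
    profile = _I_LUNG + (_I_LIVER - _I_LUNG) / (
        1.0 + np.exp(-(rr - boundary) / _EDGE_SOFT_PX)
    )
    img[band] = profile[band]

    # Heart: two bright cavities with a thin mid-gray myocardial rim, the
    # whole heart riding cranio-caudally with the diaphragm.
    heart_row = _HEART_ROW * n + _HEART_MOTION_FRACTION * disp_px
    lv_a, lv_b = _cavity_axes_px(lv_volume_ml, slice_index, config, aspect=1.0)
    rv_a, rv_b = _cavity_axes_px(rv_volume_ml, slice_index, config, aspect=_RV_ASPECT)
    rim = 2.5
    for c_frac, a, b in ((_LV_COL, lv_a, lv_b), (_RV_COL, rv_a, rv_b)):
        c0 = c_frac * n
        if (
            heart_row - a - rim < 2
            or heart_row + a + rim > lung_top - 2
            or c0 - b - rim < 2
            or c0 + b + rim > n - 2
        ):
            raise GeometryError(
                "cavity cross-section overflows the field of view; reduce volumes "
                "or enlarge the matrix"
            )
        if a <= 0:
            continue
        cav = _coverage(rr, cc, heart_row, c0, a, b)
        ring = _coverage(rr, cc, heart_row, c0, a + rim, b + rim)
        img = img * (1 - ring) + _I_MYOCARDIUM * ring
        img = img * (1 - cav) + _I_BLOOD * cav

    if rng is not None and config.noise_sd > 0:
        img = img + rng.normal(0.0, config.noise_sd, size=img.shape)
    return img.astype(np.float32)


def default_roi(config: PhantomConfig) -> tuple[int, int, int, int]:
    """Diaphragm ROI rectangle (r0, r1, c0, c1), half-open, straddling the
    lung/liver boundary over its full excursion range."""
    n = config.matrix
    return (int(0.68 * n), int(0.78 * n), int(0.20 * n), int(0.80 * n))


def _draw_breath_depths(rng: np.random.Generator, n: int, mean: float, cv: float) -> np.ndarray:
    """Truncated-normal per-breath depths (truncated to [0.2, 2] x mean)."""
    sd = cv * mean
    depths = np.empty(n)
    for i in range(n):
        d = rng.normal(mean, sd)
        while not (0.2 * mean <= d <= 2.0 * mean):
            d = rng.normal(mean, sd)
        depths[i] = d
    return depths


def simulate_subject(
    config: PhantomConfig,
    demographics: dict | None = None,
    render: bool = True,
) -> SimulatedSubject:
    """Simulate one subject's full multi-slice real-time examination.

    Slices are acquired back to back; respiration and the cardiac cycle run
    continuously across slice boundaries.  With ``render=False`` only the
    metadata and ground truth are produced (images empty), which is used by
    the fast signal-level Monte-Carlo replicates.
    """
    rng = np.random.default_rng(config.seed)
    n_total = config.n_slices * config.frames_per_slice
    slice_duration = config.frames_per_slice * config.frame_interval_ms
    total_ms = config.n_slices * slice_duration
    n_breaths = int(np.ceil(total_ms / config.breath_period_ms)) + 2
    depths = _draw_breath_depths(
        rng, n_breaths, config.breath_depth_mean, config.breath_depth_cv
    )

    # ECG R waves: fixed RR by default, optional per-beat jitter.
    rr = config.rr_interval_ms
    if config.rr_jitter_ms > 0:
        n_beats = int(np.ceil(total_ms / rr)) + 2
        intervals = rr + rng.normal(0.0, config.rr_jitter_ms, n_beats)
        intervals = np.clip(intervals, 0.5 * rr, 1.5 * rr)
        beat_times = np.concatenate([[0.0], np.cumsum(intervals)])
    else:
        beat_times = None

    rows = []
    series_list = []
    for s in range(config.n_slices):
        t = s * slice_duration + np.arange(config.frames_per_slice) * config.frame_interval_ms
        tv, phase = respiratory_waveform(t, config.resp_rate, depths)
        disp = tv / config.calibration_slope
        local_rr = None
        if beat_times is None:
            trig = np.mod(t, rr)
            frac = trig / rr
        else:
            idx = np.searchsorted(beat_times, t, side="right") - 1
            local_rr = beat_times[idx + 1] - beat_times[idx]
            trig = np.minimum(t - beat_times[idx], local_rr * (1.0 - 1e-9))
            frac = np.clip(trig / local_rr, 0.0, 1.0 - 1e-9)

        # Validate the coupling at the tidal-volume extremes, then vectorize:
        # V(f) = EDV - SV * w(f) since ESV = EDV - SV.
        for tv_extreme in (float(tv.min()), float(tv.max())):
            couple_starling(tv_extreme, config.edv0_rv, config.edv0_rv - config.esv0_rv,
                            config.preload_gain_rv, config.starling_slope_rv)
            couple_starling(tv_extreme, config.edv0_lv, config.edv0_lv - config.esv0_lv,
                            config.preload_gain_lv, config.starling_slope_lv)
        rv_edv = config.edv0_rv + config.preload_gain_rv * tv
        rv_sv = (config.edv0_rv - config.esv0_rv) + config.starling_slope_rv * (rv_edv - config.edv0_rv)
        lv_edv = config.edv0_lv + config.preload_gain_lv * tv
        lv_sv = (config.edv0_lv - config.esv0_lv) + config.starling_slope_lv * (lv_edv - config.edv0_lv)
        sf = config.systole_fraction
        w = np.where(
            frac < sf,
            0.5 * (1.0 - np.cos(np.pi * frac / sf)),
            0.5 * (1.0 + np.cos(np.pi * (frac - sf) / (1.0 - sf))),
        )
        rv_vol = rv_edv - rv_sv * w
        lv_vol = lv_edv - lv_sv * w

        images = np.zeros((config.frames_per_slice, 1, 1), dtype=np.float32)
        if render:
            images = np.empty(
                (config.frames_per_slice, config.matrix, config.matrix), dtype=np.float32
            )
            for i in range(config.frames_per_slice):
                images[i] = render_frame(rv_vol[i], lv_vol[i], disp[i], config, s, rng=rng)
        for i in range(config.frames_per_slice):
            rows.append(
                (s, i, t[i], trig[i], frac[i], tv[i], phase[i], disp[i],
                 rv_vol[i], lv_vol[i], rv_edv[i], rv_sv[i], lv_edv[i], lv_sv[i])
            )
        series_list.append(
            FrameSeries(
                images=images,
                acq_time_ms=t,
                trigger_time_ms=trig,
                slice_index=s,
                slice_thickness_mm=config.slice_thickness,
                pixel_spacing_mm=config.pixel_spacing,
                rr_interval_ms=rr,
                extra={} if local_rr is None else {"rr_local_ms": local_rr},
            )
        )

    frames = pd.DataFrame(
        rows,
        columns=[
            "slice", "frame", "t_ms", "trigger_ms", "cardiac_fraction",
            "tidal_volume_ml", "resp_phase", "displacement_mm",
            "rv_volume_ml", "lv_volume_ml", "rv_edv_ml", "rv_sv_ml",
            "lv_edv_ml", "lv_sv_ml",
        ],
    )
    truth = GroundTruth(
        frames=frames,
        calibration_slope=config.calibration_slope,
        starling_slope_rv=config.starling_slope_rv,
        starling_slope_lv=config.starling_slope_lv,
        seed=config.seed,
        breath_depths_ml=depths,
    )
    if demographics is None:
        demographics = {
            "id": "phantom",
            "age_years": 12,
            "sex": "F",
            "weight_kg": 40.0,
            "height_cm": 150.0,
            "group": "control",
        }
    return SimulatedSubject(config=config, series=series_list, truth=truth,
                            demographics=dict(demographics))


def write_subject(subject: SimulatedSubject, out_dir: str | Path) -> Path:
    """Write a simulated subject: NIfTI+sidecar per slice, truth and
    demographics as CSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for series in subject.series:
        write_series(series, out_dir)
    subject.truth.frames.to_csv(out_dir / "ground_truth.csv", index=False)
    pd.DataFrame([subject.demographics]).to_csv(out_dir / "demographics.csv", index=False)
    scalars = {
        "calibration_slope": subject.truth.calibration_slope,
        "starling_slope_rv": subject.truth.starling_slope_rv,
        "starling_slope_lv": subject.truth.starling_slope_lv,
        "seed": subject.truth.seed,
    }
    pd.Series(scalars).to_csv(out_dir / "ground_truth_scalars.csv", header=False)
    return out_dir


def reduced_scale(config: PhantomConfig, n_slices: int = 6, frames: int = 600) -> PhantomConfig:
    """Desk-scale variant of a configuration (fewer slices, shorter series)."""
    return replace(config, n_slices=n_slices, frames_per_slice=frames)
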