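"""Respiratory x cardiac binning of real-time frames.

Every valid frame of a slice is assigned to one of 8 respiratory classes
(four tidal-volume depth bands, separately for inspiration and expiration)
crossed with 25 cardiac phases derived from the frame's ECG trigger time.
Overfilled bins are resolved in two steps mirroring retrospective
self-gating practice:

1. subpixel phase-correlation registration between all candidate frames;
   candidates whose mean shift magnitude against the others deviates from
   the group mean by more than one group SD are excluded (misregistered
   outliers);
2. among the survivors, the frame whose normalized respiratory depth is
   closest to the class's median depth is kept as the bin representative.

Empty bins are filled from the nearest respiratory class at the same
cardiac phase — preferring neighbors on the same side of the
inspiration/expiration boundary — but stay flagged BORROWED and are
excluded from quantitative analysis downstream.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import DegenerateSignalError, InsufficientDataError, MetadataError
from .resp_signal import EXPIRATION, INSPIRATION, RespTrace
from .series import FrameSeries

__all__ = [
    "FILLED",
    "BORROWED",
    "EMPTY",
    "BinEntry",
    "BinGrid",
    "cardiac_phase_index",
    "respiratory_class_index",
    "subpixel_shift",
    "select_bin_representative",
    "assemble_bin_grid",
    "bin_fill_stats",
    "total_bin_count",
    "fill_percentage",
]

FILLED = "filled"
BORROWED = "borrowed"
EMPTY = "empty"

N_CARDIAC_PHASES = 25
N_DEPTH_BANDS = 4


def cardiac_phase_index(trigger_time_ms: float, rr_interval_ms: float, n_phases: int = 25) -> int:
    """1-based cardiac phase from the trigger time (time after the R wave)."""
    if rr_interval_ms <= 0:
        raise MetadataError("rr_interval_ms must be positive")
    if not 0 <= trigger_time_ms < rr_interval_ms:
        raise MetadataError(
            f"trigger time {trigger_time_ms} ms outside [0, RR={rr_interval_ms} ms)"
        )
    return min(int(math.floor(trigger_time_ms / (rr_interval_ms / n_phases))), n_phases - 1) + 1


def respiratory_class_index(normalized: float, phase: str, n_bands: int = 4) -> int:
    """1-based respiratory class: depth band for inspiration (1..4), band + 4
    for expiration (5..8).  The top band is closed so depth 1.0 maps into it."""
    if not np.isfinite(normalized) or not 0.0 <= normalized <= 1.0:
        raise ValueError(f"normalized depth {normalized} invalid (gated out?)")
    band = min(int(math.floor(normalized * n_bands)) + 1, n_bands)
    if phase == INSPIRATION:
        return band
    if phase == EXPIRATION:
        return band + n_bands
    raise ValueError(f"unknown respiratory phase {phase!r}")


def class_respiratory_phase(class_index: int, n_bands: int = 4) -> str:
    return INSPIRATION if class_index <= n_bands else EXPIRATION


def subpixel_shift(
    image_a: np.ndarray, image_b: np.ndarray, upsample_factor: int = 100
) -> tuple[float, float]:
    """Translation (dy, dx) of ``image_b`` relative to ``image_a``.

    FFT phase correlation with subpixel refinement; the shift of an image
    against itself is (0, 0), and ``subpixel_shift(a, roll(a, s))`` returns
    ``s``.
    """
    from skimage.registration import phase_cross_correlation

    a = np.asarray(image_a, dtype=float)
    b = np.asarray(image_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"image shapes differ: {a.shape} vs {b.shape}")
    if not np.any(a) or not np.any(b):
        raise DegenerateSignalError("cannot register an all-zero image")
    shift, _, _ = phase_cross_correlation(a, b, upsample_factor=upsample_factor)
    return (-float(shift[0]), -float(shift[1]))


@dataclass
class BinEntry:
    status: str                      # FILLED / BORROWED / EMPTY
    frame_index: int | None = None   # representative frame within the slice
    borrowed_from: int | None = None  # source respiratory class if BORROWED
    n_candidates: int = 0
    n_filtered_out: int = 0
    candidate_frames: list[int] = field(default_factory=list)


@dataclass
class BinGrid:
    """25 x 8 bin table of one slice (1-based indices in reports)."""

    slice_index: int
    n_phases: int = N_CARDIAC_PHASES
    n_classes: int = 2 * N_DEPTH_BANDS
    entries: dict[tuple[int, int], BinEntry] = field(default_factory=dict)
    class_median_depth: dict[int, float] = field(default_factory=dict)

    def entry(self, phase: int, resp_class: int) -> BinEntry:
        return self.entries[(phase, resp_class)]

    @property
    def total_bins(self) -> int:
        return self.n_phases * self.n_classes

    def count(self, status: str) -> int:
        return sum(1 for e in self.entries.values() if e.status == status)

    def to_json(self, path: str | Path | None = None) -> str:
        table = {
            f"{p},{c}": {
                "status": e.status,
                "frame": e.frame_index,
                "borrowed_from": e.borrowed_from,
                "n_candidates": e.n_candidates,
                "n_filtered_out": e.n_filtered_out,
            }
            for (p, c), e in sorted(self.entries.items())
        }
        payload = json.dumps(
            {
                "slice_index": self.slice_index,
                "n_phases": self.n_phases,
                "n_classes": self.n_classes,
                "index_convention": "1-based (phase, class); classes 1-4 inspiration, 5-8 expiration",
                "bins": table,
            },
            indent=1,
        )
        if path is not None:
            Path(path).write_text(payload)
        return payload


def select_bin_representative(
    frame_indices: list[int],
    depths: list[float],
    class_median_depth: float,
    acq_times: list[float] | None = None,
    images: np.ndarray | list[np.ndarray] | None = None,
    upsample_factor: int = 20,
) -> tuple[int, list[int]]:
    """Pick one frame for an overfilled bin; returns (chosen, excluded).

    With images available, each candidate's mean pairwise registration shift
    magnitude against the other candidates is computed; candidates deviating
    from the group mean by more than one group SD are excluded.  If that
    removes every candidate the unfiltered set is used.  The survivor whose
    depth is closest to the class median depth wins; ties go to the earliest
    acquisition time.
    """
    if len(frame_indices) == 0:
        raise InsufficientDataError("no candidates")
    if len(frame_indices) == 1:
        return frame_indices[0], []
    k = len(frame_indices)
    excluded: list[int] = []
    survivors = list(range(k))
    if images is not None and k > 2:
        mags = np.zeros((k, k))
        for i in range(k):
            for j in range(i + 1, k):
                dy, dx = subpixel_shift(images[i], images[j], upsample_factor)
                mags[i, j] = mags[j, i] = math.hypot(dy, dx)
        mean_shift = mags.sum(axis=1) / (k - 1)
        mu = mean_shift.mean()
        sd = mean_shift.std()
        keep = np.abs(mean_shift - mu) <= sd
        if keep.any():
            survivors = [i for i in range(k) if keep[i]]
            excluded = [frame_indices[i] for i in range(k) if not keep[i]]
    if acq_times is None:
        acq_times = list(frame_indices)  # frame order stands in for time

    def sort_key(i: int) -> tuple[float, float]:
        return (abs(depths[i] - class_median_depth), acq_times[i])

    chosen = min(survivors, key=sort_key)
    return frame_indices[chosen], excluded


def assemble_bin_grid(
    series: FrameSeries,
    trace: RespTrace,
    rr_interval_ms: float | None = None,
    n_phases: int = N_CARDIAC_PHASES,
    n_bands: int = N_DEPTH_BANDS,
    filter_images: bool = True,
    upsample_factor: int = 20,
) -> BinGrid:
    """Bin every valid frame of one slice and resolve each bin.

    ``filter_images=False`` skips the phase-correlation outlier filter
    (used on signal-only simulations without rendered images).
    """
    if rr_interval_ms is None:
        rr_interval_ms = series.rr_interval_ms
    if rr_interval_ms is None:
        raise MetadataError("rr_interval_ms required (none in series metadata)")
    n_classes = 2 * n_bands
    grid = BinGrid(slice_index=series.slice_index, n_phases=n_phases, n_classes=n_classes)

    rr_local = series.rr_local_ms
    members: dict[tuple[int, int], list[int]] = {}
    frame_class = np.full(series.n_frames, -1)
    for i in range(series.n_frames):
        if not trace.valid[i]:
            continue
        rr_i = float(rr_local[i]) if rr_local is not None else rr_interval_ms
        p = cardiac_phase_index(series.trigger_time_ms[i], rr_i, n_phases)
        c = respiratory_class_index(trace.normalized[i], trace.phase[i], n_bands)
        members.setdefault((p, c), []).append(i)
        frame_class[i] = c

    for c in range(1, n_classes + 1):
        in_class = trace.normalized[frame_class == c]
        grid.class_median_depth[c] = float(np.median(in_class)) if in_class.size else float("nan")

    has_images = filter_images and series.images.shape[1] > 1
    for p in range(1, n_phases + 1):
        for c in range(1, n_classes + 1):
            idx = members.get((p, c), [])
            if not idx:
                grid.entries[(p, c)] = BinEntry(status=EMPTY)
                continue
            chosen, excluded = select_bin_representative(
                idx,
                [trace.normalized[i] for i in idx],
                grid.class_median_depth[c],
                acq_times=[series.acq_time_ms[i] for i in idx],
                images=series.images[idx] if has_images else None,
                upsample_factor=upsample_factor,
            )
            grid.entries[(p, c)] = BinEntry(
                status=FILLED,
                frame_index=chosen,
                n_candidates=len(idx),
                n_filtered_out=len(excluded),
                candidate_frames=list(idx),
            )

    _borrow_empty_bins(grid, n_bands)
    return grid


def _neighbor_order(c: int, n_bands: int) -> list[int]:
    """Respiratory classes to borrow from, nearest first, same
    inspiration/expiration side before crossing the boundary."""
    n_classes = 2 * n_bands
    same_side = (
        range(1, n_bands + 1) if c <= n_bands else range(n_bands + 1, n_classes + 1)
    )
    other_side = (
        range(n_bands + 1, n_classes + 1) if c <= n_bands else range(1, n_bands + 1)
    )
    order = sorted((x for x in same_side if x != c), key=lambda x: (abs(x - c), x))
    order += sorted(other_side, key=lambda x: (abs(x - c), x))
    return order


def _borrow_empty_bins(grid: BinGrid, n_bands: int) -> None:
    for p in range(1, grid.n_phases + 1):
        filled = {
            c
            for c in range(1, grid.n_classes + 1)
            if grid.entries[(p, c)].status == FILLED
        }
        for c in range(1, grid.n_classes + 1):
            e = grid.entries[(p, c)]
            if e.status != EMPTY:
                continue
            if not filled:
                raise InsufficientDataError(
                    f"cardiac phase {p} is empty across all respiratory classes "
                    f"in slice {grid.slice_index}"
                )
            source = next(x for x in _neighbor_order(c, n_bands) if x in filled)
            grid.entries[(p, c)] = BinEntry(
                status=BORROWED,
                frame_index=grid.entries[(p, source)].frame_index,
                borrowed_from=source,
            )


def total_bin_count(slice_counts: list[int], n_phases: int = 25, n_classes: int = 8) -> int:
    """Total bins for a set of subjects given their slice counts."""
    return sum(slice_counts) * n_phases * n_classes


def fill_percentage(filled: int, total: int) -> float:
    """Filled-bin percentage to one decimal (as reported in bin accounting)."""
    if total == 0:
        return 0.0
    return round(100.0 * filled / total, 1)


def bin_fill_stats(
    grids: list[BinGrid],
    ed_phase: int | None = None,
    es_phase: int | None = None,
) -> dict:
    """Fill accounting across slices (optionally per ED/ES cardiac phase)."""
    total = sum(g.total_bins for g in grids)
    filled = sum(g.count(FILLED) for g in grids)
    borrowed = sum(g.count(BORROWED) for g in grids)
    stats = {
        "n_slices": len(grids),
        "total_bins": total,
        "filled": filled,
        "filled_pct": fill_percentage(filled, total),
        "borrowed": borrowed,
        "index_convention": "1-based bin indices",
    }
    for name, phase in (("ed", ed_phase), ("es", es_phase)):
        if phase is None:
            continue
        n = sum(1 for g in grids for c in range(1, g.n_classes + 1))
        unfilled = sum(
            1
            for g in grids
            for c in range(1, g.n_classes + 1)
            if g.entries[(phase, c)].status != FILLED
        )
        stats[f"{name}_phase"] = phase
        stats[f"{name}_unfilled"] = unfilled
        stats[f"{name}_bins"] = n
    return stats
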