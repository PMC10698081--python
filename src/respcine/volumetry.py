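"""Per-respiratory-class ventricular volumetry from binned stacks.

Each respiratory class of a subject yields a conventional-looking 25-phase
short-axis cine stack.  Cavity masks (threshold segmentation on phantom
images, or externally produced label masks on real data) are summed slice
by slice — disc summation at 8 mm slice thickness with no gap — to per-phase
cavity volumes.  End-diastole and end-systole are the phases of maximal and
minimal volume per ventricle, selected among the phases whose bins are all
genuinely filled — bins borrowed from a neighboring respiratory class never
contribute to a reported volume; stroke volume, ejection fraction and
BSA-indexed variants follow.  A class with fewer than two fully filled
phases yields no entry.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InsufficientDataError, InvalidPhysiologyError

__all__ = [
    "SubjectRecord",
    "dubois_bsa",
    "segment_phantom_frame",
    "stack_volume",
    "class_volume_set",
    "classify_rv_overload",
    "LV_LABEL",
    "RV_LABEL",
]

LV_LABEL = 1
RV_LABEL = 2


@dataclass(frozen=True)
class SubjectRecord:
    """Demographics of one subject."""

    id: str
    age_years: float
    sex: str
    weight_kg: float
    height_cm: float
    group: str = "control"
    heart_rate_bpm: float | None = None
    resp_rate_bpm: float | None = None

    def __post_init__(self) -> None:
        if self.weight_kg <= 0 or self.height_cm <= 0:
            raise ValueError("weight and height must be positive")

    @property
    def bsa_m2(self) -> float:
        return dubois_bsa(self.weight_kg, self.height_cm)


def dubois_bsa(weight_kg: float, height_cm: float) -> float:
    """DuBois body surface area: 0.007184 * weight^0.425 * height^0.725 (m^2)."""
    if weight_kg <= 0 or height_cm <= 0:
        raise ValueError("weight and height must be positive")
    return 0.007184 * weight_kg**0.425 * height_cm**0.725


def segment_phantom_frame(
    image: np.ndarray,
    threshold: float = 0.725,
    lv_column_frac: float = 0.31,
    rv_column_frac: float = 0.62,
    min_area_px: int = 10,
    cardiac_row_limit_frac: float = 0.575,
) -> np.ndarray:
    """Label mask {0 background, 1 LV cavity, 2 RV cavity} of a phantom frame.

    Bright blood-pool pixels above ``threshold`` (the midpoint between the
    myocardial rim and blood intensities, so the anti-aliased cavity edge is
    cut at half coverage and the area is unbiased) are grouped into
    connected components; each sufficiently large component is assigned to
    the ventricle whose known cavity column its centroid is closest to.
    Rows below ``cardiac_row_limit_frac`` (the lung/liver band) are ignored.
    Deterministic for a fixed frame and thresholds.
    """
    from skimage import measure

    img = np.asarray(image, dtype=float)
    binary = img > threshold
    binary[int(cardiac_row_limit_frac * img.shape[0]):, :] = False
    labels = measure.label(binary, connectivity=2)
    out = np.zeros_like(labels, dtype=np.uint8)
    n_cols = img.shape[1]
    centers = {LV_LABEL: lv_column_frac * n_cols, RV_LABEL: rv_column_frac * n_cols}
    found = False
    for region in measure.regionprops(labels):
        if region.area < min_area_px:
            continue
        col = region.centroid[1]
        label = min(centers, key=lambda k: abs(centers[k] - col))
        out[labels == region.label] = label
        found = True
    if not found:
        raise InsufficientDataError("no cavity component found above threshold")
    return out


def stack_volume(
    masks: list[np.ndarray] | np.ndarray,
    pixel_spacing_mm: float,
    slice_thickness_mm: float = 8.0,
    label: int = 1,
) -> float:
    """Disc-summation volume (ml) of one labeled cavity across the stack."""
    masks = [np.asarray(m) for m in masks]
    shapes = {m.shape for m in masks}
    if len(shapes) > 1:
        raise ValueError(f"inconsistent mask shapes: {shapes}")
    pixel_area = pixel_spacing_mm**2
    count = sum(int(np.count_nonzero(m == label)) for m in masks)
    return count * pixel_area * slice_thickness_mm / 1000.0


def _cyclic_distance(p: int, ref: int, n: int) -> int:
    d = abs(p - ref)
    return min(d, n - d)


def class_volume_set(
    phase_volumes: dict[str, np.ndarray],
    phase_borrowed: np.ndarray,
    record: SubjectRecord,
    resp_class: int,
    ref_phases: dict[str, tuple[int, int]] | None = None,
    neighborhood: int = 1,
) -> list[dict]:
    """Derive the per-class volume entry for both ventricles.

    Parameters
    ----------
    phase_volumes:
        {"RV": array of 25 per-phase volumes (ml), "LV": ...}.
    phase_borrowed:
        Boolean per phase: did any contributing bin borrow its frame.
    ref_phases:
        Optional per-ventricle reference (ED phase, ES phase), 1-based,
        typically located on the subject's best-covered respiratory class.
        When given, the class must have a genuinely filled phase within
        ``neighborhood`` (cyclic) of each reference — otherwise its volume
        extremes cannot be trusted to bracket end-diastole/end-systole and
        no entry is produced.
    """
    phase_borrowed = np.asarray(phase_borrowed, dtype=bool)
    entries = []
    for ventricle, vols in phase_volumes.items():
        vols = np.asarray(vols, dtype=float)
        if vols.size < 2:
            raise InsufficientDataError("need >= 2 cardiac phases for ED/ES selection")
        usable = ~phase_borrowed
        if usable.sum() < 2:
            raise InsufficientDataError(
                f"fewer than 2 fully filled cardiac phases in class {resp_class}"
            )
        if ref_phases is not None and ventricle in ref_phases:
            n = vols.size
            clean = [p for p in range(1, n + 1) if usable[p - 1]]
            for ref in ref_phases[ventricle]:
                if not any(_cyclic_distance(p, ref, n) <= neighborhood for p in clean):
                    raise InsufficientDataError(
                        f"class {resp_class}: no filled phase near cardiac phase {ref}"
                    )
        # Borrowed bins never feed a reported volume: ED/ES are selected
        # among the phases whose bins are all genuinely filled.
        masked = np.where(usable, vols, np.nan)
        ed_phase = int(np.nanargmax(masked))
        es_phase = int(np.nanargmin(masked))
        edv = float(vols[ed_phase])
        esv = float(vols[es_phase])
        if edv <= esv:
            raise InvalidPhysiologyError("degenerate cine: EDV <= ESV")
        sv = edv - esv
        ef = 100.0 * sv / edv
        bsa = record.bsa_m2
        entries.append(
            {
                "subject": record.id,
                "ventricle": ventricle,
                "resp_class": resp_class,
                "ed_phase": ed_phase + 1,
                "es_phase": es_phase + 1,
                "edv_ml": edv,
                "esv_ml": esv,
                "sv_ml": sv,
                "ef_pct": ef,
                "edvi": edv / bsa,
                "esvi": esv / bsa,
                "svi": sv / bsa,
                "excluded": bool(phase_borrowed[ed_phase] or phase_borrowed[es_phase]),
            }
        )
    return entries


def volume_sets_to_frame(entries: list[dict]) -> pd.DataFrame:
    return pd.DataFrame(entries)


def classify_rv_overload(
    rv_edvi: float, age_years: float, percentile_table: pd.DataFrame
) -> bool:
    """True iff RV-EDVi lies strictly above the age's 90th-percentile
    reference value.

    ``percentile_table`` columns: age_min, age_max (inclusive), rv_edvi_p90.
    """
    t = percentile_table
    rows = t[(t["age_min"] <= age_years) & (age_years <= t["age_max"])]
    if rows.empty:
        raise ValueError(f"age {age_years} not covered by the percentile table")
    threshold = float(rows.iloc[0]["rv_edvi_p90"])
    return rv_edvi > threshold
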