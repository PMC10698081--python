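"""Frame-series container and on-disk round trip.

A :class:`FrameSeries` holds the ordered 2-D frames of one short-axis slice
together with the per-frame timing metadata the binning stage needs: the
acquisition time (clock time of the frame within the examination) and the
trigger time (time elapsed since the preceding ECG R wave, as written by the
scanner into the frame metadata).

On disk a slice is a NIfTI image volume of shape (x, y, frame) plus a JSON
sidecar carrying the per-frame timing vectors, mirroring the common
research-PACS export convention.  A DICOM directory with per-frame
``TriggerTime`` attributes is accepted as an alternative input.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import MetadataError

SIDECAR_SUFFIX = ".json"


@dataclass
class FrameSeries:
    """Ordered frames of one slice with acquisition/trigger timing.

    Attributes
    ----------
    images:
        Array of shape (n_frames, n_rows, n_cols), float32 intensities.
    acq_time_ms:
        Acquisition time of each frame in ms from the start of the exam.
    trigger_time_ms:
        Time after the preceding ECG R wave for each frame, in ms.
    """

    images: np.ndarray
    acq_time_ms: np.ndarray
    trigger_time_ms: np.ndarray
    slice_index: int
    slice_thickness_mm: float = 8.0
    pixel_spacing_mm: float = 1.6
    rr_interval_ms: float | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.images = np.asarray(self.images, dtype=np.float32)
        self.acq_time_ms = np.asarray(self.acq_time_ms, dtype=float)
        self.trigger_time_ms = np.asarray(self.trigger_time_ms, dtype=float)
        n = self.images.shape[0]
        if self.acq_time_ms.shape != (n,) or self.trigger_time_ms.shape != (n,):
            raise MetadataError(
                f"timing metadata length does not match {n} frames"
            )
        if n == 0:
            raise MetadataError("empty frame series")
        self.sort_by_acquisition_time()
        if np.any(np.diff(self.acq_time_ms) <= 0):
            raise MetadataError("acquisition times are not strictly increasing")
        if np.any(self.trigger_time_ms < 0):
            raise MetadataError("negative trigger_time_ms")
        rr_local = self.rr_local_ms
        if rr_local is not None:
            if np.any(self.trigger_time_ms >= rr_local):
                raise MetadataError("trigger_time_ms >= per-beat RR interval")
        elif self.rr_interval_ms is not None and np.any(
            self.trigger_time_ms >= self.rr_interval_ms
        ):
            raise MetadataError("trigger_time_ms >= rr_interval_ms")

    @property
    def rr_local_ms(self) -> np.ndarray | None:
        """Per-frame RR interval of the beat each frame fell in, if known."""
        rr = self.extra.get("rr_local_ms")
        return None if rr is None else np.asarray(rr, dtype=float)

    @property
    def n_frames(self) -> int:
        return self.images.shape[0]

    def sort_by_acquisition_time(self) -> None:
        order = np.argsort(self.acq_time_ms, kind="stable")
        if not np.array_equal(order, np.arange(len(order))):
            self.images = self.images[order]
            self.acq_time_ms = self.acq_time_ms[order]
            self.trigger_time_ms = self.trigger_time_ms[order]
            n = len(order)
            for key, value in list(self.extra.items()):
                arr = np.asarray(value)
                if arr.ndim >= 1 and arr.shape[0] == n:
                    self.extra[key] = arr[order]


def write_series(series: FrameSeries, out_dir: str | Path) -> Path:
    """Write one slice as NIfTI (x, y, frame) plus a JSON sidecar."""
    import nibabel as nib

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stem = f"slice{series.slice_index:02d}"
    # NIfTI convention: spatial axes first, frame axis last.
    data = np.transpose(series.images, (1, 2, 0)).astype(np.float32)
    affine = np.diag(
        [series.pixel_spacing_mm, series.pixel_spacing_mm, series.slice_thickness_mm, 1.0]
    )
    nii_path = out_dir / f"{stem}.nii.gz"
    nib.save(nib.Nifti1Image(data, affine), str(nii_path))
    sidecar = {
        "slice_index": series.slice_index,
        "slice_thickness_mm": series.slice_thickness_mm,
        "pixel_spacing_mm": series.pixel_spacing_mm,
        "rr_interval_ms": series.rr_interval_ms,
        "acquisition_time_ms": series.acq_time_ms.tolist(),
        "trigger_time_ms": series.trigger_time_ms.tolist(),
    }
    if series.rr_local_ms is not None:
        sidecar["rr_local_ms"] = series.rr_local_ms.tolist()
    (out_dir / f"{stem}{SIDECAR_SUFFIX}").write_text(json.dumps(sidecar))
    return nii_path


def read_series_file(nii_path: str | Path) -> FrameSeries:
    """Read one NIfTI+sidecar pair back into a :class:`FrameSeries`."""
    import nibabel as nib

    nii_path = Path(nii_path)
    name = nii_path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            stem = name[: -len(suffix)]
            break
    else:
        raise MetadataError(f"not a NIfTI file: {nii_path}")
    sidecar_path = nii_path.with_name(stem + SIDECAR_SUFFIX)
    if not sidecar_path.exists():
        raise MetadataError(f"missing JSON sidecar for {nii_path}")
    meta = json.loads(sidecar_path.read_text())
    for key in ("acquisition_time_ms", "trigger_time_ms"):
        if key not in meta:
            raise MetadataError(f"sidecar {sidecar_path} lacks required field '{key}'")
    data = np.asanyarray(nib.load(str(nii_path)).dataobj, dtype=np.float32)
    images = np.transpose(data, (2, 0, 1))
    n = images.shape[0]
    if len(meta["acquisition_time_ms"]) != n:
        raise MetadataError(
            f"sidecar lists {len(meta['acquisition_time_ms'])} frames, image has {n}"
        )
    extra = {}
    if "rr_local_ms" in meta:
        extra["rr_local_ms"] = np.asarray(meta["rr_local_ms"], dtype=float)
    return FrameSeries(
        images=images,
        acq_time_ms=np.asarray(meta["acquisition_time_ms"], dtype=float),
        trigger_time_ms=np.asarray(meta["trigger_time_ms"], dtype=float),
        slice_index=int(meta.get("slice_index", 0)),
        slice_thickness_mm=float(meta.get("slice_thickness_mm", 8.0)),
        pixel_spacing_mm=float(meta.get("pixel_spacing_mm", 1.6)),
        rr_interval_ms=meta.get("rr_interval_ms"),
        extra=extra,
    )


def read_series_dir(path: str | Path) -> list[FrameSeries]:
    """Read every slice series found under ``path``.

    NIfTI+JSON pairs are preferred; a directory of DICOM files with
    ``TriggerTime`` attributes is accepted as a fallback.
    """
    path = Path(path)
    nii_files = sorted(path.glob("slice*.nii.gz")) + sorted(path.glob("slice*.nii"))
    if nii_files:
        series = [read_series_file(p) for p in nii_files]
        return sorted(series, key=lambda s: s.slice_index)
    dcm_files = sorted(path.glob("*.dcm")) + sorted(path.glob("*.IMA"))
    if dcm_files:
        return _read_dicom_series(dcm_files)
    raise MetadataError(f"no slice series (NIfTI+JSON or DICOM) found in {path}")


def _read_dicom_series(files: list[Path]) -> list[FrameSeries]:
    import pydicom

    by_slice: dict[int, list] = {}
    for f in files:
        ds = pydicom.dcmread(str(f))
        if "TriggerTime" not in ds:
            raise MetadataError(
                f"DICOM frame {f} lacks the TriggerTime attribute needed for cardiac binning"
            )
        key = int(getattr(ds, "InstanceNumber", 0)) // 10_000
        by_slice.setdefault(int(getattr(ds, "SliceLocation", key)), []).append(ds)
    out = []
    for idx, (loc, frames) in enumerate(sorted(by_slice.items())):
        frames.sort(key=lambda d: float(d.AcquisitionTime))
        spacing = float(frames[0].PixelSpacing[0]) if "PixelSpacing" in frames[0] else 1.6
        out.append(
            FrameSeries(
                images=np.stack([d.pixel_array.astype(np.float32) for d in frames]),
                acq_time_ms=np.array([float(d.AcquisitionTime) * 1000.0 for d in frames]),
                trigger_time_ms=np.array([float(d.TriggerTime) for d in frames]),
                slice_index=idx,
                slice_thickness_mm=float(getattr(frames[0], "SliceThickness", 8.0)),
                pixel_spacing_mm=spacing,
            )
        )
    return out
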