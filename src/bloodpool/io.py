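"""Reading and writing gated blood-pool cine scans.

Two dialects are supported: multi-frame nuclear-medicine DICOM (read only,
via :mod:`pydicom`) and a portable HDF5 fixture container (read/write) that
round-trips a cine bit-for-bit together with its acquisition metadata.

Conventions used throughout the package: frames are stored row-major with
pixel ``(0, 0)`` at the top-left, and frame index 0 is the first gated frame
after the R-wave.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np

__all__ = [
    "AcquisitionMeta",
    "GatedCine",
    "read_gated_scan",
    "write_fixture",
    "export_parameters",
    "MIN_FRAMES",
]

#: Minimum number of gated frames accepted; reference acquisitions use 16.
MIN_FRAMES = 8


@dataclass(frozen=True)
class AcquisitionMeta:
    """Gating metadata attached to a cine.

    All times are in milliseconds, heart rate in beats/min, pixel spacing in
    mm/pixel (row, column). Fields that the source did not record are
    ``None`` — absent tags are never silently replaced by defaults.
    """

    n_frames: int
    frame_time: float | None = None
    heart_rate: float | None = None
    accepted_beats: int | None = None
    rejected_beats: int | None = None
    mean_beat_duration: float | None = None
    pixel_spacing: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        for name in ("frame_time", "heart_rate", "mean_beat_duration"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValueError(f"{name} must be strictly positive, got {v}")
        for name in ("accepted_beats", "rejected_beats"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")
        if self.pixel_spacing is not None:
            ps = tuple(float(x) for x in self.pixel_spacing)
            if len(ps) != 2 or any(x <= 0 for x in ps):
                raise ValueError("pixel_spacing must be a positive (row, col) pair")
            object.__setattr__(self, "pixel_spacing", ps)


@dataclass
class GatedCine:
    """A T-frame stack of count images plus acquisition metadata.

    Raw scans hold non-negative integers; background correction and
    filtering produce real-valued frames, still non-negative.
    """

    frames: np.ndarray
    meta: AcquisitionMeta

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (T, height, width) stack")
        if self.frames.shape[0] < MIN_FRAMES:
            raise ValueError(
                f"too few frames: {self.frames.shape[0]} < {MIN_FRAMES}"
            )
        if np.any(self.frames < 0):
            raise ValueError("negative counts in frame stack")
        if self.meta.n_frames != self.frames.shape[0]:
            raise ValueError("meta.n_frames does not match frame count")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    def with_frames(self, frames: np.ndarray) -> "GatedCine":
        """Copy of this cine with a replaced frame stack (same metadata)."""
        return GatedCine(frames=frames, meta=self.meta)


_META_FIELDS = (
    "frame_time",
    "heart_rate",
    "accepted_beats",
    "rejected_beats",
    "mean_beat_duration",
    "pixel_spacing",
)


def _meta_to_json(meta: AcquisitionMeta) -> str:
    d: dict = {"n_frames": meta.n_frames}
    for name in _META_FIELDS:
        v = getattr(meta, name)
        if v is not None:
            d[name] = list(v) if isinstance(v, tuple) else v
    return json.dumps(d)


def _meta_from_json(blob: str) -> AcquisitionMeta:
    d = json.loads(blob)
    if "pixel_spacing" in d:
        d["pixel_spacing"] = tuple(d["pixel_spacing"])
    return AcquisitionMeta(**d)


def read_gated_scan(path, dialect: str = "fixture") -> GatedCine:
    """Read a gated cine from ``path``.

    ``dialect='dicom'`` expects a multi-frame nuclear-medicine DICOM with
    ``NumberOfFrames >= 8``; frames are taken in stored (trigger-time)
    order and raw counts are left untouched. ``dialect='fixture'`` reads
    the HDF5 container written by :func:`write_fixture`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "fixture":
        return _read_fixture(path)
    if dialect == "dicom":
        return _read_dicom(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_fixture(path: Path) -> GatedCine:
    try:
        with h5py.File(path, "r") as f:
            frames = f["frames"][()]
            meta = _meta_from_json(f.attrs["meta"])
    except (OSError, KeyError) as exc:
        raise OSError(f"unreadable fixture file {path}: {exc}") from exc
    return GatedCine(frames=frames, meta=meta)


def _read_dicom(path: Path) -> GatedCine:
    import pydicom

    try:
        ds = pydicom.dcmread(path)
        frames = ds.pixel_array
    except Exception as exc:  # pydicom raises a mix of exception types
        raise OSError(f"unreadable DICOM file {path}: {exc}") from exc
    n = int(ds.get("NumberOfFrames", frames.shape[0] if frames.ndim == 3 else 1))
    if frames.ndim == 2:
        frames = frames[None]
    if n < MIN_FRAMES or frames.shape[0] < MIN_FRAMES:
        raise ValueError(f"too few frames: {min(n, frames.shape[0])} < {MIN_FRAMES}")

    def _get(tag, cast):
        v = ds.get(tag)
        return cast(v) if v not in (None, "") else None

    spacing = ds.get("PixelSpacing")
    meta = AcquisitionMeta(
        n_frames=frames.shape[0],
        frame_time=_get("FrameTime", float),
        heart_rate=_get("HeartRate", float),
        accepted_beats=_get("IntervalsAcquired", int),
        rejected_beats=_get("IntervalsRejected", int),
        mean_beat_duration=None,
        pixel_spacing=tuple(float(x) for x in spacing) if spacing else None,
    )
    return GatedCine(frames=frames, meta=meta)


def write_fixture(cine: GatedCine, path) -> Path:
    """Write ``cine`` to an HDF5 fixture; :func:`read_gated_scan` inverts it.

    Frames keep their dtype, so integer stacks round-trip bit-for-bit.
    Absent metadata fields are omitted from the JSON block and read back
    as absent.
    """
    path = Path(path)
    try:
        with h5py.File(path, "w") as f:
            f.create_dataset("frames", data=cine.frames)
            f.attrs["meta"] = _meta_to_json(cine.meta)
    except OSError as exc:
        raise OSError(f"cannot write fixture to {path}: {exc}") from exc
    return path


def export_parameters(rows, path) -> Path:
    """Write one CSV row per :class:`~bloodpool.parameters.ParameterSet`.

    Columns follow the documented fixed order; absent values are written
    as empty cells (never 0).
    """
    import pandas as pd

    from .parameters import ParameterSet

    rows = list(rows)
    if not rows:
        raise ValueError("export_parameters requires at least one row")
    cols = ParameterSet.csv_columns()
    records = []
    for ps in rows:
        rec = {}
        for c in cols:
            v = getattr(ps, c)
            rec[c] = np.nan if v is None else v
        records.append(rec)
    df = pd.DataFrame.from_records(records, columns=cols)
    df.to_csv(path, index=False)
    return Path(path)
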