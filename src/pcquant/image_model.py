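"""Calibrated image containers and TIFF/CSV I/O.

The pipeline's universal input is the :class:`ImageStack`: a scalar intensity
grid with an explicit axis declaration drawn from ``t`` (time), ``z`` (depth),
``c`` (channel), ``y``, ``x``, plus physical calibration (µm/pixel in-plane,
µm/slice axially, seconds/frame).  Axis order is always declared — in TIFF
metadata written by this package, or by the caller — never guessed.

Coordinate convention: 0-based pixel indices, voxel centers at integer
coordinates, physical position = index x pixel size.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile

from .errors import (
    AxisAmbiguityError,
    CalibrationError,
    FormatError,
    FrameMismatchError,
    SchemaError,
)

VALID_AXES = "tzcyx"

_DESCRIPTION_KEY = "pcquant"


def _validate_axes(axes: str, ndim: int) -> str:
    axes = axes.lower()
    if len(axes) != ndim:
        raise AxisAmbiguityError(
            f"axis string {axes!r} has {len(axes)} axes but data has {ndim}"
        )
    if len(set(axes)) != len(axes):
        raise AxisAmbiguityError(f"axis string {axes!r} repeats an axis")
    for a in axes:
        if a not in VALID_AXES:
            raise AxisAmbiguityError(f"unknown axis {a!r} in {axes!r}")
    if "y" not in axes or "x" not in axes:
        raise AxisAmbiguityError(f"axis string {axes!r} must contain 'y' and 'x'")
    # canonical order: any subset of tzcyx in that order
    order = [a for a in VALID_AXES if a in axes]
    if list(axes) != order:
        raise AxisAmbiguityError(
            f"axes must be declared in canonical t-z-c-y-x order, got {axes!r}"
        )
    return axes


@dataclass
class ImageStack:
    """A calibrated multi-dimensional intensity grid.

    Parameters
    ----------
    data:
        Scalar array whose dimensions follow ``axes``.
    axes:
        Axis declaration, an ordered subset of ``"tzcyx"`` ending in ``"yx"``.
    pixel_size_xy:
        In-plane calibration, µm per pixel (> 0). Required.
    pixel_size_z:
        Axial calibration, µm per z-slice (> 0). Required iff a ``z`` axis is
        present.
    frame_interval:
        Seconds between frames (> 0). Required iff a ``t`` axis is present.
    channel_names:
        One identifier per channel. Defaults to ``ch0, ch1, ...``.
    """

    data: np.ndarray
    axes: str
    pixel_size_xy: float
    pixel_size_z: float | None = None
    frame_interval: float | None = None
    channel_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim < 2:
            raise AxisAmbiguityError("image data must have at least y and x axes")
        self.axes = _validate_axes(self.axes, self.data.ndim)
        if not np.all(np.isfinite(self.data)):
            raise ValueError("image intensities must be finite")
        if self.pixel_size_xy is None or self.pixel_size_xy <= 0:
            raise CalibrationError(f"pixel_size_xy must be > 0, got {self.pixel_size_xy}")
        if "z" in self.axes:
            if self.pixel_size_z is None or self.pixel_size_z <= 0:
                raise CalibrationError(
                    f"z axis present: pixel_size_z must be > 0, got {self.pixel_size_z}"
                )
        if "t" in self.axes:
            if self.frame_interval is None or self.frame_interval <= 0:
                raise CalibrationError(
                    f"t axis present: frame_interval must be > 0, got {self.frame_interval}"
                )
        n_ch = self.n_channels
        if self.channel_names is None:
            self.channel_names = [f"ch{i}" for i in range(n_ch)]
        if len(self.channel_names) != n_ch:
            raise ValueError(
                f"{len(self.channel_names)} channel names for {n_ch} channels"
            )

    # -- axis helpers -----------------------------------------------------
    def axis_index(self, axis: str) -> int:
        if axis not in self.axes:
            raise KeyError(f"axis {axis!r} not present (axes={self.axes!r})")
        return self.axes.index(axis)

    @property
    def n_channels(self) -> int:
        return self.data.shape[self.axis_index("c")] if "c" in self.axes else 1

    @property
    def n_frames(self) -> int:
        return self.data.shape[self.axis_index("t")] if "t" in self.axes else 1

    @property
    def spatial_shape(self) -> tuple[int, ...]:
        """Shape of one channel/timepoint: (z, y, x) or (y, x)."""
        shape = []
        for a, n in zip(self.axes, self.data.shape):
            if a in "zyx":
                shape.append(n)
        return tuple(shape)

    def channel(self, which: int | str) -> np.ndarray:
        """One channel's data with the channel axis removed."""
        if isinstance(which, str):
            which = self.channel_names.index(which)
        if "c" not in self.axes:
            if which != 0:
                raise KeyError(f"single-channel stack has no channel {which}")
            return self.data
        return np.take(self.data, which, axis=self.axis_index("c"))

    def frame(self, t: int) -> np.ndarray:
        """One timepoint's data with the time axis removed."""
        if "t" not in self.axes:
            if t != 0:
                raise KeyError(f"static stack has no frame {t}")
            return self.data
        return np.take(self.data, t, axis=self.axis_index("t"))


@dataclass
class Mask:
    """A binary mask over one channel's spatial grid (values 0/1)."""

    data: np.ndarray
    pixel_size_xy: float = 1.0
    pixel_size_z: float | None = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.dtype != bool:
            uniq = np.unique(arr)
            if not np.all(np.isin(uniq, (0, 1))):
                raise ValueError("mask values must be 0/1")
            arr = arr.astype(bool)
        self.data = arr

    def check_same_frame(self, other: "Mask | LabelMap | np.ndarray") -> None:
        shape = other.shape if isinstance(other, np.ndarray) else other.data.shape
        if self.data.shape != shape:
            raise FrameMismatchError(
                f"shape mismatch: {self.data.shape} vs {shape}"
            )

    @property
    def area_pixels(self) -> int:
        return int(self.data.sum())


@dataclass
class LabelMap:
    """Integer-labeled objects: 0 = background, labels 1..n_labels gap-free."""

    data: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if not np.issubdtype(arr.dtype, np.integer):
            raise ValueError("label map must be integer-valued")
        if arr.min() < 0:
            raise ValueError("label map must be non-negative")
        self.data = arr
        labels = np.unique(arr)
        labels = labels[labels > 0]
        n = int(labels.size)
        if n and (labels[0] != 1 or labels[-1] != n):
            raise ValueError("labels must be 1..n with no gaps")
        self.n_labels = n

    @property
    def foreground(self) -> np.ndarray:
        return self.data > 0


@dataclass
class ObjectRecord:
    """One detected object in pixel coordinates.

    ``centroid`` is (x, y) or (x, y, z); ``bbox`` stores per-axis
    (min, max-exclusive) extents in the same order.
    """

    label: int
    centroid: tuple[float, ...]
    voxel_count: int
    bbox: tuple[tuple[int, int], ...]
    channel: str = ""

    def __post_init__(self) -> None:
        if self.voxel_count < 1:
            raise ValueError("voxel_count must be >= 1")
        for c, (lo, hi) in zip(self.centroid, self.bbox):
            if not (lo - 0.5 <= c <= hi - 0.5):
                raise ValueError(f"centroid {self.centroid} outside bbox {self.bbox}")


def records_from_labels(labels: LabelMap, channel: str = "") -> list[ObjectRecord]:
    """Per-object centroid / size / bbox records from a label map.

    Centroids and bboxes are reported in (x, y[, z]) order, i.e. the reverse
    of the array's (z, )y, x axis order.
    """
    from scipy import ndimage as ndi

    arr = labels.data
    if labels.n_labels == 0:
        return []
    idx = np.arange(1, labels.n_labels + 1)
    centroids = ndi.center_of_mass(arr > 0, arr, idx)
    slices = ndi.find_objects(arr)
    counts = ndi.sum_labels(np.ones_like(arr, dtype=np.int64), arr, idx)
    records = []
    for lab, com, cnt in zip(idx, centroids, counts):
        sl = slices[lab - 1]
        bbox = tuple((s.start, s.stop) for s in reversed(sl))
        centroid = tuple(reversed([float(c) for c in com]))
        records.append(
            ObjectRecord(
                label=int(lab),
                centroid=centroid,
                voxel_count=int(cnt),
                bbox=bbox,
                channel=channel,
            )
        )
    return records


# ---------------------------------------------------------------------------
# TIFF I/O
# ---------------------------------------------------------------------------

def write_stack(stack: ImageStack, path: str | Path) -> None:
    """Write an ImageStack as a TIFF with a JSON calibration description.

    The axis string and calibration are embedded in the ImageDescription tag
    so that :func:`read_stack` round-trips without sidecar files.
    """
    meta = {
        _DESCRIPTION_KEY: {
            "axes": stack.axes,
            "pixel_size_xy": stack.pixel_size_xy,
            "pixel_size_z": stack.pixel_size_z,
            "frame_interval": stack.frame_interval,
            "channel_names": stack.channel_names,
        }
    }
    tifffile.imwrite(str(path), stack.data, description=json.dumps(meta))


def read_stack(
    path: str | Path,
    axes: str | None = None,
    pixel_size_xy: float | None = None,
    pixel_size_z: float | None = None,
    frame_interval: float | None = None,
    channel_names: Sequence[str] | None = None,
) -> ImageStack:
    """Read a TIFF into an ImageStack.

    Metadata written by :func:`write_stack` is honoured; explicit keyword
    overrides win over file metadata.  Missing axes or calibration with no
    override is an error — nothing is guessed.
    """
    try:
        with tifffile.TiffFile(str(path)) as tif:
            data = tif.asarray()
            desc = tif.pages[0].description or ""
    except (OSError, ValueError, tifffile.TiffFileError) as exc:
        raise FormatError(f"cannot read TIFF {path}: {exc}") from exc

    meta: dict = {}
    if desc:
        try:
            parsed = json.loads(desc)
            if isinstance(parsed, dict):
                meta = parsed.get(_DESCRIPTION_KEY, {}) or {}
        except json.JSONDecodeError:
            meta = {}

    axes = axes or meta.get("axes")
    if axes is None:
        if data.ndim == 2:
            axes = "yx"
        else:
            raise AxisAmbiguityError(
                f"{path}: {data.ndim}-D TIFF with no axis declaration; "
                "pass axes= explicitly"
            )

    def pick(override, key):
        return override if override is not None else meta.get(key)

    pixel_size_xy = pick(pixel_size_xy, "pixel_size_xy")
    if pixel_size_xy is None:
        raise CalibrationError(f"{path}: no pixel_size_xy in metadata or override")
    pixel_size_z = pick(pixel_size_z, "pixel_size_z")
    frame_interval = pick(frame_interval, "frame_interval")
    channel_names = pick(
        list(channel_names) if channel_names is not None else None, "channel_names"
    )
    return ImageStack(
        data=data,
        axes=axes,
        pixel_size_xy=pixel_size_xy,
        pixel_size_z=pixel_size_z,
        frame_interval=frame_interval,
        channel_names=channel_names,
    )


# ---------------------------------------------------------------------------
# Table output
# ---------------------------------------------------------------------------

def _record_to_row(rec) -> dict:
    if dataclasses.is_dataclass(rec) and not isinstance(rec, type):
        d = dataclasses.asdict(rec)
    elif isinstance(rec, Mapping):
        d = dict(rec)
    else:
        raise SchemaError(f"unsupported record type {type(rec).__name__}")
    row = {}
    for k, v in d.items():
        if isinstance(v, tuple):
            # flatten centroid/bbox-style tuples into scalar columns
            flat = np.asarray(v).ravel()
            names = "xyzw"
            for i, x in enumerate(flat):
                suffix = names[i] if len(flat) <= 4 else str(i)
                row[f"{k}_{suffix}"] = x
        else:
            row[k] = v
    return row


def write_table(
    records: Iterable,
    path: str | Path,
    header_lines: Sequence[str] = (),
    columns: Sequence[str] | None = None,
) -> None:
    """Write records (dataclasses or mappings sharing a schema) to CSV.

    Rows keep input order; numeric fields are serialized at full ``repr``
    precision.  ``header_lines`` are emitted as ``#``-prefixed comment lines
    before the CSV header (used by the CLI for provenance).  ``columns``
    supplies the header for an empty record set.
    """
    rows = [_record_to_row(r) for r in records]
    if rows:
        schema = list(rows[0].keys())
        for i, r in enumerate(rows[1:], start=1):
            if list(r.keys()) != schema:
                raise SchemaError(
                    f"record {i} schema {list(r.keys())} != record 0 schema {schema}"
                )
        df = pd.DataFrame(rows, columns=schema)
    else:
        df = pd.DataFrame(columns=list(columns) if columns else [])
    path = Path(path)
    try:
        with open(path, "w", newline="") as fh:
            for line in header_lines:
                fh.write(f"# {line}\n")
            df.to_csv(fh, index=False)
    except OSError as exc:
        raise IOError(f"cannot write {path}: {exc}") from exc


def read_table(path: str | Path) -> pd.DataFrame:
    """Read a CSV written by :func:`write_table`, skipping provenance lines."""
    return pd.read_csv(path, comment="#")


def write_overlay(img: np.ndarray, labels: "LabelMap", path: str | Path) -> None:
    """QC export: detected object outlines (red) over the raw 2-D image (PNG).

    3-D inputs are maximum-projected along the first axis.
    """
    from skimage.io import imsave
    from skimage.segmentation import find_boundaries

    img = np.asarray(img, dtype=np.float64)
    lab = labels.data
    if img.ndim == 3:
        img = img.max(axis=0)
        lab = lab.max(axis=0)
    lo, hi = img.min(), img.max()
    norm = (img - lo) / (hi - lo) if hi > lo else np.zeros_like(img)
    rgb = np.stack([norm] * 3, axis=-1)
    edges = find_boundaries(lab, mode="outer")
    rgb[edges] = [1.0, 0.0, 0.0]
    imsave(str(path), (rgb * 255).astype(np.uint8), check_contrast=False)
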