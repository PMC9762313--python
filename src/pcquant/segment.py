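"""Detection core: pre-filters, thresholding, labeling, splitting, filtering.

This is the shared machinery behind every counting readout in the pipeline:
an image is optionally denoised (median / Gaussian / variance filter),
optionally background-subtracted (rolling ball), binarized at an automatic
threshold that the user may scale with a multiplier ``k`` and clamp to a
minimum permitted value ``t_min`` (to prevent segmentation of background),
hole-filled, labeled as contiguous foreground regions, optionally split with
a distance-transform watershed, and finally filtered by object size and an
optional region of interest.

All window filters use nearest-edge replication and operate per 2-D plane;
z-stacks are filtered slice by slice, while hole filling and labeling run in
the mask's native dimensionality.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.morphology import disk, opening
from skimage.segmentation import watershed

from .errors import DegenerateHistogramError, ValidationError
from .image_model import ImageStack, LabelMap, Mask, ObjectRecord, records_from_labels

N_OTSU_BINS = 256


# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------

@dataclass
class DetectionParams:
    """Full parameterization of :func:`detect`.

    ``threshold_multiplier`` (k) scales the automatically computed threshold;
    ``threshold_minimum`` (t_min) clamps it from below.  The adjusted
    threshold is ``max(k * t0, t_min)``.  With ``t_min_fractional`` the
    minimum is interpreted as a fraction of the image intensity range rather
    than an absolute intensity.
    """

    prefilter: Literal["none", "median", "gaussian", "variance"] = "none"
    prefilter_radius: int = 1        # median/variance window radius, pixels
    prefilter_sigma: float = 1.0     # gaussian sigma, pixels
    background: Literal["none", "rolling_ball"] = "none"
    background_radius: int = 15
    threshold_method: Literal["otsu", "mean", "fixed"] = "otsu"
    threshold_fixed: float = 0.0
    threshold_multiplier: float = 1.0
    threshold_minimum: float = 0.0
    t_min_fractional: bool = False
    fill_holes: bool = False
    split_touching: bool = False
    min_object_voxels: int = 1
    roi: Mask | None = None
    connectivity: int | None = None  # 4|8 (2D), 6|26 (3D); None = full (8/26)

    def __post_init__(self) -> None:
        if self.threshold_multiplier <= 0:
            raise ValidationError(
                f"threshold_multiplier must be > 0, got {self.threshold_multiplier}"
            )
        if self.min_object_voxels < 1:
            raise ValidationError(
                f"min_object_voxels must be >= 1, got {self.min_object_voxels}"
            )
        if self.prefilter not in ("none", "median", "gaussian", "variance"):
            raise ValidationError(f"unknown prefilter {self.prefilter!r}")
        if self.background not in ("none", "rolling_ball"):
            raise ValidationError(f"unknown background mode {self.background!r}")
        if self.threshold_method not in ("otsu", "mean", "fixed"):
            raise ValidationError(f"unknown threshold method {self.threshold_method!r}")
        if self.connectivity not in (None, 4, 8, 6, 26):
            raise ValidationError(f"unsupported connectivity {self.connectivity}")

    def provenance(self) -> dict:
        d = {
            k: v
            for k, v in self.__dict__.items()
            if k != "roi"
        }
        d["roi"] = self.roi is not None
        return d


def _structure(ndim: int, connectivity: int | None) -> np.ndarray:
    """Binary structure for a 4/8 (2D) or 6/26 (3D) connectivity code."""
    if connectivity is None:
        order = ndim  # full connectivity: 8 in 2D, 26 in 3D
    elif connectivity in (4, 6):
        order = 1
    elif connectivity in (8, 26):
        order = ndim
    else:  # pragma: no cover - guarded by DetectionParams
        raise ValidationError(f"unsupported connectivity {connectivity}")
    return ndi.generate_binary_structure(ndim, order)


# ---------------------------------------------------------------------------
# Filters (per 2-D plane, nearest-edge replication)
# ---------------------------------------------------------------------------

def _as_array(img) -> np.ndarray:
    return img.data if isinstance(img, ImageStack) else np.asarray(img)

def _like(img, out: np.ndarray):
    if isinstance(img, ImageStack):
        return replace(img, data=out)
    return out


def _per_plane(data: np.ndarray, func2d) -> np.ndarray:
    """Apply a 2-D filter to every trailing (y, x) plane."""
    if data.ndim == 2:
        return func2d(data)
    flat = data.reshape(-1, *data.shape[-2:])
    out = np.stack([func2d(p) for p in flat])
    return out.reshape(data.shape)


def median_filter_2d(img, radius: int):
    """Per-slice median filter over a (2r+1)^2 neighborhood."""
    if radius < 1:
        raise ValidationError(f"median radius must be >= 1, got {radius}")
    size = 2 * radius + 1
    data = _as_array(img)
    out = _per_plane(data, lambda p: ndi.median_filter(p, size=size, mode="nearest"))
    return _like(img, out)


def gaussian_filter(img, sigma: float):
    """Per-slice normalized Gaussian smoothing; sigma=0 is the identity."""
    if sigma < 0:
        raise ValidationError(f"gaussian sigma must be >= 0, got {sigma}")
    data = _as_array(img)
    if sigma == 0:
        return _like(img, data.copy())
    out = _per_plane(
        data.astype(np.float64),
        lambda p: ndi.gaussian_filter(p, sigma=sigma, mode="nearest"),
    )
    return _like(img, out)


def variance_filter(img, radius: int):
    """Per-slice population variance of the (2r+1)^2 neighborhood."""
    if radius < 1:
        raise ValidationError(f"variance radius must be >= 1, got {radius}")
    size = 2 * radius + 1

    def _var(p: np.ndarray) -> np.ndarray:
        p = p.astype(np.float64)
        mean = ndi.uniform_filter(p, size=size, mode="nearest")
        sq = ndi.uniform_filter(p * p, size=size, mode="nearest")
        return np.maximum(sq - mean * mean, 0.0)

    return _like(img, _per_plane(_as_array(img), _var))


def rolling_ball_subtract(img, radius: int):
    """Background subtraction: input minus its grayscale opening.

    The background is the morphological opening with a disk of the given
    radius (per 2-D plane); structures wider than the ball survive into the
    background and are removed, narrow peaks are preserved.  Output is
    clipped at zero.
    """
    if radius < 1:
        raise ValidationError(f"rolling-ball radius must be >= 1, got {radius}")
    footprint = disk(radius)

    def _sub(p: np.ndarray) -> np.ndarray:
        bg = opening(p, footprint)
        return np.clip(p.astype(np.float64) - bg, 0.0, None)

    return _like(img, _per_plane(_as_array(img), _sub))


# ---------------------------------------------------------------------------
# Thresholding
# ---------------------------------------------------------------------------

def otsu_threshold(img: np.ndarray) -> float:
    """Otsu threshold on a 256-bin histogram spanning [min, max].

    Maximizes the between-class variance over all 255 split points; ties go
    to the lowest bin.  The returned threshold is the upper edge of the
    winning bin, so strict ``> t`` binarization separates the classes.
    Raises on constant images, whose histogram admits no split.
    """
    img = np.asarray(img)
    if img.size == 0:
        raise DegenerateHistogramError("empty image")
    lo = float(img.min())
    hi = float(img.max())
    if lo == hi:
        raise DegenerateHistogramError(f"constant image (value {lo})")
    counts, edges = np.histogram(img, bins=N_OTSU_BINS, range=(lo, hi))
    counts = counts.astype(np.float64)
    total = counts.sum()
    centers = (edges[:-1] + edges[1:]) / 2.0

    w0 = np.cumsum(counts)                      # pixels in bins 0..k
    m0 = np.cumsum(counts * centers)            # intensity mass in bins 0..k
    w1 = total - w0
    m_total = m0[-1]
    with np.errstate(invalid="ignore", divide="ignore"):
        mu0 = m0 / w0
        mu1 = (m_total - m0) / w1
        sigma_b = w0 * w1 * (mu0 - mu1) ** 2
    valid = (w0 > 0) & (w1 > 0)
    sigma_b = np.where(valid[:-1], sigma_b[:-1], -np.inf)  # split after bin k<255
    k = int(np.argmax(sigma_b))  # argmax returns the first (lowest) maximizer
    return float(edges[k + 1])


def compute_threshold(
    img,
    method: str = "otsu",
    k: float = 1.0,
    t_min: float = 0.0,
    fixed: float = 0.0,
    t_min_fractional: bool = False,
) -> float:
    """Adjusted threshold t = max(k * t0, t_min).

    ``t0`` is the raw threshold from the chosen method (otsu / mean /
    fixed).  The multiplier is applied first and the minimum clamp second.
    """
    if k <= 0:
        raise ValidationError(f"threshold multiplier must be > 0, got {k}")
    arr = _as_array(img)
    if arr.size == 0:
        raise DegenerateHistogramError("empty image")
    if method == "otsu":
        t0 = otsu_threshold(arr)
    elif method == "mean":
        t0 = float(arr.mean())
    elif method == "fixed":
        t0 = float(fixed)
    else:
        raise ValidationError(f"unknown threshold method {method!r}")
    if t_min_fractional:
        lo, hi = float(arr.min()), float(arr.max())
        t_min = lo + t_min * (hi - lo)
    return max(k * t0, t_min)


def binarize(img, t: float) -> Mask:
    """Foreground where intensity is strictly greater than ``t``."""
    arr = _as_array(img)
    kwargs = {}
    if isinstance(img, ImageStack):
        kwargs = {"pixel_size_xy": img.pixel_size_xy, "pixel_size_z": img.pixel_size_z}
    return Mask(data=arr > t, **kwargs)


# ---------------------------------------------------------------------------
# Binary operations and labeling
# ---------------------------------------------------------------------------

def fill_holes(mask: Mask) -> Mask:
    """Fill background regions not connected to the image border."""
    filled = ndi.binary_fill_holes(mask.data)
    return Mask(data=filled, pixel_size_xy=mask.pixel_size_xy,
                pixel_size_z=mask.pixel_size_z)


def relabel_canonical(arr: np.ndarray) -> np.ndarray:
    """Relabel to 1..n ordered by first-encountered voxel in raster scan."""
    flat = arr.ravel()
    fg = flat > 0
    if not fg.any():
        return np.zeros_like(arr, dtype=np.int32)
    labels, first = np.unique(flat[fg], return_index=True)
    order = np.argsort(first, kind="stable")
    mapping = np.zeros(int(labels.max()) + 1, dtype=np.int32)
    mapping[labels[order]] = np.arange(1, len(labels) + 1, dtype=np.int32)
    return mapping[arr]


def label_components(mask: Mask, connectivity: int | None = None) -> LabelMap:
    """Connected-components labeling of contiguous foreground regions.

    Labels are assigned 1..n in order of each component's first voxel in a
    raster scan, which makes the output deterministic across runs.
    """
    structure = _structure(mask.data.ndim, connectivity)
    raw, _ = ndi.label(mask.data, structure=structure)
    return LabelMap(
        data=relabel_canonical(raw),
        provenance={"op": "label_components", "connectivity": connectivity},
    )


def watershed_split(mask: Mask, connectivity: int | None = None) -> LabelMap:
    """Split touching convex objects with a distance-transform watershed.

    Seeds are local maxima of the Euclidean distance transform; maxima
    closer together than the larger seed's own distance value (its inscribed
    radius) are merged, which suppresses the spurious plateau maxima a
    single object generates.  The watershed of the negated distance
    transform, constrained to the mask, then partitions the foreground.
    """
    fg = mask.data
    if not fg.any():
        return LabelMap(data=np.zeros(fg.shape, dtype=np.int32),
                        provenance={"op": "watershed_split"})
    dist = ndi.distance_transform_edt(fg)
    coords = peak_local_max(dist, labels=fg.astype(np.int32), exclude_border=False)
    # order peaks by descending distance (stable for reproducibility)
    vals = dist[tuple(coords.T)]
    order = np.lexsort((*coords.T[::-1], -vals))
    accepted: list[np.ndarray] = []
    for i in order:
        c = coords[i]
        r = dist[tuple(c)]
        if all(np.linalg.norm(c - a) > r for a in accepted):
            accepted.append(c)
    markers = np.zeros(fg.shape, dtype=np.int32)
    for j, c in enumerate(accepted, start=1):
        markers[tuple(c)] = j
    conn_order = 1 if connectivity in (4, 6) else fg.ndim
    labels = watershed(-dist, markers=markers, mask=fg, connectivity=conn_order)
    return LabelMap(
        data=relabel_canonical(labels),
        provenance={"op": "watershed_split", "connectivity": connectivity},
    )


def filter_objects(
    labels: LabelMap,
    min_voxels: int = 1,
    roi: Mask | None = None,
) -> LabelMap:
    """Drop small objects and objects whose centroid falls outside the ROI.

    Survivors are relabeled canonically (1..n, raster order).
    """
    if min_voxels < 1:
        raise ValidationError(f"min_voxels must be >= 1, got {min_voxels}")
    arr = labels.data
    if labels.n_labels == 0:
        return LabelMap(data=arr.copy(), provenance=dict(labels.provenance))
    counts = np.bincount(arr.ravel(), minlength=labels.n_labels + 1)
    keep = counts >= min_voxels
    keep[0] = False
    if roi is not None:
        roi.check_same_frame(labels)
        idx = np.arange(1, labels.n_labels + 1)
        centroids = ndi.center_of_mass(arr > 0, arr, idx)
        for lab, com in zip(idx, centroids):
            if not keep[lab]:
                continue
            voxel = tuple(
                int(np.clip(round(c), 0, s - 1)) for c, s in zip(com, arr.shape)
            )
            if not roi.data[voxel]:
                keep[lab] = False
    out = np.where(keep[arr], arr, 0)
    prov = dict(labels.provenance)
    prov.update({"min_voxels": min_voxels, "roi": roi is not None})
    return LabelMap(data=relabel_canonical(out), provenance=prov)


# ---------------------------------------------------------------------------
# Composite detection pipeline
# ---------------------------------------------------------------------------

def detect(
    stack: ImageStack,
    channel: int | str,
    params: DetectionParams,
) -> tuple[LabelMap, list[ObjectRecord]]:
    """Run the full detection pipeline on one channel of a stack.

    prefilter -> background subtraction -> threshold (with multiplier and
    minimum clamp) -> binarize -> optional hole filling -> connected
    components -> optional watershed split -> size/ROI filter.

    Returns the label map (with full parameter provenance) and one
    :class:`~pcquant.image_model.ObjectRecord` per surviving object.
    """
    img = stack.channel(channel)
    if "t" in stack.axes:
        raise ValidationError("detect expects a static stack; select a frame first")

    if params.prefilter == "median":
        img = _as_array(median_filter_2d(img, params.prefilter_radius))
    elif params.prefilter == "gaussian":
        img = _as_array(gaussian_filter(img, params.prefilter_sigma))
    elif params.prefilter == "variance":
        img = _as_array(variance_filter(img, params.prefilter_radius))

    if params.background == "rolling_ball":
        img = _as_array(rolling_ball_subtract(img, params.background_radius))

    t = compute_threshold(
        img,
        method=params.threshold_method,
        k=params.threshold_multiplier,
        t_min=params.threshold_minimum,
        fixed=params.threshold_fixed,
        t_min_fractional=params.t_min_fractional,
    )
    mask = Mask(data=img > t, pixel_size_xy=stack.pixel_size_xy,
                pixel_size_z=stack.pixel_size_z)
    if params.fill_holes:
        mask = fill_holes(mask)
    if params.split_touching:
        labels = watershed_split(mask, params.connectivity)
    else:
        labels = label_components(mask, params.connectivity)
    labels = filter_objects(labels, params.min_object_voxels, params.roi)
    prov = params.provenance()
    prov.update({"op": "detect", "threshold_applied": t, "channel": str(channel)})
    labels.provenance = prov
    ch_name = channel if isinstance(channel, str) else stack.channel_names[channel]
    records = records_from_labels(labels, channel=ch_name)
    return labels, records
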