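"""Reported quantities: containment, colocalization, areas, growth, volume.

These operations turn detections and masks into the numbers the imaging
workflows report: the fraction of protocells inside leukocytes and of
leukocytes containing protocells (the uptake readout), overlap of protocells
with a marker channel (lysosome targeting, intact-cargo calls), pigmented
area fractions, fluorescent pixel counts, tumor areas and their growth
relative to a first timepoint, stain-positive area fractions of tumor
sections, and the Cavalieri tumor-volume estimate from serial sections
(section area x section thickness, summed).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import DegenerateBaselineError, FrameMismatchError, ValidationError
from .image_model import ImageStack, LabelMap, Mask, ObjectRecord
from .segment import compute_threshold

DEFAULT_SECTION_THICKNESS_UM = 10.0


# ---------------------------------------------------------------------------
# Containment (uptake)
# ---------------------------------------------------------------------------

@dataclass
class ContainmentResult:
    """Uptake readout: which protocells sit inside which cells.

    ``per_pc`` maps each protocell label to its owning cell label (0 =
    outside every cell); ``per_cell`` counts contained protocells per cell
    label (cells with zero protocells included).
    """

    per_cell: dict[int, int]
    per_pc: dict[int, int]
    pct_pcs_inside: float
    pct_cells_with_pc: float

    @property
    def n_inside(self) -> int:
        return sum(1 for owner in self.per_pc.values() if owner > 0)

    @property
    def n_outside(self) -> int:
        return sum(1 for owner in self.per_pc.values() if owner == 0)


def containment(cells: LabelMap, pcs: Sequence[ObjectRecord],
                rule: str = "centroid") -> ContainmentResult:
    """Classify each protocell as inside or outside a labeled cell.

    Under the default ``centroid`` rule a protocell is inside iff the cell
    label at its rounded centroid voxel is non-zero; that label is its
    owner.  Percentages are computed over all protocells and all cells.
    """
    if rule != "centroid":
        raise ValidationError(f"unknown containment rule {rule!r}")
    arr = cells.data
    per_pc: dict[int, int] = {}
    for rec in pcs:
        # centroid is (x, y[, z]); array index order is reversed
        idx = tuple(
            int(np.clip(round(c), 0, s - 1))
            for c, s in zip(reversed(rec.centroid), arr.shape)
        )
        if len(idx) != arr.ndim:
            raise FrameMismatchError(
                f"protocell centroid has {len(rec.centroid)} axes, "
                f"cell map has {arr.ndim}"
            )
        per_pc[rec.label] = int(arr[idx])
    per_cell = {lab: 0 for lab in range(1, cells.n_labels + 1)}
    for owner in per_pc.values():
        if owner > 0:
            per_cell[owner] += 1
    n_total = len(per_pc)
    n_inside = sum(1 for o in per_pc.values() if o > 0)
    n_cells_with = sum(1 for v in per_cell.values() if v > 0)
    return ContainmentResult(
        per_cell=per_cell,
        per_pc=per_pc,
        pct_pcs_inside=100.0 * n_inside / n_total if n_total else 0.0,
        pct_cells_with_pc=100.0 * n_cells_with / cells.n_labels if cells.n_labels else 0.0,
    )


# ---------------------------------------------------------------------------
# Colocalization
# ---------------------------------------------------------------------------

def overlap_fraction(labels: LabelMap, label: int, marker: Mask) -> float:
    """Fraction of one object's voxels lying inside a marker mask."""
    marker.check_same_frame(labels)
    obj = labels.data == label
    n = int(obj.sum())
    if n == 0:
        raise ValidationError(f"label {label} not present")
    return float(np.logical_and(obj, marker.data).sum() / n)


def classify_marker_positive(
    labels: LabelMap,
    objects: Sequence[ObjectRecord],
    marker: Mask,
    min_fraction: float = 1.0,
) -> tuple[dict[int, bool], float]:
    """Per-object marker call: positive iff overlap fraction >= min_fraction.

    ``min_fraction=1.0`` encodes the strict "fully colocalized" criterion
    used for lysosome targeting; a looser value (e.g. 0.5) suits
    intact-cargo calls.  Returns the per-label boolean map and the positive
    percentage over all objects.
    """
    if not (0.0 <= min_fraction <= 1.0):
        raise ValidationError("min_fraction must be in [0, 1]")
    calls = {
        rec.label: overlap_fraction(labels, rec.label, marker) >= min_fraction
        for rec in objects
    }
    pct = 100.0 * sum(calls.values()) / len(calls) if calls else 0.0
    return calls, pct


# ---------------------------------------------------------------------------
# Area-based readouts
# ---------------------------------------------------------------------------

def pigmentation_fraction(
    brightfield: ImageStack | np.ndarray,
    region: Mask | None = None,
    method: str = "otsu",
    polarity: str = "dark",
    k: float = 1.0,
    t_min: float = 0.0,
    fixed: float = 0.0,
) -> float:
    """Percentage of region pixels on the pigment side of a threshold.

    For brightfield pigment the relevant side is ``dark`` (at or below the
    threshold); ``polarity="bright"`` counts above-threshold pixels instead.
    """
    img = brightfield.data if isinstance(brightfield, ImageStack) else np.asarray(brightfield)
    if region is None:
        region_data = np.ones(img.shape, dtype=bool)
    else:
        region.check_same_frame(img)
        region_data = region.data
    n_region = int(region_data.sum())
    if n_region == 0:
        raise ValidationError("empty region")
    t = compute_threshold(img, method=method, k=k, t_min=t_min, fixed=fixed)
    if polarity == "dark":
        hit = img <= t
    elif polarity == "bright":
        hit = img > t
    else:
        raise ValidationError(f"polarity must be 'dark' or 'bright', got {polarity!r}")
    return 100.0 * int(np.logical_and(hit, region_data).sum()) / n_region


def fluorescent_pixel_count(
    img: ImageStack | np.ndarray,
    t: float,
    region: Mask | None = None,
) -> int:
    """Number of region pixels with intensity strictly above ``t``."""
    arr = img.data if isinstance(img, ImageStack) else np.asarray(img)
    hit = arr > t
    if region is not None:
        region.check_same_frame(arr)
        hit = np.logical_and(hit, region.data)
    return int(hit.sum())


def positive_area_fraction(mask: Mask, region: Mask) -> float:
    """100 * |mask AND region| / |region| — stain-positive area percentage."""
    region.check_same_frame(mask)
    n_region = region.area_pixels
    if n_region == 0:
        raise ValidationError("empty region")
    return 100.0 * int(np.logical_and(mask.data, region.data).sum()) / n_region


def double_positive_area_fraction(mask_a: Mask, mask_b: Mask, region: Mask) -> float:
    """100 * |A AND B AND region| / |region| — double-positive percentage."""
    region.check_same_frame(mask_a)
    region.check_same_frame(mask_b)
    n_region = region.area_pixels
    if n_region == 0:
        raise ValidationError("empty region")
    inter = mask_a.data & mask_b.data & region.data
    return 100.0 * int(inter.sum()) / n_region


# ---------------------------------------------------------------------------
# Tumor area, growth, and volume
# ---------------------------------------------------------------------------

def tumor_area(outline_mask: Mask, pixel_size: float | None = None) -> float:
    """Outlined-region area in µm²: foreground pixel count x pixel size²."""
    px = pixel_size if pixel_size is not None else outline_mask.pixel_size_xy
    if px is None or px <= 0:
        raise ValidationError("pixel_size must be > 0")
    return outline_mask.area_pixels * px**2


def relative_growth(areas: Sequence[float]) -> list[float]:
    """Each area as a percentage of the first timepoint (first entry = 100)."""
    areas = list(areas)
    if not areas:
        return []
    if areas[0] == 0:
        raise DegenerateBaselineError("first-timepoint area is zero")
    return [100.0 * a / areas[0] for a in areas]


def section_volume(
    per_section_areas: Sequence[float],
    thickness: float = DEFAULT_SECTION_THICKNESS_UM,
) -> float:
    """Cavalieri volume estimate: sum of section area x section thickness.

    Areas in µm², thickness in µm (default 10, the cryosection thickness),
    volume in µm³.
    """
    if thickness <= 0:
        raise ValidationError(f"thickness must be > 0, got {thickness}")
    return float(sum(a * thickness for a in per_section_areas))


@dataclass
class SectionQuant:
    """Per-section stain quantification plus the Cavalieri volume."""

    per_section: list[dict]       # tumor_area_um2, positive_area_um2, positive_fraction
    total_volume_um3: float
    thickness_um: float


def quantify_sections(
    sections: Sequence[tuple[Mask, Mask]],
    thickness: float = DEFAULT_SECTION_THICKNESS_UM,
) -> SectionQuant:
    """Tumor and stain-positive areas per serial section, plus total volume.

    Each item pairs a tumor mask with a stain-positive mask on the same
    grid; areas use the masks' pixel calibration.
    """
    rows = []
    areas = []
    for tumor, positive in sections:
        tumor.check_same_frame(positive)
        px = tumor.pixel_size_xy
        a_t = tumor.area_pixels * px**2
        a_p = int(np.logical_and(tumor.data, positive.data).sum()) * px**2
        rows.append({
            "tumor_area_um2": a_t,
            "positive_area_um2": a_p,
            "positive_fraction": (a_p / a_t) if a_t else 0.0,
        })
        areas.append(a_t)
    return SectionQuant(
        per_section=rows,
        total_volume_um3=section_volume(areas, thickness),
        thickness_um=thickness,
    )
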