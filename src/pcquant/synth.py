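"""Synthetic microscopy scenes with planted ground truth.

Every quantification stage in the pipeline can be verified against scenes
generated here: two-channel fields of leukocyte-like blobs with ~2 µm
protocell spheres planted inside or outside them at a controlled containment
fraction, pulsatile directional flow movies, serial cryosections of a solid
of known volume with stain-positive sub-masks, and bimodal pigmented
brightfield fields with an exact dark-pixel fraction.

Cells are rendered as smooth radial-falloff blobs rather than hard disks, so
automatic threshold choice is non-trivial, as in real fluorescence images.
Noise is shot (Poisson) plus read (Gaussian) at a stated peak-signal-to-noise
ratio; at ``snr=inf`` the image equals the noiseless render exactly.

One integer seed drives a hierarchy of independent substreams (cell
placement, protocell placement, noise), so changing the number of protocells
does not perturb cell placement.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import DegenerateSectionError, PackingError, ValidationError
from .image_model import ImageStack, Mask

#: Relative protocell density presets derived from the injected titers
#: (1.25e7 / 5e6 / 2.5e6 protocells per µL, i.e. 5 : 2 : 1).
TITER_PRESETS = {"high": 50, "medium": 20, "low": 10}

_PC_DIAMETER_UM = 2.0  # nominal protocell diameter for IV delivery


@dataclass
class SceneParams:
    """Parameters of an uptake scene (two channels: cells, protocells)."""

    n_cells: int = 50
    cell_radius_range: tuple[float, float] = (5.0, 8.0)   # µm
    n_pcs: int = 50
    pc_diameter: float = _PC_DIAMETER_UM                   # µm
    frac_cells_with_pc: float = 0.4
    pcs_per_loaded_cell_range: tuple[int, int] = (1, 3)
    field_size: tuple[float, float] = (200.0, 200.0)       # µm (y, x)
    pixel_size_xy: float = 0.5                             # µm / pixel
    snr: float = 20.0
    background: tuple[float, float] = (10.0, 5.0)          # offset, gradient amp
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 0 or self.n_pcs < 0:
            raise ValidationError("counts must be >= 0")
        if not (0.0 <= self.frac_cells_with_pc <= 1.0):
            raise ValidationError("frac_cells_with_pc must be in [0, 1]")
        if self.pc_diameter >= 2 * self.cell_radius_range[0]:
            raise ValidationError("pc_diameter must be smaller than the cell diameter")
        if self.snr <= 0:
            raise ValidationError("snr must be > 0")
        if self.pixel_size_xy <= 0:
            raise ValidationError("pixel_size_xy must be > 0")
        lo, hi = self.pcs_per_loaded_cell_range
        if lo < 1 or hi < lo:
            raise ValidationError("pcs_per_loaded_cell_range must be 1 <= lo <= hi")


@dataclass
class SceneTruth:
    """Planted ground truth emitted alongside every synthetic scene.

    All coordinates are continuous pixel coordinates in (x, y) order, in the
    same frame as the rendered image.  Only the fields relevant to the
    generating operation are populated.
    """

    pixel_size_xy: float = 1.0
    # uptake scenes
    cell_centers: np.ndarray | None = None          # (n_cells, 2) px
    cell_radii: np.ndarray | None = None            # (n_cells,) px
    pc_centers: np.ndarray | None = None            # (n_pcs, 2) px
    pc_radius: float | None = None                  # px
    pc_inside_flags: np.ndarray | None = None       # (n_pcs,) bool
    pc_owner: np.ndarray | None = None              # (n_pcs,) cell index or -1
    containment_fraction_cells: float | None = None
    # flow movies
    frame_interval: float | None = None             # s
    positions: list[np.ndarray] | None = None       # per frame (n_alive, 3): id, x, y
    displacements: list[np.ndarray] | None = None   # per step (n, 3): id, dx, dy (px)
    speeds: list[np.ndarray] | None = None          # per step (n,) µm/s
    removed: list[tuple[int, int]] | None = None    # (frame, particle id)
    # section series
    section_areas_um2: np.ndarray | None = None
    positive_fractions: np.ndarray | None = None
    analytic_volume_um3: float | None = None
    section_thickness_um: float | None = None
    # pigment fields
    dark_fraction: float | None = None
    dark_mask: np.ndarray | None = None

    def recompute_inside_flags(self) -> np.ndarray:
        """Re-derive containment flags from stored geometry.

        A protocell is inside iff its center lies within its owner's
        boundary minus one protocell radius.  Used as a self-consistency
        check on generated scenes.
        """
        flags = np.zeros(len(self.pc_centers), dtype=bool)
        for i, (c, owner) in enumerate(zip(self.pc_centers, self.pc_owner)):
            if owner < 0:
                continue
            d = np.linalg.norm(c - self.cell_centers[owner])
            flags[i] = d <= self.cell_radii[owner] - self.pc_radius
        return flags


# ---------------------------------------------------------------------------
# Rendering helpers
# ---------------------------------------------------------------------------

def _soft_blob(shape: tuple[int, int], center: np.ndarray, radius: float,
               amplitude: float, softness: float) -> np.ndarray:
    """Logistic-edged radial blob: amplitude / (1 + exp((d - r) / w))."""
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    d = np.hypot(xx - center[0], yy - center[1])
    z = np.clip((d - radius) / softness, -500.0, 500.0)
    return amplitude / (1.0 + np.exp(z))


def _render_blobs(shape, centers, radii, amplitude, softness) -> np.ndarray:
    img = np.zeros(shape, dtype=np.float64)
    for c, r in zip(centers, np.broadcast_to(np.atleast_1d(radii), (len(centers),))):
        img += _soft_blob(shape, c, r, amplitude, softness)
    return img


def _background(shape, offset: float, gradient_amp: float) -> np.ndarray:
    ramp = np.linspace(0.0, 1.0, shape[1])[None, :]
    return offset + gradient_amp * ramp * np.ones((shape[0], 1))


def add_noise(render: np.ndarray, snr: float, rng: np.random.Generator) -> np.ndarray:
    """Poisson shot noise plus Gaussian read noise at a peak SNR.

    The total noise standard deviation at the peak signal equals
    ``peak / snr``, split evenly (in variance) between the shot and read
    components.  ``snr=inf`` returns the render unchanged.
    """
    if math.isinf(snr):
        return render.astype(np.float32)
    peak = float(render.max())
    if peak <= 0:
        return render.astype(np.float32)
    sigma_tot = peak / snr
    gain = 2.0 * peak / sigma_tot**2        # photons per intensity unit
    shot = rng.poisson(np.clip(render, 0, None) * gain) / gain
    read = rng.normal(0.0, sigma_tot / math.sqrt(2.0), size=render.shape)
    return (shot + read).astype(np.float32)


def _substreams(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


# ---------------------------------------------------------------------------
# Uptake scene
# ---------------------------------------------------------------------------

def gen_uptake_scene(params: SceneParams) -> tuple[ImageStack, SceneTruth]:
    """Two-channel field: cell blobs (ch 0) and protocell spheres (ch 1).

    Exactly ``round(frac_cells_with_pc * n_cells)`` cells own at least one
    protocell; the remaining protocells are placed outside every cell with a
    clearance margin of at least one protocell radius.  Placement uses
    bounded rejection sampling and raises :class:`PackingError` when the
    requested counts do not fit the field.
    """
    p = params
    px = p.pixel_size_xy
    shape = (int(round(p.field_size[0] / px)), int(round(p.field_size[1] / px)))
    rng_cells, rng_pcs, rng_noise = _substreams(p.seed, 3)
    r_pc = p.pc_diameter / 2.0 / px
    gap = 7.0  # px clearance between rendered objects so detections never merge

    # -- cells ------------------------------------------------------------
    centers: list[np.ndarray] = []
    radii: list[float] = []
    max_tries = 2000
    for _ in range(p.n_cells):
        for attempt in range(max_tries):
            r = rng_cells.uniform(*p.cell_radius_range) / px
            margin = r + gap
            c = rng_cells.uniform([margin, margin],
                                  [shape[1] - margin, shape[0] - margin])
            if all(np.linalg.norm(c - c2) > r + r2 + gap
                   for c2, r2 in zip(centers, radii)):
                centers.append(c)
                radii.append(r)
                break
        else:
            raise PackingError(
                f"could not place cell {len(centers) + 1}/{p.n_cells} "
                f"in a {shape} px field"
            )
    cell_centers = np.array(centers).reshape(-1, 2)
    cell_radii = np.array(radii)

    # -- protocell assignment --------------------------------------------
    n_loaded = int(round(p.frac_cells_with_pc * p.n_cells))
    if n_loaded > p.n_pcs:
        raise ValidationError(
            f"{n_loaded} cells must hold >= 1 protocell but only {p.n_pcs} exist"
        )
    loaded = rng_pcs.choice(p.n_cells, size=n_loaded, replace=False) if n_loaded else []
    lo, hi = p.pcs_per_loaded_cell_range
    per_cell = rng_pcs.integers(lo, hi + 1, size=n_loaded)
    while per_cell.sum() > p.n_pcs:
        reducible = np.flatnonzero(per_cell > 1)
        per_cell[rng_pcs.choice(reducible)] -= 1

    pc_centers: list[np.ndarray] = []
    pc_owner: list[int] = []
    for cell_idx, count in zip(loaded, per_cell):
        cc, cr = cell_centers[cell_idx], cell_radii[cell_idx]
        placed_here: list[np.ndarray] = []
        for _ in range(int(count)):
            for attempt in range(max_tries):
                rad = (cr - r_pc) * math.sqrt(rng_pcs.uniform())
                ang = rng_pcs.uniform(0, 2 * math.pi)
                c = cc + rad * np.array([math.cos(ang), math.sin(ang)])
                # keep co-internalized protocells resolvable after thresholding
                if all(np.linalg.norm(c - q) > 2 * r_pc + 3.0 for q in placed_here):
                    placed_here.append(c)
                    pc_centers.append(c)
                    pc_owner.append(int(cell_idx))
                    break
            else:
                raise PackingError(
                    f"could not place {count} protocells inside cell {cell_idx}"
                )

    n_outside = p.n_pcs - len(pc_centers)
    outside: list[np.ndarray] = []
    for _ in range(n_outside):
        for attempt in range(max_tries):
            margin = r_pc + gap
            c = rng_pcs.uniform([margin, margin],
                                [shape[1] - margin, shape[0] - margin])
            clear_of_cells = all(
                np.linalg.norm(c - cc) > cr + 2 * r_pc
                for cc, cr in zip(cell_centers, cell_radii)
            )
            clear_of_pcs = all(
                np.linalg.norm(c - q) > 2 * r_pc + gap
                for q in outside + pc_centers[: len(pc_centers)]
            )
            if clear_of_cells and clear_of_pcs:
                outside.append(c)
                break
        else:
            raise PackingError(f"could not place outside protocell {len(outside)+1}")
    pc_centers.extend(outside)
    pc_owner.extend([-1] * n_outside)
    pc_centers_arr = np.array(pc_centers).reshape(-1, 2)
    pc_owner_arr = np.array(pc_owner, dtype=int)
    inside_flags = pc_owner_arr >= 0

    # -- render -----------------------------------------------------------
    bg = _background(shape, *p.background)
    ch_cells = bg + _render_blobs(shape, cell_centers, cell_radii,
                                  amplitude=150.0, softness=1.5)
    ch_pcs = bg + _render_blobs(shape, pc_centers_arr,
                                np.full(len(pc_centers_arr), r_pc),
                                amplitude=200.0, softness=0.5)
    data = np.stack([
        add_noise(ch_cells, p.snr, rng_noise),
        add_noise(ch_pcs, p.snr, rng_noise),
    ])
    stack = ImageStack(
        data=data, axes="cyx", pixel_size_xy=px,
        channel_names=["cells", "pcs"],
    )
    truth = SceneTruth(
        pixel_size_xy=px,
        cell_centers=cell_centers,
        cell_radii=cell_radii,
        pc_centers=pc_centers_arr,
        pc_radius=r_pc,
        pc_inside_flags=inside_flags,
        pc_owner=pc_owner_arr,
        containment_fraction_cells=(n_loaded / p.n_cells) if p.n_cells else 0.0,
    )
    return stack, truth


# ---------------------------------------------------------------------------
# Flow movie
# ---------------------------------------------------------------------------

def gen_flow_movie(
    n_particles: int = 10,
    speed_mean: float = 10.0,          # µm/s
    speed_pulsatility: float = 0.2,    # relative amplitude
    direction_deg: float = 0.0,        # 0 = +x ("left to right")
    n_frames: int = 100,
    frame_interval: float = 0.1,       # s
    field_size: tuple[float, float] = (50.0, 200.0),  # µm (y, x)
    pixel_size_xy: float = 0.5,
    snr: float = 20.0,
    pulse_freq: float = 2.5,           # Hz, heartbeat-like
    seed: int = 0,
) -> tuple[ImageStack, SceneTruth]:
    """Movie of particles advected along one direction with pulsatile speed.

    The speed at step ``i`` is ``speed_mean * (1 + a * sin(2*pi*f*t_i))``
    with ``t_i = i * frame_interval``; each particle advances by exactly
    ``speed_i * dt`` along ``direction_deg``.  Particles leaving the field
    are removed and logged.  Ground truth stores per-frame positions,
    per-step displacement vectors (px) and instantaneous speeds (µm/s).
    """
    if n_frames < 2:
        raise ValidationError("n_frames must be >= 2")
    if speed_pulsatility < 0 or speed_mean < 0:
        raise ValidationError("speeds must be >= 0")
    px = pixel_size_xy
    shape = (int(round(field_size[0] / px)), int(round(field_size[1] / px)))
    rng_init, rng_noise = _substreams(seed, 2)

    theta = math.radians(direction_deg)
    unit = np.array([math.cos(theta), math.sin(theta)])  # (x, y), y down
    margin = 4.0
    pos = rng_init.uniform(
        [margin, margin], [shape[1] - margin, shape[0] - margin],
        size=(n_particles, 2),
    )
    ids = np.arange(n_particles)

    positions: list[np.ndarray] = []
    displacements: list[np.ndarray] = []
    speeds: list[np.ndarray] = []
    removed: list[tuple[int, int]] = []
    frames = np.zeros((n_frames, *shape), dtype=np.float64)

    def render(frame_idx: int) -> None:
        img = np.full(shape, 10.0)
        for c in pos:
            img += _soft_blob(shape, c, radius=1.5, amplitude=200.0, softness=0.5)
        frames[frame_idx] = img

    render(0)
    positions.append(np.column_stack([ids, pos]).copy())
    for i in range(n_frames - 1):
        t_i = i * frame_interval
        v = speed_mean * (1.0 + speed_pulsatility * math.sin(2 * math.pi * pulse_freq * t_i))
        step_px = v * frame_interval / px
        disp = unit * step_px
        pos = pos + disp
        inside = (
            (pos[:, 0] >= 0) & (pos[:, 0] <= shape[1] - 1)
            & (pos[:, 1] >= 0) & (pos[:, 1] <= shape[0] - 1)
        )
        for pid in ids[~inside]:
            removed.append((i + 1, int(pid)))
        displacements.append(
            np.column_stack([ids[inside], np.tile(disp, (int(inside.sum()), 1))])
        )
        speeds.append(np.full(int(inside.sum()), v))
        ids = ids[inside]
        pos = pos[inside]
        render(i + 1)
        positions.append(np.column_stack([ids, pos]).copy())

    noisy = np.stack([add_noise(f, snr, rng_noise) for f in frames])
    stack = ImageStack(
        data=noisy, axes="tyx", pixel_size_xy=px,
        frame_interval=frame_interval, channel_names=["pcs"],
    )
    truth = SceneTruth(
        pixel_size_xy=px,
        frame_interval=frame_interval,
        positions=positions,
        displacements=displacements,
        speeds=speeds,
        removed=removed,
    )
    return stack, truth


# ---------------------------------------------------------------------------
# Serial sections
# ---------------------------------------------------------------------------

def gen_section_series(
    shape: dict,
    section_thickness: float = 10.0,    # µm
    positive_fraction: float = 0.0,
    pixel_size: float = 0.5,            # µm
    seed: int = 0,
) -> tuple[list[tuple[Mask, Mask]], SceneTruth]:
    """Serial cross-sections of a sphere or ellipsoid of known volume.

    ``shape`` is ``{"sphere": r}`` or ``{"ellipsoid": (a, b, c)}`` with
    semi-axes in µm (the solid is sectioned along its last axis).  Section
    ``k``'s tumor mask is the rasterized cross-section at depth
    ``(k + 1/2) * thickness``; the positive mask marks a random subset of
    tumor pixels matching ``positive_fraction`` to within one pixel.
    """
    if "sphere" in shape:
        r = float(shape["sphere"])
        a = b = c = r
    elif "ellipsoid" in shape:
        a, b, c = (float(v) for v in shape["ellipsoid"])
    else:
        raise ValidationError(f"unknown shape {shape!r}")
    if not (0.0 <= positive_fraction <= 1.0):
        raise ValidationError("positive_fraction must be in [0, 1]")
    extent = 2.0 * c
    if section_thickness >= extent:
        raise DegenerateSectionError(
            f"thickness {section_thickness} µm >= solid extent {extent} µm"
        )
    n_sections = int(math.ceil(extent / section_thickness))
    margin = 2.0  # µm
    w = int(math.ceil(2 * (a + margin) / pixel_size))
    h = int(math.ceil(2 * (b + margin) / pixel_size))
    cx, cy = (w - 1) / 2.0, (h - 1) / 2.0
    yy, xx = np.mgrid[:h, :w]
    (rng,) = _substreams(seed, 1)

    pairs: list[tuple[Mask, Mask]] = []
    areas = []
    realized_fracs = []
    for k in range(n_sections):
        depth = (k + 0.5) * section_thickness
        scale = 1.0 - ((depth - c) / c) ** 2
        if scale <= 0:
            tumor = np.zeros((h, w), dtype=bool)
        else:
            ax = a * math.sqrt(scale) / pixel_size
            by = b * math.sqrt(scale) / pixel_size
            tumor = ((xx - cx) / ax) ** 2 + ((yy - cy) / by) ** 2 <= 1.0
        n_tumor = int(tumor.sum())
        positive = np.zeros((h, w), dtype=bool)
        if n_tumor and positive_fraction > 0:
            n_pos = int(round(positive_fraction * n_tumor))
            idx = np.flatnonzero(tumor.ravel())
            chosen = rng.choice(idx, size=n_pos, replace=False)
            positive.ravel()[chosen] = True
        pairs.append((
            Mask(data=tumor, pixel_size_xy=pixel_size),
            Mask(data=positive, pixel_size_xy=pixel_size),
        ))
        areas.append(n_tumor * pixel_size**2)
        realized_fracs.append((positive.sum() / n_tumor) if n_tumor else 0.0)

    truth = SceneTruth(
        pixel_size_xy=pixel_size,
        section_areas_um2=np.array(areas),
        positive_fractions=np.array(realized_fracs),
        analytic_volume_um3=4.0 / 3.0 * math.pi * a * b * c,
        section_thickness_um=section_thickness,
    )
    return pairs, truth


# ---------------------------------------------------------------------------
# Pigment field
# ---------------------------------------------------------------------------

def gen_pigment_image(
    dark_fraction: float,
    field_shape: tuple[int, int] = (100, 100),  # px (y, x)
    pixel_size_xy: float = 1.0,
    seed: int = 0,
) -> tuple[ImageStack, SceneTruth]:
    """Bimodal brightfield image with an exact planted dark-pixel fraction.

    A smoothed random field is thresholded at its ``dark_fraction`` quantile
    so exactly ``round(dark_fraction * n_pixels)`` pixels are dark (pigment,
    intensity ~40) and the rest bright (~200), giving spatially coherent
    pigment patches.  Mild within-class jitter keeps the histogram bimodal
    but non-degenerate.
    """
    if not (0.0 <= dark_fraction <= 1.0):
        raise ValidationError("dark_fraction must be in [0, 1]")
    from scipy import ndimage as ndi

    rng_field, rng_jitter = _substreams(seed, 2)
    h, w = field_shape
    n = h * w
    k = int(round(dark_fraction * n))
    smooth = ndi.gaussian_filter(rng_field.normal(size=(h, w)), sigma=5.0)
    order = np.argsort(smooth.ravel(), kind="stable")
    dark = np.zeros(n, dtype=bool)
    dark[order[:k]] = True
    dark = dark.reshape(h, w)
    img = np.where(dark, 40.0, 200.0) + rng_jitter.normal(0.0, 3.0, size=(h, w))
    stack = ImageStack(
        data=img.astype(np.float32), axes="yx", pixel_size_xy=pixel_size_xy,
        channel_names=["brightfield"],
    )
    truth = SceneTruth(
        pixel_size_xy=pixel_size_xy,
        dark_fraction=k / n,
        dark_mask=dark,
    )
    return stack, truth
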