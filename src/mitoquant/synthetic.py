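"""Synthetic microscopy and plate-reader data with exact ground truth.

Every generator returns rendered data plus a :class:`GroundTruthManifest`
so that each downstream quantifier can be validated by recovering the
manifest from pixels alone. Rendering choices are made for exact
invertibility at zero noise rather than optical realism:

* Fluorescent particles are diffraction-blurred spots drawn as discrete
  2-D Gaussians whose FWHM equals the particle diameter. Each kernel is
  renormalised to unit discrete sum, so a particle of amplitude *A*
  deposits exactly *A* integrated counts into the frame no matter its
  sub-pixel position.
* Transmitted-light particles attenuate a uniform illumination field with
  a flat-transmittance core and a smooth cosine rim, so the darkest
  fixed-area region inside the core reads the requested transmittance
  ratio exactly at zero noise (particles >= ~1.4 um at the 40x pixel
  size; the swelling presets use 1.5-3 um).
* All randomness flows through one ``numpy`` Generator seeded from the
  config: identical seed + config gives bit-identical arrays.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull
from skimage.draw import polygon as draw_polygon

from .config import SimConfig
from .images import ImageBundle
from .manifest import GroundTruthManifest, ObjectTruth

FWHM_PER_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))

# Axial extent of the defocus envelope used for transmitted-light stacks.
AXIAL_SIGMA_UM = 0.6

# Illumination level of transmitted-light stacks (arbitrary units).
TRANSMITTED_I0 = 1000.0


# ---------------------------------------------------------------------------
# event / swelling specifications


@dataclass(frozen=True)
class CalceinEvent:
    """A calcein-release event for one mitochondrion.

    ``mode="step"`` drops the integrated intensity abruptly at ``frame``
    (permeability-transition-like); ``mode="ramp"`` declines linearly from
    ``frame`` to the last frame by the same total fraction (negative
    control: slow leakage that the per-interval rule must not flag).
    """

    frame: int
    drop_fraction: float
    mode: str = "step"

    def __post_init__(self) -> None:
        if self.mode not in ("step", "ramp"):
            raise ValueError(f"unknown event mode {self.mode!r}")
        if not (0.0 < self.drop_fraction <= 1.0):
            raise ValueError("drop_fraction must be in (0, 1]")


@dataclass(frozen=True)
class SwellSpec:
    """Transmittance trajectory of one mitochondrion.

    ``post == baseline`` (or ``onset_min is None``) means no swelling.
    """

    baseline: float
    post: float
    onset_min: float | None = None

    def __post_init__(self) -> None:
        for name, v in (("baseline", self.baseline), ("post", self.post)):
            if not (0.0 < v <= 1.0):
                raise ValueError(f"transmittance {name}={v} outside (0, 1]")

    @property
    def swells(self) -> bool:
        return self.onset_min is not None and self.post != self.baseline

    def value_at(self, t_min: float) -> float:
        if self.onset_min is not None and t_min >= self.onset_min:
            return self.post
        return self.baseline


# ---------------------------------------------------------------------------
# low-level rendering


def sigma_px(diameter_um: float, pixel_size_um: float) -> float:
    """Gaussian sigma (pixels) whose FWHM equals the particle diameter."""
    return diameter_um / pixel_size_um / FWHM_PER_SIGMA


def kernel_radius_px(diameter_um: float, pixel_size_um: float) -> int:
    """Half-width of the discrete render window for a spot of this size."""
    return int(math.ceil(3.5 * sigma_px(diameter_um, pixel_size_um))) + 1


def render_spot(
    field: np.ndarray,
    center: tuple[float, float],
    diameter_um: float,
    amplitude: float,
    pixel_size_um: float,
) -> None:
    """Add a unit-sum Gaussian spot of integrated ``amplitude`` in place."""
    s = sigma_px(diameter_um, pixel_size_um)
    r = kernel_radius_px(diameter_um, pixel_size_um)
    cr, cc = center
    r0, r1 = int(math.floor(cr)) - r, int(math.floor(cr)) + r + 1
    c0, c1 = int(math.floor(cc)) - r, int(math.floor(cc)) + r + 1
    r0, r1 = max(r0, 0), min(r1, field.shape[0])
    c0, c1 = max(c0, 0), min(c1, field.shape[1])
    if r0 >= r1 or c0 >= c1:
        raise ValueError(f"spot at {center} lies outside the field")
    rows = np.arange(r0, r1)[:, None]
    cols = np.arange(c0, c1)[None, :]
    kernel = np.exp(-((rows - cr) ** 2 + (cols - cc) ** 2) / (2.0 * s * s))
    kernel /= kernel.sum()  # exact integrated amplitude, even when clipped
    field[r0:r1, c0:c1] += amplitude * kernel


def _transmittance_profile(
    shape: tuple[int, int],
    center: tuple[float, float],
    diameter_um: float,
    pixel_size_um: float,
) -> tuple[slice, slice, np.ndarray]:
    """Radial opacity profile in [0, 1]: 1 inside the flat core, cosine rim.

    Returns a window and the profile within it; the attenuated image is
    ``I0 * (1 - (1 - T) * profile)`` for target core transmittance ``T``.
    """
    r_px = 0.5 * diameter_um / pixel_size_um
    core = 0.75 * r_px
    rim = 0.45 * r_px
    extent = int(math.ceil(core + rim)) + 1
    cr, cc = center
    r0 = max(int(math.floor(cr)) - extent, 0)
    r1 = min(int(math.floor(cr)) + extent + 1, shape[0])
    c0 = max(int(math.floor(cc)) - extent, 0)
    c1 = min(int(math.floor(cc)) + extent + 1, shape[1])
    rows = np.arange(r0, r1)[:, None]
    cols = np.arange(c0, c1)[None, :]
    rad = np.hypot(rows - cr, cols - cc)
    prof = np.zeros(rad.shape)
    prof[rad <= core] = 1.0
    on_rim = (rad > core) & (rad < core + rim)
    prof[on_rim] = 0.5 * (1.0 + np.cos(math.pi * (rad[on_rim] - core) / rim))
    return slice(r0, r1), slice(c0, c1), prof


# ---------------------------------------------------------------------------
# placement


def _check_centers(
    centers: Sequence[tuple[float, float]], diameters_px: Sequence[float]
) -> None:
    """Reject spot centers closer than one diameter: per-object truth must
    stay unambiguous."""
    for i in range(len(centers)):
        for j in range(i + 1, len(centers)):
            d = math.hypot(
                centers[i][0] - centers[j][0], centers[i][1] - centers[j][1]
            )
            if d < max(diameters_px[i], diameters_px[j]):
                raise ValueError(
                    f"objects {i} and {j} overlap: separation {d:.1f} px is "
                    f"below one diameter"
                )


def _place_centers(
    rng: np.random.Generator,
    shape: tuple[int, int],
    diameters_px: Sequence[float],
    margin_px: float,
    sep_extra_px: float,
    forbidden: np.ndarray | None = None,
    max_tries: int = 20000,
    max_restarts: int = 5,
) -> list[tuple[float, float]]:
    """Sequential rejection sampling of non-overlapping spot centers.

    Sequential placement can paint itself into a corner on crowded
    fields, so a failed pass restarts from scratch a few times before
    giving up."""
    for _restart in range(max_restarts):
        centers: list[tuple[float, float]] = []
        for d in diameters_px:
            m = margin_px + 0.5 * d
            if shape[0] - 2 * m <= 1 or shape[1] - 2 * m <= 1:
                raise ValueError("field too small to place objects without overlap")
            for _ in range(max_tries):
                cr = rng.uniform(m, shape[0] - m)
                cc = rng.uniform(m, shape[1] - m)
                if forbidden is not None and forbidden[int(cr), int(cc)]:
                    continue
                ok = all(
                    math.hypot(cr - pr, cc - pc)
                    >= 0.5 * (d + pd) + sep_extra_px
                    for (pr, pc), pd in zip(centers, diameters_px)
                )
                if ok:
                    centers.append((cr, cc))
                    break
            else:
                break  # this pass failed; restart
        else:
            return centers
    raise ValueError("field too small to place objects without overlap")


def _amplitudes(
    rng: np.random.Generator, n: int, base: float, cv: float
) -> np.ndarray:
    if cv <= 0:
        return np.full(n, base)
    # clip far tail so amplitudes stay strictly positive
    return base * np.clip(1.0 + cv * rng.standard_normal(n), 0.05, None)


def _exact_subset(rng: np.random.Generator, n: int, fraction: float) -> np.ndarray:
    """Boolean mask with exactly round(fraction * n) True entries."""
    k = int(round(fraction * n))
    if not 0 <= k <= n:
        raise ValueError("fraction outside [0, 1]")
    mask = np.zeros(n, dtype=bool)
    mask[rng.choice(n, size=k, replace=False)] = True
    return mask


# ---------------------------------------------------------------------------
# calcein time-lapse


def expected_calcein_amplitude(obj: ObjectTruth, frame: int, n_frames: int) -> float:
    """Manifest-truth integrated intensity of one mitochondrion at ``frame``."""
    a = float(obj.amplitude)
    if obj.mpt_event_frame is None:
        return a
    f0, drop = obj.mpt_event_frame, float(obj.drop_fraction)
    if frame < f0:
        return a
    if obj.event_mode == "ramp" and n_frames - 1 > f0:
        prog = min((frame - f0) / (n_frames - 1 - f0), 1.0)
        return a * (1.0 - drop * prog)
    return a * (1.0 - drop)


def gen_calcein_timelapse(
    config: SimConfig,
    n_mito: int,
    events: Sequence[CalceinEvent | None] | None = None,
    *,
    event_fraction: float | None = None,
    drop_range: tuple[float, float] = (0.5, 0.8),
    diameters_um: Sequence[float] | None = None,
    centers: Sequence[tuple[float, float]] | None = None,
    amplitude: float = 1000.0,
    amplitude_cv: float = 0.0,
) -> tuple[ImageBundle, GroundTruthManifest]:
    """Render a calcein time-lapse of adsorbed mitochondria.

    Each mitochondrion is a stationary diffraction-blurred spot; at its
    event frame its integrated intensity drops abruptly by the specified
    fraction (calcein release through the opened permeability pore).
    When ``events`` is None and ``event_fraction`` is given, exactly
    ``round(event_fraction * n_mito)`` objects receive a step event at a
    frame >= 6 min (the Ca2+ trigger is added at t = 5 min, between the
    4- and 6-min frames) with drop fractions uniform in ``drop_range``.
    """
    if n_mito < 0:
        raise ValueError("n_mito must be >= 0")
    rng = np.random.default_rng(config.seed)
    shape = config.field_shape

    if diameters_um is None:
        lo, hi = config.particle_diameter_um
        diameters_um = rng.uniform(lo, hi, n_mito)
    diameters_um = np.asarray(diameters_um, dtype=float)
    d_px = diameters_um / config.pixel_size_um
    max_r = (
        max((kernel_radius_px(d, config.pixel_size_um) for d in diameters_um), default=3)
    )

    if centers is None:
        centers = _place_centers(
            rng, shape, d_px, margin_px=max_r + 2.0, sep_extra_px=max_r + 4.0
        )
    else:
        centers = [tuple(c) for c in centers]
        _check_centers(centers, d_px)

    if events is None:
        events = [None] * n_mito
        if event_fraction is not None:
            first_frame = max(
                1, int(math.ceil(6.0 / config.frame_interval_min))
            )  # trigger added at t = 5 min
            if first_frame > config.n_frames - 1:
                raise ValueError("too few frames for post-trigger events")
            which = _exact_subset(rng, n_mito, event_fraction)
            frames = rng.integers(first_frame, config.n_frames, size=n_mito)
            drops = rng.uniform(*drop_range, size=n_mito)
            events = [
                CalceinEvent(int(f), float(dr)) if w else None
                for w, f, dr in zip(which, frames, drops)
            ]
    if len(events) != n_mito:
        raise ValueError("events must have one entry per mitochondrion")
    for ev in events:
        if ev is not None and not (1 <= ev.frame <= config.n_frames - 1):
            raise ValueError(f"event frame {ev.frame} outside 1..{config.n_frames - 1}")

    amps = _amplitudes(rng, n_mito, amplitude, amplitude_cv)
    objects = [
        ObjectTruth(
            object_id=f"mito_{i:03d}",
            obj_class="mitochondrion",
            center=centers[i],
            diameter_um=float(diameters_um[i]),
            amplitude=float(amps[i]),
            mpt_event_frame=None if events[i] is None else events[i].frame,
            drop_fraction=None if events[i] is None else events[i].drop_fraction,
            event_mode=None if events[i] is None else events[i].mode,
        )
        for i in range(n_mito)
    ]

    frames = np.full((config.n_frames,) + shape, config.background, dtype=float)
    for t in range(config.n_frames):
        for obj in objects:
            render_spot(
                frames[t],
                obj.center,
                obj.diameter_um,
                expected_calcein_amplitude(obj, t, config.n_frames),
                config.pixel_size_um,
            )
        if config.noise_sd > 0:
            frames[t] += rng.normal(0.0, config.noise_sd, shape)

    bundle = ImageBundle(
        frames=frames,
        channel="calcein",
        timepoints_min=np.asarray(config.timepoints_min),
        pixel_size_um=config.pixel_size_um,
    )
    manifest = GroundTruthManifest(
        objects=objects,
        extras={"background": config.background, "amplitude": amplitude},
    )
    return bundle, manifest


# ---------------------------------------------------------------------------
# transmitted-light z-stacks


def gen_transmittance_zstacks(
    config: SimConfig,
    n_mito: int,
    swell: Sequence[SwellSpec] | None = None,
    *,
    swollen_fraction: float | None = None,
    stack_times_min: Sequence[float] = (0.0, 10.0),
    baseline_range: tuple[float, float] = (0.55, 0.70),
    swell_delta_range: tuple[float, float] = (0.18, 0.28),
    onset_min: float = 5.0,
    diameters_um: Sequence[float] | None = None,
) -> tuple[list[ImageBundle], GroundTruthManifest]:
    """Render repeated transmitted-light z-stacks of adsorbed mitochondria.

    Each particle attenuates a uniform illumination field so that the
    mean over the darkest fixed-area region of its in-focus slice equals
    the requested transmittance ratio against a blank of 1. Swelling
    raises transmittance from ``baseline`` to ``post`` at its onset time
    (matrix expansion reduces optical density).
    """
    if n_mito < 0:
        raise ValueError("n_mito must be >= 0")
    stack_times = [float(t) for t in stack_times_min]
    if sorted(stack_times) != stack_times:
        raise ValueError("stack_times_min must be increasing")
    rng = np.random.default_rng(config.seed)
    shape = config.field_shape

    if diameters_um is None:
        lo, hi = config.particle_diameter_um
        diameters_um = rng.uniform(lo, hi, n_mito)
    diameters_um = np.asarray(diameters_um, dtype=float)
    d_px = diameters_um / config.pixel_size_um

    centers = _place_centers(
        rng, shape, 1.2 * d_px, margin_px=float(d_px.max() if n_mito else 2.0) + 4.0,
        sep_extra_px=12.0,
    )

    if swell is None:
        if swollen_fraction is None:
            swollen_fraction = 0.0
        which = _exact_subset(rng, n_mito, swollen_fraction)
        baselines = rng.uniform(*baseline_range, size=n_mito)
        deltas = rng.uniform(*swell_delta_range, size=n_mito)
        swell = [
            SwellSpec(
                baseline=float(b),
                post=float(min(b + dl, 0.99)) if w else float(b),
                onset_min=onset_min if w else None,
            )
            for b, dl, w in zip(baselines, deltas, which)
        ]
    if len(swell) != n_mito:
        raise ValueError("swell must have one entry per mitochondrion")

    mid = config.n_slices // 2
    focus = (
        mid + rng.integers(-2, 3, size=n_mito)
        if config.n_slices >= 5
        else np.full(n_mito, mid)
    )
    focus = np.clip(focus, 0, config.n_slices - 1)

    objects = [
        ObjectTruth(
            object_id=f"mito_{i:03d}",
            obj_class="mitochondrion",
            center=centers[i],
            diameter_um=float(diameters_um[i]),
            transmittance_baseline=swell[i].baseline,
            transmittance_post=swell[i].post,
            swelling_onset_min=swell[i].onset_min if swell[i].swells else None,
            focus_slice=int(focus[i]),
        )
        for i in range(n_mito)
    ]

    profiles = [
        _transmittance_profile(shape, centers[i], diameters_um[i], config.pixel_size_um)
        for i in range(n_mito)
    ]
    z_um = np.arange(config.n_slices) * config.z_step_um
    bundles = []
    for t_min in stack_times:
        stack = np.full((config.n_slices,) + shape, TRANSMITTED_I0, dtype=float)
        for i, obj in enumerate(objects):
            t_val = swell[i].value_at(t_min)
            rs, cs, prof = profiles[i]
            dz = (z_um - z_um[focus[i]])
            w = np.exp(-(dz**2) / (2.0 * AXIAL_SIGMA_UM**2))
            for z in range(config.n_slices):
                stack[z, rs, cs] -= TRANSMITTED_I0 * (1.0 - t_val) * w[z] * prof
        if config.noise_sd > 0:
            stack += rng.normal(0.0, config.noise_sd, stack.shape)
        bundles.append(
            ImageBundle(
                frames=stack[None, ...],
                channel="transmitted",
                timepoints_min=[t_min],
                z_positions_um=z_um,
                pixel_size_um=config.pixel_size_um,
            )
        )
    manifest = GroundTruthManifest(
        objects=objects,
        extras={"illumination": TRANSMITTED_I0, "stack_times_min": stack_times},
    )
    return bundles, manifest


# ---------------------------------------------------------------------------
# two-channel uptake / polarization fields


def gen_uptake_field(
    config: SimConfig,
    n_cells: int,
    per_cell_counts: Sequence[int],
    n_free_particles: int,
    *,
    free_polarized_fraction: float = 1.0,
    implanted_polarized_fraction: float = 0.0,
    intensity_cv: float = 0.0,
    free_diameters_um: Sequence[float] | None = None,
    punctum_diameter_um: float = 1.0,
    amplitude: float = 600.0,
    tmre_amplitude: float = 2000.0,
    cell_radius_um: float = 12.0,
    cell_autofluorescence: float = 30.0,
) -> tuple[dict[str, ImageBundle], GroundTruthManifest]:
    """Render a GFP/TMRE field of cells with implanted puncta plus free
    extracellular mitochondria.

    Implanted GFP puncta share one reference amplitude (up to
    ``intensity_cv`` dispersion) with the free particles, so the
    intensity-ratio counting estimator is unbiased by construction. The
    TMRE channel renders polarized objects only; by default free
    particles are polarized and internalized ones are not, matching the
    observation that internalized mitochondria lack membrane potential.
    Each cell keeps a puncta-free internal disk recorded in the manifest
    for background estimation.
    """
    if n_cells < 0 or n_free_particles < 0:
        raise ValueError("counts must be >= 0")
    if len(per_cell_counts) != n_cells:
        raise ValueError("per_cell_counts must have one entry per cell")
    if any(c < 0 for c in per_cell_counts):
        raise ValueError("per-cell counts must be >= 0")
    rng = np.random.default_rng(config.seed)
    shape = config.field_shape
    px = config.pixel_size_um
    r_cell = cell_radius_um / px
    r_k = kernel_radius_px(punctum_diameter_um, px)

    # --- cells on a jittered grid
    cell_objs: list[ObjectTruth] = []
    cell_masks: list[np.ndarray] = []
    if n_cells:
        n_cols = int(math.ceil(math.sqrt(n_cells)))
        n_rows = int(math.ceil(n_cells / n_cols))
        pitch_r = shape[0] / n_rows
        pitch_c = shape[1] / n_cols
        if min(pitch_r, pitch_c) < 2.35 * r_cell:
            raise ValueError("field too small to place cells without overlap")
        for i in range(n_cells):
            gr, gc = divmod(i, n_cols)
            cr = (gr + 0.5) * pitch_r + rng.uniform(-2, 2)
            cc = (gc + 0.5) * pitch_c + rng.uniform(-2, 2)
            ang = np.sort(rng.uniform(0, 2 * math.pi, 12))
            rad = rng.uniform(0.82, 1.0, 12) * r_cell
            pts = np.column_stack(
                [cr + rad * np.sin(ang), cc + rad * np.cos(ang)]
            )
            hull = ConvexHull(pts)
            verts = pts[hull.vertices]
            rr, ccol = draw_polygon(verts[:, 0], verts[:, 1], shape)
            mask = np.zeros(shape, dtype=bool)
            mask[rr, ccol] = True
            cell_masks.append(mask)
            cell_objs.append(
                ObjectTruth(
                    object_id=f"cell_{i:03d}",
                    obj_class="cell",
                    center=(float(cr), float(cc)),
                    polygon=[(float(a), float(b)) for a, b in verts],
                    implanted_count=int(per_cell_counts[i]),
                )
            )

    # --- implanted puncta with a reserved background disk per cell
    from scipy import ndimage

    punctum_objs: list[ObjectTruth] = []
    n_total_puncta = int(sum(per_cell_counts))
    impl_pol = (
        _exact_subset(rng, n_total_puncta, implanted_polarized_fraction)
        if n_total_puncta
        else np.zeros(0, dtype=bool)
    )
    amps_puncta = _amplitudes(rng, n_total_puncta, amplitude, intensity_cv)
    p_idx = 0
    for ci, (obj, mask) in enumerate(zip(cell_objs, cell_masks)):
        edt = ndimage.distance_transform_edt(mask)
        bd_r, bd_c = np.unravel_index(np.argmax(edt), edt.shape)
        bd_rad = float(min(4.0, edt[bd_r, bd_c] - 1.0))
        if bd_rad < 2.0:
            raise ValueError("field too small to place objects without overlap")
        cell_objs[ci] = ObjectTruth(
            **{
                **obj.__dict__,
                "background_disk": (float(bd_r), float(bd_c), bd_rad),
            }
        )
        allowed = edt > (r_k + 1)
        rows_g, cols_g = np.indices(shape)
        # keep the full punctum kernel support out of the background disk
        allowed &= np.hypot(rows_g - bd_r, cols_g - bd_c) > (bd_rad + r_k + 1)
        cand = np.argwhere(allowed)
        if len(cand) < 5 * max(per_cell_counts[ci], 1):
            raise ValueError("field too small to place objects without overlap")
        placed: list[tuple[float, float]] = []
        for _ in range(per_cell_counts[ci]):
            for _try in range(5000):
                pr, pc = cand[rng.integers(len(cand))]
                pr, pc = pr + rng.uniform(-0.5, 0.5), pc + rng.uniform(-0.5, 0.5)
                if all(math.hypot(pr - a, pc - b) >= 3.0 for a, b in placed):
                    placed.append((float(pr), float(pc)))
                    break
            else:
                raise ValueError("field too small to place objects without overlap")
            punctum_objs.append(
                ObjectTruth(
                    object_id=f"punctum_{p_idx:03d}",
                    obj_class="punctum",
                    center=placed[-1],
                    diameter_um=punctum_diameter_um,
                    amplitude=float(amps_puncta[p_idx]),
                    polarized=bool(impl_pol[p_idx]),
                    cell_id=cell_objs[ci].object_id,
                )
            )
            p_idx += 1

    # --- free extracellular particles
    if free_diameters_um is None:
        free_diameters_um = rng.uniform(1.0, 2.0, n_free_particles)
    free_diameters_um = np.asarray(free_diameters_um, dtype=float)
    if len(free_diameters_um) != n_free_particles:
        raise ValueError("free_diameters_um must have one entry per particle")
    max_rk = (
        max(
            (kernel_radius_px(d, px) for d in free_diameters_um),
            default=r_k,
        )
    )
    # separations sized so a square measurement window (bbox plus
    # kernel-radius padding, corners included) around any particle
    # contains no other object's support and no cell autofluorescence
    forbidden = None
    if cell_masks:
        from skimage.morphology import disk as disk_footprint

        union = np.any(cell_masks, axis=0)
        forbidden = ndimage.binary_dilation(
            union, structure=disk_footprint(int(1.5 * max_rk + 8))
        )
    free_centers = _place_centers(
        rng,
        shape,
        free_diameters_um / px,
        margin_px=max_rk + 2.0,
        sep_extra_px=2.4 * max_rk + 10.0,
        forbidden=forbidden,
    )
    free_pol = _exact_subset(rng, n_free_particles, free_polarized_fraction)
    amps_free = _amplitudes(rng, n_free_particles, amplitude, intensity_cv)
    free_objs = [
        ObjectTruth(
            object_id=f"free_{i:03d}",
            obj_class="mitochondrion",
            center=free_centers[i],
            diameter_um=float(free_diameters_um[i]),
            amplitude=float(amps_free[i]),
            polarized=bool(free_pol[i]),
        )
        for i in range(n_free_particles)
    ]

    # --- render channels
    gfp = np.full(shape, config.background, dtype=float)
    for mask in cell_masks:
        gfp[mask] += cell_autofluorescence
    for obj in punctum_objs + free_objs:
        render_spot(gfp, obj.center, obj.diameter_um, obj.amplitude, px)

    tmre = np.full(shape, config.background, dtype=float)
    for obj in punctum_objs + free_objs:
        if obj.polarized:
            render_spot(tmre, obj.center, obj.diameter_um, tmre_amplitude, px)

    if config.noise_sd > 0:
        gfp += rng.normal(0.0, config.noise_sd, shape)
        tmre += rng.normal(0.0, config.noise_sd, shape)

    def _bundle(arr: np.ndarray, channel: str) -> ImageBundle:
        return ImageBundle(
            frames=arr[None, ...],
            channel=channel,
            timepoints_min=[0.0],
            pixel_size_um=px,
        )

    manifest = GroundTruthManifest(
        objects=cell_objs + punctum_objs + free_objs,
        extras={
            "background": config.background,
            "cell_autofluorescence": cell_autofluorescence,
            "amplitude": amplitude,
            "tmre_amplitude": tmre_amplitude,
            "punctum_diameter_um": punctum_diameter_um,
        },
    )
    return {"GFP": _bundle(gfp, "GFP"), "TMRE": _bundle(tmre, "TMRE")}, manifest


# ---------------------------------------------------------------------------
# plate readouts


def gen_plate_readouts(
    design: Mapping[str, Mapping[str, tuple[float, float]]],
    n_wells: int = 6,
    seed: int = 0,
) -> tuple[pd.DataFrame, GroundTruthManifest]:
    """Emit per-well raw values for plate assays with known group structure.

    ``design`` maps condition -> assay -> (true_mean, noise_sd). Values
    are Gaussian around the true mean; assays whose name starts with
    ``count`` are rounded to whole cells when noise is present.
    """
    if not design:
        raise ValueError("design must contain at least one condition")
    rng = np.random.default_rng(seed)
    rows = []
    truth_rows = []
    well_no = 0
    for condition, assays in design.items():
        if not assays:
            raise ValueError(f"condition {condition!r} lists no assays")
        for assay, (mean, sd) in assays.items():
            if sd < 0:
                raise ValueError("noise_sd must be >= 0")
            truth_rows.append(
                {"condition": condition, "assay": assay, "true_mean": mean, "noise_sd": sd}
            )
        for rep in range(n_wells):
            well_no += 1
            well = f"{chr(ord('A') + (well_no - 1) // 12)}{(well_no - 1) % 12 + 1}"
            for assay, (mean, sd) in assays.items():
                value = float(mean) if sd == 0 else float(mean + rng.normal(0.0, sd))
                if assay.startswith("count") and sd > 0:
                    value = float(max(round(value), 0))
                rows.append(
                    {
                        "well": well,
                        "condition": condition,
                        "replicate": rep,
                        "assay": assay,
                        "value": value,
                    }
                )
    table = pd.DataFrame(rows, columns=["well", "condition", "replicate", "assay", "value"])
    manifest = GroundTruthManifest(well_truth=pd.DataFrame(truth_rows))
    return table, manifest
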