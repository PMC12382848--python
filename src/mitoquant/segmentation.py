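"""Particle detection, ROI bookkeeping and intensity extraction.

Conventions: coordinates are 0-based, row-major, at pixel centers; ROI
masks are full-field booleans. Particle size is reported as the
equivalent diameter of the half-maximum contour, which matches the
FWHM-based diameter of a diffraction-blurred spot to about one pixel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.draw import disk as draw_disk
from skimage.draw import polygon as draw_polygon
from skimage.filters import threshold_otsu
from skimage.measure import label as sk_label
from skimage.measure import regionprops

from .images import ImageBundle


@dataclass
class ROI:
    """A region of interest: binary mask plus derived geometry."""

    mask: np.ndarray
    centroid: tuple[float, float]
    equivalent_diameter_um: float | None = None
    roi_id: str = ""

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("ROI mask must be 2-D")
        if not self.mask.any():
            raise ValueError("ROI mask is empty")

    @property
    def area_px(self) -> int:
        return int(self.mask.sum())

    def bbox(self) -> tuple[int, int, int, int]:
        rows = np.flatnonzero(self.mask.any(axis=1))
        cols = np.flatnonzero(self.mask.any(axis=0))
        return int(rows[0]), int(rows[-1]) + 1, int(cols[0]), int(cols[-1]) + 1


@dataclass
class IntensityTrace:
    """Background-subtracted integrated intensity of one ROI over time."""

    timepoints_min: np.ndarray
    values: np.ndarray
    roi_id: str = ""

    def __post_init__(self) -> None:
        self.timepoints_min = np.asarray(self.timepoints_min, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.timepoints_min) != len(self.values):
            raise ValueError("timepoints and values must have equal length")
        if len(self.timepoints_min) > 1 and np.any(np.diff(self.timepoints_min) <= 0):
            raise ValueError("timepoints must be strictly increasing")


@dataclass
class CellFluorescenceRecord:
    """Integrated, background-subtracted fluorescence of one cell in one
    channel; negative totals are clipped to zero and flagged."""

    cell_id: str
    channel: str
    integrated: float
    background_per_pixel: float
    clipped: bool = False


# ---------------------------------------------------------------------------
# ROI constructors


def roi_from_polygon(
    vertices: list[tuple[float, float]], shape: tuple[int, int], roi_id: str = ""
) -> ROI:
    rr, cc = draw_polygon([v[0] for v in vertices], [v[1] for v in vertices], shape)
    mask = np.zeros(shape, dtype=bool)
    mask[rr, cc] = True
    centroid = (float(np.mean(rr)), float(np.mean(cc)))
    return ROI(mask=mask, centroid=centroid, roi_id=roi_id)


def roi_from_disk(
    center: tuple[float, float], radius: float, shape: tuple[int, int], roi_id: str = ""
) -> ROI:
    rr, cc = draw_disk(center, radius, shape=shape)
    mask = np.zeros(shape, dtype=bool)
    mask[rr, cc] = True
    return ROI(mask=mask, centroid=(float(center[0]), float(center[1])), roi_id=roi_id)


# ---------------------------------------------------------------------------
# detection


def detect_particles(
    image: np.ndarray,
    pixel_size_um: float,
    d_range: tuple[float, float] = (0.5, 3.0),
    threshold: float | None = None,
    min_pixels: int = 2,
) -> list[ROI]:
    """Detect bright particles and keep those whose equivalent diameter
    lies within ``d_range`` (inclusive at both ends).

    The foreground threshold defaults to Otsu's method; pass ``threshold``
    for an absolute cutoff. The size gate uses the equivalent diameter of
    the half-maximum contour (area-equivalent circle at the stated pixel
    size), measured per particle against the background estimated as the
    image median.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("detect_particles expects a 2-D image")
    if not np.all(np.isfinite(image)):
        raise ValueError("image contains non-finite values")
    if pixel_size_um <= 0:
        raise ValueError("pixel_size_um must be > 0")
    if image.max() == image.min():
        return []
    thr = threshold_otsu(image) if threshold is None else float(threshold)
    labels = sk_label(image > thr)
    background = float(np.median(image))
    rois: list[ROI] = []
    for k, prop in enumerate(regionprops(labels, intensity_image=image)):
        if prop.area < min_pixels:
            continue
        r0, c0, r1, c1 = prop.bbox
        peak = float(prop.intensity_max)
        half = background + 0.5 * (peak - background)
        # measure the half-maximum area in a padded local window
        pad = max(3, (r1 - r0), (c1 - c0))
        wr0, wr1 = max(r0 - pad, 0), min(r1 + pad, image.shape[0])
        wc0, wc1 = max(c0 - pad, 0), min(c1 + pad, image.shape[1])
        window = image[wr0:wr1, wc0:wc1]
        half_mask = window >= half
        # restrict to the component containing this particle's peak
        comp = sk_label(half_mask)
        pr, pc = np.unravel_index(np.argmax(window), window.shape)
        # peak of the window may belong to a neighbour; use this prop's peak pixel
        local = np.where(
            labels[wr0:wr1, wc0:wc1] == prop.label, window, -np.inf
        )
        pr, pc = np.unravel_index(np.argmax(local), local.shape)
        area_half = int(np.sum(comp == comp[pr, pc])) if comp[pr, pc] else prop.area
        d_eq_um = 2.0 * math.sqrt(area_half / math.pi) * pixel_size_um
        if not (d_range[0] <= d_eq_um <= d_range[1]):
            continue
        mask = labels == prop.label
        rois.append(
            ROI(
                mask=mask,
                centroid=(float(prop.centroid[0]), float(prop.centroid[1])),
                equivalent_diameter_um=d_eq_um,
                roi_id=f"roi_{len(rois):03d}",
            )
        )
    return rois


def auto_threshold(
    image: np.ndarray, k_sigma: float = 5.0, frac: float = 0.1
) -> float:
    """Robust foreground threshold for sparse bright particles: the image
    median plus the larger of ``k_sigma`` noise SDs (MAD estimate) and
    ``frac`` of the peak excursion above the median."""
    image = np.asarray(image, dtype=float)
    med = float(np.median(image))
    sigma = 1.4826 * float(np.median(np.abs(image - med)))
    return med + max(k_sigma * sigma, frac * (float(image.max()) - med))


def occupied_mask(rois: list[ROI], shape: tuple[int, int], dilate_px: int = 4) -> np.ndarray:
    """Union of all ROI masks, dilated — the region unsafe for blanks."""
    occ = np.zeros(shape, dtype=bool)
    for roi in rois:
        occ |= roi.mask
    if dilate_px > 0 and occ.any():
        occ = ndimage.binary_dilation(occ, iterations=dilate_px)
    return occ


def adjacent_blank(
    roi: ROI, occupied: np.ndarray, width_px: int = 6, gap_px: int = 4
) -> ROI:
    """Blank ROI: an annulus around the particle excluding all detections."""
    inner = ndimage.binary_dilation(roi.mask, iterations=gap_px)
    outer = ndimage.binary_dilation(inner, iterations=width_px)
    ring = outer & ~inner & ~occupied
    if not ring.any():
        raise ValueError(f"no blank area adjacent to ROI {roi.roi_id!r}")
    return ROI(mask=ring, centroid=roi.centroid, roi_id=f"{roi.roi_id}_blank")


# ---------------------------------------------------------------------------
# intensity extraction


def extract_trace(stack: ImageBundle, roi: ROI, blank: ROI) -> IntensityTrace:
    """Integrated intensity over ``roi`` per frame, minus the mean blank
    level times the ROI area. Positions are assumed stationary across
    frames (the dish does not move during acquisition)."""
    if stack.is_zstack:
        raise ValueError("extract_trace expects a (t, y, x) time-lapse")
    if roi.mask.shape != stack.field_shape or blank.mask.shape != stack.field_shape:
        raise ValueError("ROI does not match the image bounds")
    if np.any(roi.mask & blank.mask):
        raise ValueError("roi and blank must be disjoint")
    area = roi.area_px
    values = [
        float(frame[roi.mask].sum() - frame[blank.mask].mean() * area)
        for frame in stack.frames
    ]
    return IntensityTrace(
        timepoints_min=stack.timepoints_min, values=np.asarray(values), roi_id=roi.roi_id
    )


def particle_intensity(
    image: np.ndarray,
    roi: ROI,
    background_per_px: float,
    pad_px: int = 0,
) -> float:
    """Background-subtracted integrated intensity over the ROI's bounding
    box expanded by ``pad_px`` (captures the full blur of a point-like
    particle when padded past the render kernel radius)."""
    image = np.asarray(image, dtype=float)
    r0, r1, c0, c1 = roi.bbox()
    r0, c0 = max(r0 - pad_px, 0), max(c0 - pad_px, 0)
    r1, c1 = min(r1 + pad_px, image.shape[0]), min(c1 + pad_px, image.shape[1])
    window = image[r0:r1, c0:c1]
    return float(window.sum() - background_per_px * window.size)


def measure_cell_fluorescence(
    image: np.ndarray,
    cell_mask: ROI,
    internal_background_region: ROI,
    channel: str = "GFP",
    cell_id: str = "",
) -> CellFluorescenceRecord:
    """Integrated intensity over a cell minus per-pixel background times
    the mask area; the background comes from a region inside the same
    cell lacking labelled structures."""
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("expected a 2-D image")
    bg_mask = internal_background_region.mask
    if not np.all(cell_mask.mask[bg_mask]):
        raise ValueError("background region must lie inside the cell mask")
    if bg_mask.sum() > cell_mask.mask.sum():
        raise ValueError("background region larger than the cell")
    bg = float(image[bg_mask].mean())
    total = float(image[cell_mask.mask].sum() - bg * cell_mask.area_px)
    clipped = total < 0
    return CellFluorescenceRecord(
        cell_id=cell_id or cell_mask.roi_id,
        channel=channel,
        integrated=max(total, 0.0),
        background_per_pixel=bg,
        clipped=clipped,
    )
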