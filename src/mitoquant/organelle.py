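"""Per-mitochondrion decision rules.

The four classifiers implemented here are the quantitative core of the
assay suite:

* **MPT calling** — a mitochondrion has undergone permeability transition
  if its integrated calcein intensity falls by more than 20% of its
  initial value within any single 2-min frame interval (abrupt release
  through the opened pore; a slow monotone leak never triggers the rule).
* **Swelling** — the transmittance ratio of a particle (minimum
  blank-normalised darkest-region mean across a z-stack) increases when
  the matrix expands; a change above 0.16 from the pre-exposure baseline
  is called swelling.
* **Polarization** — TMRE accumulates in polarized mitochondria; an ROI
  is polarized when its integrated TMRE signal exceeds a multiple of the
  local background over the same area.
* **ETC response** — the rise in per-cell integrated TMRE after substrate
  (malate) addition, expressed relative to an untreated control (= 100).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .images import ImageBundle
from .segmentation import ROI, IntensityTrace

MPT_DROP_THRESHOLD = 0.20
SWELLING_THRESHOLD = 0.16
TRANSMITTANCE_REGION_UM2 = 0.46


@dataclass
class MptCall:
    roi_id: str
    underwent_mpt: bool
    event_interval: tuple[int, int] | None
    drop_fraction: float


@dataclass
class TransmittanceSeries:
    roi_id: str
    timepoints_min: np.ndarray
    transmittance: np.ndarray
    swollen: bool = False
    change: float = 0.0

    def __post_init__(self) -> None:
        self.timepoints_min = np.asarray(self.timepoints_min, dtype=float)
        self.transmittance = np.asarray(self.transmittance, dtype=float)
        if len(self.timepoints_min) != len(self.transmittance):
            raise ValueError("timepoints and transmittance must have equal length")


@dataclass
class PolarizationCall:
    roi_id: str
    polarized: bool
    tmre_over_background: float
    substrate: str = "none"


@dataclass
class EtcResponse:
    cell_id: str
    increase: float
    normalized_increase: float | None = None


# ---------------------------------------------------------------------------


def call_mpt(
    trace: IntensityTrace,
    threshold: float = MPT_DROP_THRESHOLD,
    relative_to: str = "initial",
) -> MptCall:
    """Flag MPT if any consecutive-frame drop exceeds ``threshold`` of the
    reference intensity.

    ``relative_to="initial"`` (default) anchors the percentage to the
    trace's first value; ``"current"`` anchors each interval's drop to the
    intensity at the start of that interval.
    """
    values = trace.values
    if len(values) < 2:
        raise ValueError("trace needs at least 2 timepoints")
    f0 = float(values[0])
    if f0 <= 0:
        raise ValueError("initial trace value must be > 0")
    if relative_to not in ("initial", "current"):
        raise ValueError(f"unknown reference {relative_to!r}")
    drops = values[:-1] - values[1:]
    ref = f0 if relative_to == "initial" else values[:-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(np.asarray(ref) > 0, drops / ref, np.inf * np.sign(drops))
    hits = np.flatnonzero(frac > threshold)
    # drop_fraction is always reported on the initial-value scale
    max_drop = float(np.max(drops) / f0)
    if len(hits):
        first = int(hits[0])
        return MptCall(
            roi_id=trace.roi_id,
            underwent_mpt=True,
            event_interval=(first, first + 1),
            drop_fraction=max_drop,
        )
    return MptCall(
        roi_id=trace.roi_id, underwent_mpt=False, event_interval=None, drop_fraction=max_drop
    )


def mpt_fraction(calls: list[MptCall]) -> float:
    """Percentage of mitochondria undergoing MPT."""
    if not calls:
        raise ValueError("no MPT calls supplied")
    return 100.0 * sum(c.underwent_mpt for c in calls) / len(calls)


# ---------------------------------------------------------------------------


def region_mean_stack(
    zstack: ImageBundle,
    region_area_um2: float = TRANSMITTANCE_REGION_UM2,
    pixel_size_um: float | None = None,
) -> np.ndarray:
    """Per-slice moving means over the fixed measurement area (square of
    the stated area); precompute once per stack when measuring many ROIs."""
    px = pixel_size_um or zstack.pixel_size_um
    if px is None or px <= 0:
        raise ValueError("a positive pixel size is required")
    side = max(1, int(round(np.sqrt(region_area_um2) / px)))
    slices = zstack.frames[0]
    return np.stack([ndimage.uniform_filter(p, size=side, mode="nearest") for p in slices])


def compute_transmittance(
    zstack: ImageBundle,
    roi: ROI,
    blank: ROI,
    region_area_um2: float = TRANSMITTANCE_REGION_UM2,
    pixel_size_um: float | None = None,
    region_means: np.ndarray | None = None,
) -> float:
    """Transmittance ratio of one particle from a single z-stack.

    For each slice, the mean intensity over the darkest square region of
    the stated area whose centre lies on the particle is divided by the
    mean of the adjacent blank area in the same slice; the minimum ratio
    across slices is the particle's transmittance. Per-slice blank
    normalisation makes the result invariant to global illumination
    scaling.
    """
    if not zstack.is_zstack:
        raise ValueError("compute_transmittance expects a z-stack bundle")
    px = pixel_size_um or zstack.pixel_size_um
    if px is None or px <= 0:
        raise ValueError("a positive pixel size is required")
    if np.any(roi.mask & blank.mask):
        raise ValueError("roi and blank must be disjoint")
    if region_means is None:
        region_means = region_mean_stack(zstack, region_area_um2, px)
    slices = zstack.frames[0]  # (z, y, x): one stack per bundle timepoint
    best = np.inf
    for plane, means in zip(slices, region_means):
        blank_mean = float(plane[blank.mask].mean())
        if blank_mean <= 0:
            raise ValueError("blank mean must be > 0")
        darkest = float(means[roi.mask].min())
        best = min(best, darkest / blank_mean)
    return float(best)


def call_swelling(
    series: TransmittanceSeries,
    threshold: float = SWELLING_THRESHOLD,
    baseline_index: int = 0,
) -> TransmittanceSeries:
    """Set the swelling flag: the maximum absolute change in transmittance
    relative to the pre-exposure baseline timepoint exceeds ``threshold``."""
    t = series.transmittance
    if len(t) < 2:
        raise ValueError("series needs at least 2 timepoints")
    baseline = t[baseline_index]
    rest = np.delete(t, baseline_index)
    change = float(np.max(np.abs(rest - baseline)))
    series.change = change
    series.swollen = change > threshold
    return series


def swollen_fraction(series_list: list[TransmittanceSeries]) -> float:
    if not series_list:
        raise ValueError("no transmittance series supplied")
    return 100.0 * sum(s.swollen for s in series_list) / len(series_list)


# ---------------------------------------------------------------------------


def classify_polarization(
    tmre_integrated: float,
    background_per_px: float,
    roi_area_px: float,
    ratio_threshold: float = 2.0,
    roi_id: str = "",
    substrate: str = "none",
) -> PolarizationCall:
    """Polarized iff integrated TMRE over the ROI is at least
    ``ratio_threshold`` times the background over the same area."""
    if background_per_px <= 0:
        raise ValueError("background must be > 0")
    if roi_area_px <= 0:
        raise ValueError("roi area must be > 0")
    ratio = float(tmre_integrated / (background_per_px * roi_area_px))
    return PolarizationCall(
        roi_id=roi_id,
        polarized=ratio >= ratio_threshold,
        tmre_over_background=ratio,
        substrate=substrate,
    )


def polarized_fraction(calls: list[PolarizationCall]) -> float:
    if not calls:
        raise ValueError("no polarization calls supplied")
    return 100.0 * sum(c.polarized for c in calls) / len(calls)


# ---------------------------------------------------------------------------


def etc_response(
    series: np.ndarray,
    malate_frame: int = 3,
    control_increase: float | None = None,
    cell_id: str = "",
) -> EtcResponse:
    """Rise in per-cell integrated TMRE after malate addition.

    ``series`` holds one integrated intensity per minute (10 frames by
    default; malate enters between frames 3 and 4, 0-based). The increase
    is mean(frames after the addition frame) minus mean(frames before
    it), skipping the addition frame itself to avoid the mixing
    transient. When ``control_increase`` is given the increase is also
    expressed as a percentage of it (untreated control = 100).
    """
    series = np.asarray(series, dtype=float)
    if len(series) < malate_frame + 2:
        raise ValueError("series too short for the stated malate frame")
    if malate_frame < 1:
        raise ValueError("malate_frame must be >= 1")
    pre = float(series[:malate_frame].mean())
    post = float(series[malate_frame + 1 :].mean())
    increase = post - pre
    normalized = None
    if control_increase is not None:
        if control_increase <= 0:
            raise ValueError("control_increase must be > 0 for normalization")
        normalized = 100.0 * increase / control_increase
    return EtcResponse(cell_id=cell_id, increase=increase, normalized_increase=normalized)
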