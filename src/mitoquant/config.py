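"""Acquisition-level configuration shared by the synthetic generators.

The defaults mirror the imaging protocol the quantifiers were designed
around: calcein time-lapses at one frame per 2 min for 20 min (11 frames),
transmitted-light z-stacks of 20 slices at 0.2 um spacing, and a CCD pixel
size of 0.325 um after 2x2 binning at 20x (use 0.1625 um for the 40x
transmittance acquisitions).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from typing import Any


@dataclass(frozen=True)
class SimConfig:
    """Geometry, timing and noise of a simulated acquisition.

    Parameters
    ----------
    pixel_size_um
        Projected pixel size in the sample plane, um/pixel. Must be > 0.
    frame_interval_min
        Time between successive time-lapse frames, minutes.
    n_frames
        Number of time-lapse frames (default 11: t = 0..20 min at 2 min).
    z_step_um, n_slices
        Axial spacing and slice count of each transmitted-light z-stack.
    particle_diameter_um
        (low, high) range particles are drawn from, um.
    noise_sd
        Standard deviation of additive Gaussian pixel noise, arbitrary
        intensity units. 0 disables noise.
    seed
        Seed for the generator's private RNG; identical seed + config
        produce bit-identical output arrays.
    exposure_model
        Only ``"linear"`` is supported: recorded intensity is proportional
        to collected photons with no saturation.
    field_shape
        (rows, cols) of every rendered frame, pixels.
    background
        Constant camera/autofluorescence offset added to every pixel.
    """

    pixel_size_um: float = 0.325
    frame_interval_min: float = 2.0
    n_frames: int = 11
    z_step_um: float = 0.2
    n_slices: int = 20
    particle_diameter_um: tuple[float, float] = (0.5, 3.0)
    noise_sd: float = 0.0
    seed: int = 0
    exposure_model: str = "linear"
    field_shape: tuple[int, int] = (256, 256)
    background: float = 10.0

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")
        if self.n_slices < 1:
            raise ValueError("n_slices must be >= 1")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        lo, hi = self.particle_diameter_um
        if not (0 < lo <= hi):
            raise ValueError("particle_diameter_um must satisfy 0 < low <= high")
        if self.exposure_model != "linear":
            raise ValueError(f"unsupported exposure_model {self.exposure_model!r}")

    @property
    def timepoints_min(self) -> list[float]:
        return [i * self.frame_interval_min for i in range(self.n_frames)]

    def replace(self, **kwargs: Any) -> "SimConfig":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "SimConfig":
        d = dict(d)
        for key in ("particle_diameter_um", "field_shape"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)
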