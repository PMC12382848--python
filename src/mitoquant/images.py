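"""In-memory image container and multi-page TIFF round-trip."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

VALID_CHANNELS = ("calcein", "GFP", "TMRE", "MSR", "transmitted")


@dataclass
class ImageBundle:
    """An ordered set of frames from one channel of one acquisition.

    ``frames`` is ``(t, y, x)`` for a time-lapse or ``(t, z, y, x)`` when
    each timepoint is a z-stack. ``timepoints_min`` must be strictly
    increasing and match the leading axis.
    """

    frames: np.ndarray
    channel: str
    timepoints_min: np.ndarray
    z_positions_um: np.ndarray | None = None
    pixel_size_um: float | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.timepoints_min = np.asarray(self.timepoints_min, dtype=float)
        if self.channel not in VALID_CHANNELS:
            raise ValueError(f"unknown channel {self.channel!r}")
        if self.frames.ndim not in (3, 4):
            raise ValueError("frames must be (t, y, x) or (t, z, y, x)")
        if len(self.timepoints_min) != self.frames.shape[0]:
            raise ValueError("timepoints_min length must match frame count")
        if len(self.timepoints_min) > 1 and np.any(np.diff(self.timepoints_min) <= 0):
            raise ValueError("timepoints_min must be strictly increasing")
        if self.z_positions_um is not None:
            self.z_positions_um = np.asarray(self.z_positions_um, dtype=float)
            if self.frames.ndim != 4 or len(self.z_positions_um) != self.frames.shape[1]:
                raise ValueError("z_positions_um must match the z axis")

    @property
    def n_timepoints(self) -> int:
        return self.frames.shape[0]

    @property
    def is_zstack(self) -> bool:
        return self.frames.ndim == 4

    @property
    def field_shape(self) -> tuple[int, int]:
        return self.frames.shape[-2], self.frames.shape[-1]

    def save_tiff(self, path: str | Path) -> None:
        """Write as multi-page float32 TIFF with JSON metadata in the description."""
        meta = {
            "channel": self.channel,
            "timepoints_min": self.timepoints_min.tolist(),
            "z_positions_um": None
            if self.z_positions_um is None
            else self.z_positions_um.tolist(),
            "pixel_size_um": self.pixel_size_um,
            "axes": "TZYX" if self.is_zstack else "TYX",
        }
        tifffile.imwrite(
            str(path),
            self.frames.astype(np.float32),
            description=json.dumps(meta),
            metadata=None,
        )

    @classmethod
    def load_tiff(cls, path: str | Path) -> "ImageBundle":
        with tifffile.TiffFile(str(path)) as tif:
            data = tif.asarray()
            desc = tif.pages[0].description
        meta = json.loads(desc)
        axes = meta.get("axes", "TYX")
        data = np.asarray(data, dtype=float).reshape(
            (len(meta["timepoints_min"]), -1) + data.shape[-2:]
        )
        if axes == "TYX":
            data = data[:, 0]
        return cls(
            frames=data,
            channel=meta["channel"],
            timepoints_min=np.asarray(meta["timepoints_min"]),
            z_positions_um=None
            if meta.get("z_positions_um") is None
            else np.asarray(meta["z_positions_um"]),
            pixel_size_um=meta.get("pixel_size_um"),
        )
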