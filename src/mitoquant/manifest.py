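"""Ground-truth manifests emitted by every synthetic generator.

Each rendered object appears exactly once; downstream quantifiers are
validated by recovering these records from the rendered pixels alone.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterator

import numpy as np
import pandas as pd

OBJECT_CLASSES = ("mitochondrion", "cell", "punctum", "blank")


@dataclass
class ObjectTruth:
    """Per-object ground truth; unused fields stay ``None``."""

    object_id: str
    obj_class: str
    center: tuple[float, float] | None = None  # (row, col), pixels
    diameter_um: float | None = None
    amplitude: float | None = None  # integrated intensity, a.u.
    mpt_event_frame: int | None = None
    drop_fraction: float | None = None
    event_mode: str | None = None  # "step" | "ramp"
    swelling_onset_min: float | None = None
    transmittance_baseline: float | None = None
    transmittance_post: float | None = None
    focus_slice: int | None = None
    polarized: bool | None = None
    implanted_count: int | None = None
    cell_id: str | None = None
    polygon: list[tuple[float, float]] | None = None  # cell outline vertices
    background_disk: tuple[float, float, float] | None = None  # (row, col, radius)

    def __post_init__(self) -> None:
        if self.obj_class not in OBJECT_CLASSES:
            raise ValueError(f"unknown object class {self.obj_class!r}")


@dataclass
class GroundTruthManifest:
    objects: list[ObjectTruth] = field(default_factory=list)
    well_truth: pd.DataFrame | None = None
    extras: dict[str, Any] = field(default_factory=dict)

    def __iter__(self) -> Iterator[ObjectTruth]:
        return iter(self.objects)

    def __len__(self) -> int:
        return len(self.objects)

    def of_class(self, obj_class: str) -> list[ObjectTruth]:
        return [o for o in self.objects if o.obj_class == obj_class]

    @property
    def mitochondria(self) -> list[ObjectTruth]:
        return self.of_class("mitochondrion")

    @property
    def cells(self) -> list[ObjectTruth]:
        return self.of_class("cell")

    def event_fraction(self) -> float:
        """Fraction of mitochondria carrying an MPT event."""
        mitos = self.mitochondria
        if not mitos:
            raise ValueError("manifest holds no mitochondria")
        return sum(m.mpt_event_frame is not None for m in mitos) / len(mitos)

    def swollen_fraction(self) -> float:
        mitos = self.mitochondria
        if not mitos:
            raise ValueError("manifest holds no mitochondria")
        return (
            sum(
                m.transmittance_post is not None
                and m.transmittance_baseline is not None
                and m.transmittance_post != m.transmittance_baseline
                for m in mitos
            )
            / len(mitos)
        )

    def polarized_fraction(self) -> float:
        mitos = self.mitochondria
        if not mitos:
            raise ValueError("manifest holds no mitochondria")
        return sum(bool(m.polarized) for m in mitos) / len(mitos)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "objects": [dataclasses.asdict(o) for o in self.objects],
            "well_truth": None
            if self.well_truth is None
            else self.well_truth.to_dict(orient="records"),
            "extras": _jsonable(self.extras),
        }
        text = json.dumps(payload, indent=1, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "GroundTruthManifest":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        payload = json.loads(text)
        objects = []
        for rec in payload["objects"]:
            for key in ("center", "background_disk"):
                if rec.get(key) is not None:
                    rec[key] = tuple(rec[key])
            if rec.get("polygon") is not None:
                rec["polygon"] = [tuple(v) for v in rec["polygon"]]
            objects.append(ObjectTruth(**rec))
        well = payload.get("well_truth")
        return cls(
            objects=objects,
            well_truth=None if well is None else pd.DataFrame(well),
            extras=payload.get("extras", {}),
        )


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj
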