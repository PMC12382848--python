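"""Well-level assay arithmetic: control normalization, adherent-cell
ratios, linear calibration curves and dose/mixing calculations."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sp_stats


@dataclass
class CalibrationCurve:
    """Ordinary least-squares line ``signal = slope * concentration +
    intercept`` fitted to standards."""

    slope: float
    intercept: float
    r_squared: float
    standards: pd.DataFrame  # columns: concentration, signal

    def signal_range(self) -> tuple[float, float]:
        s = self.standards["signal"]
        return float(s.min()), float(s.max())


@dataclass
class DoseMix:
    final_concentration: float
    final_volume: float
    component_amounts: list[float]

    @property
    def total_amount(self) -> float:
        return float(sum(self.component_amounts))


def normalize_to_control(
    wells: pd.DataFrame,
    control_condition: str,
    value_col: str = "value",
    by_assay: bool = True,
) -> pd.DataFrame:
    """Rescale every value so the control-condition mean becomes exactly
    100 (per assay when ``by_assay``). Idempotent: renormalizing a
    normalized table is a no-op."""
    required = {"condition", value_col} | ({"assay"} if by_assay else set())
    missing = required - set(wells.columns)
    if missing:
        raise ValueError(f"well table lacks columns {sorted(missing)}")
    out = wells.copy()
    group_cols = ["assay"] if by_assay else [None]
    for key, idx in (
        out.groupby("assay").groups.items() if by_assay else [(None, out.index)]
    ):
        sub = out.loc[idx]
        ctrl = sub.loc[sub["condition"] == control_condition, value_col]
        if ctrl.empty:
            raise ValueError(
                f"control condition {control_condition!r} absent"
                + (f" for assay {key!r}" if by_assay else "")
            )
        ctrl_mean = float(ctrl.mean())
        if ctrl_mean <= 0:
            raise ValueError("control mean must be > 0")
        out.loc[idx, value_col] = sub[value_col] * (100.0 / ctrl_mean)
    return out


def adherent_ratio(pre_count: float, post_count: float) -> float:
    """Post-incubation over pre-incubation adherent cell count in the
    same field (dead/shrunken cells are excluded upstream)."""
    if pre_count <= 0:
        raise ValueError("pre-incubation count must be > 0")
    if post_count < 0:
        raise ValueError("post-incubation count must be >= 0")
    return post_count / pre_count


def fit_calibration(
    standards: Sequence[tuple[float, float]] | pd.DataFrame,
) -> CalibrationCurve:
    """OLS fit of signal against standard concentration."""
    if isinstance(standards, pd.DataFrame):
        df = standards[["concentration", "signal"]].astype(float)
    else:
        df = pd.DataFrame(standards, columns=["concentration", "signal"], dtype=float)
    if len(df) < 2:
        raise ValueError("need at least 2 standards")
    conc = df["concentration"].to_numpy()
    if np.allclose(conc, conc[0]):
        raise ValueError("standards must span at least 2 distinct concentrations")
    fit = sp_stats.linregress(conc, df["signal"].to_numpy())
    return CalibrationCurve(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        standards=df,
    )


def invert_calibration(
    curve: CalibrationCurve, signal: float, dilution_factor: float = 1.0
) -> float:
    """Concentration in the original sample: ``(signal - intercept) /
    slope * dilution_factor``. Signals outside the calibrated range are
    still inverted but raise an extrapolation warning."""
    if curve.slope == 0:
        raise ValueError("calibration slope is 0: curve not invertible")
    if dilution_factor <= 0:
        raise ValueError("dilution_factor must be > 0")
    lo, hi = curve.signal_range()
    if not (lo <= signal <= hi):
        warnings.warn(
            f"signal {signal} outside calibrated range [{lo}, {hi}]; extrapolating",
            stacklevel=2,
        )
    return (signal - curve.intercept) / curve.slope * dilution_factor


def dose_mix(components: Iterable[tuple[float, float]]) -> DoseMix:
    """Mix components given as (volume, concentration) pairs.

    Units are caller-defined but must be consistent; amounts are returned
    in volume x concentration units. Conservation holds exactly:
    ``final_concentration * final_volume == sum(v_i * c_i)``.
    """
    comps = [(float(v), float(c)) for v, c in components]
    if not comps:
        raise ValueError("no components supplied")
    if any(v <= 0 for v, _ in comps):
        raise ValueError("volumes must be > 0")
    volume = sum(v for v, _ in comps)
    amounts = [v * c for v, c in comps]
    return DoseMix(
        final_concentration=sum(amounts) / volume,
        final_volume=volume,
        component_amounts=amounts,
    )
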