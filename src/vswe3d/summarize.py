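"""Tumour-level reduction of speed and quality maps.

The centroid of the per-tumour c_s distribution is the spatial median over
valid measurement points; derived statistics are the dispersion slope
(c_s versus vibration frequency, reflecting tissue viscosity), the
within-subject coefficient of variation over paired repeats,

    CV_WS(%) = 100 · sqrt( Σ (Δ/m)² / (2n) ),

relative treatment change, and Young's modulus under the incompressible
purely elastic assumption E = 3·ρ·c_s².  Hypothesis testing is deliberately
left to external statistics packages; this module only exports tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .containers import ConformanceMap
from .speed import SpeedMap

__all__ = [
    "SummaryRecord",
    "RepeatabilityInput",
    "AcquisitionPlan",
    "tumour_median",
    "dispersion_slope",
    "cv_ws",
    "relative_change",
    "youngs_modulus",
    "plan_counts",
    "summarize_speed_map",
    "records_to_frame",
]


@dataclass
class SummaryRecord:
    """One row of the tumour-level summary table."""

    subject_id: str
    session_id: str
    frequency_hz: float
    median_c_s: float                 # m/s, over valid points
    n_valid: int
    median_conformance: Optional[float] = None   # %
    median_gof: Optional[float] = None
    mean_c_s: Optional[float] = None  # diagnostic only; the median is the statistic


@dataclass
class RepeatabilityInput:
    """Paired repeat determinations of median c_s, one pair per subject."""

    pairs: Sequence[tuple[float, float]]

    def __post_init__(self) -> None:
        if len(self.pairs) < 1:
            raise ValueError("need at least one repeat pair")
        for a, b in self.pairs:
            if a <= 0 or b <= 0:
                raise ValueError("repeat values must be positive")


@dataclass
class AcquisitionPlan:
    """Scan-session bookkeeping: which frequencies, shaker configurations and
    sessions are acquired, and the elevational geometry of each scan."""

    frequencies_hz: Sequence[float] = (700.0, 1000.0, 1200.0)
    shaker_configs: Sequence[str] = ("one", "two")
    sessions: Sequence[str] = ("day1", "day2", "day3")
    scan_length_mm: float = 10.0
    elevational_step_mm: float = 0.2

    def __post_init__(self) -> None:
        if not (self.frequencies_hz and self.shaker_configs and self.sessions):
            raise ValueError("plan lists must be non-empty")
        if self.elevational_step_mm <= 0:
            raise ValueError("elevational step must be positive")


def tumour_median(vswe_map: Union[SpeedMap, ConformanceMap],
                  mask: Optional[np.ndarray] = None) -> float:
    """Spatial median over valid (and optionally masked) points.

    For a SpeedMap the reduction runs over valid measurement points (mask
    applies to the (m, n, p) point lattice); for a ConformanceMap over
    defined voxels.  Returns NaN if no valid points remain.
    """
    if isinstance(vswe_map, SpeedMap):
        select = vswe_map.valid.copy()
        values = vswe_map.c_s
    elif isinstance(vswe_map, ConformanceMap):
        select = vswe_map.defined.copy()
        values = vswe_map.data
    else:
        raise TypeError(f"unsupported map type {type(vswe_map).__name__}")
    if mask is not None:
        select &= np.asarray(mask, dtype=bool)
    if not select.any():
        return float("nan")
    return float(np.median(values[select]))


def dispersion_slope(medians: Sequence[tuple[float, float]]) -> float:
    """OLS slope of tumour-median c_s (m/s) versus vibration frequency (Hz)."""
    freqs = np.array([f for f, _ in medians], dtype=float)
    speeds = np.array([c for _, c in medians], dtype=float)
    if len(np.unique(freqs)) < 2:
        raise ValueError("need at least two distinct frequencies for a slope")
    return float(np.polyfit(freqs, speeds, 1)[0])


def cv_ws(pairs: Union[RepeatabilityInput, Sequence[tuple[float, float]]]) -> float:
    """Within-subject coefficient of variation (%) over paired repeats.

    CV_WS(%) = 100 · sqrt( Σ (Δ/m)² / (2n) ), with m the pair mean, Δ the
    absolute pair difference and n the number of test–retest pairs.
    """
    if not isinstance(pairs, RepeatabilityInput):
        pairs = RepeatabilityInput(pairs)
    total = 0.0
    for a, b in pairs.pairs:
        m = (a + b) / 2.0
        if m == 0:
            raise ValueError("pair mean must be non-zero")
        total += (abs(a - b) / m) ** 2
    n = len(pairs.pairs)
    return float(100.0 * np.sqrt(total / (2.0 * n)))


def relative_change(baseline: float, followup: float) -> float:
    """Relative change in c_s (%), 100·(followup − baseline)/baseline."""
    if baseline <= 0:
        raise ValueError("baseline must be positive")
    return float(100.0 * (followup - baseline) / baseline)


def youngs_modulus(c_s: float, density_kg_m3: float = 1000.0) -> float:
    """Young's modulus in kPa from shear wave speed, E = 3·ρ·c_s².

    Assumes incompressible, purely elastic tissue; 4 m/s at ρ = 1000 kg/m³
    gives 48 kPa.
    """
    if c_s < 0:
        raise ValueError("shear wave speed must be non-negative")
    if density_kg_m3 <= 0:
        raise ValueError("density must be positive")
    return float(3.0 * density_kg_m3 * c_s ** 2 / 1000.0)


def plan_counts(plan: AcquisitionPlan) -> tuple[int, int]:
    """(datasets per subject, elevational slices per scan) for a plan."""
    datasets = len(plan.frequencies_hz) * len(plan.shaker_configs) * len(plan.sessions)
    slices = int(round(plan.scan_length_mm / plan.elevational_step_mm))
    return datasets, slices


def summarize_speed_map(speed_map: SpeedMap,
                        subject_id: str = "subject",
                        session_id: str = "session",
                        conformance_map: Optional[ConformanceMap] = None,
                        conformance_mask: Optional[np.ndarray] = None) -> SummaryRecord:
    """Reduce one speed map (and optional Conformance map) to a SummaryRecord."""
    speeds = speed_map.valid_speeds()
    gofs = speed_map.gof[speed_map.valid]
    median_c = tumour_median(speed_map)
    record = SummaryRecord(
        subject_id=subject_id, session_id=session_id,
        frequency_hz=speed_map.frequency_hz,
        median_c_s=median_c, n_valid=int(speeds.size),
        median_gof=float(np.median(gofs)) if gofs.size else None,
        mean_c_s=float(np.mean(speeds)) if speeds.size else None,
    )
    if conformance_map is not None:
        record.median_conformance = tumour_median(conformance_map, conformance_mask)
    return record


def records_to_frame(records: Sequence[SummaryRecord]) -> pd.DataFrame:
    """Summary table with one row per subject × session × frequency."""
    return pd.DataFrame([vars(r) for r in records])
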