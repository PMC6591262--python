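"""Sand-pack column oil-recovery bookkeeping.

A column is saturated with brine (pore volume PV from the wet/dry mass
difference), flooded with ~1 PV of heavy oil, then waterflooded; the oil that
stays behind is the residual oil in place (ROIP).  A microbial treatment
stage follows, and its produced oil is reported as a percentage of ROIP.
Produced oil is measured by dichloromethane extraction of the effluent and
A600 of the extract against a linear calibration curve.

Volumes in mL throughout; percent-ROIP values are percentages.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "ColumnSpec",
    "CalibrationCurve",
    "EffluentSample",
    "RecoveryResult",
    "ColumnRecord",
    "pore_volume",
    "oil_volume_from_A600",
    "compute_roip",
    "percent_roip",
    "net_recovery",
    "summarize_columns",
]

_SUBSTRATE_TAGS = {"E", "T", "N", "EN", "TN"}


@dataclass(frozen=True)
class ColumnSpec:
    id: str
    PV: float  # mL
    pressure: float = 27.2  # atm
    oil_injected: float = 0.0  # mL
    substrates: frozenset[str] = frozenset()
    inoculum: str = "none"
    inoculum_od: float = 0.0

    def __post_init__(self) -> None:
        if self.PV <= 0:
            raise ValueError(f"column {self.id}: PV must be positive")
        if self.oil_injected > self.PV:
            raise ValueError(f"column {self.id}: oil_injected exceeds PV")
        bad = set(self.substrates) - _SUBSTRATE_TAGS
        if bad:
            raise ValueError(f"column {self.id}: unknown substrate tags {bad}")


@dataclass(frozen=True)
class CalibrationCurve:
    """A600 of the oil-dichloromethane extract vs oil content (mL oil / mL solvent)."""

    slope: float
    intercept: float = 0.0
    max_a600: float | None = None  # upper end of the calibrated range

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("calibration slope must be positive")


@dataclass(frozen=True)
class EffluentSample:
    stage: str  # "waterflood" | "MEOR"
    cumulative_PV_injected: float
    aqueous_volume: float  # mL
    extract_A600: float
    solvent_volume: float  # mL dichloromethane
    nitrate_mM: float = 0.0
    nitrite_mM: float = 0.0

    def __post_init__(self) -> None:
        if self.stage not in ("waterflood", "MEOR"):
            raise ValueError(f"unknown stage {self.stage!r}")
        if self.aqueous_volume <= 0 or self.solvent_volume <= 0:
            raise ValueError("volumes must be positive")
        if self.extract_A600 < 0:
            raise ValueError("A600 must be non-negative")


@dataclass(frozen=True)
class RecoveryResult:
    column_id: str
    ROIP: float  # mL
    roip_pv_fraction: float
    meor_oil: float = 0.0  # mL
    percent_roip: float = 0.0
    net_percent_roip: float | None = None


@dataclass(frozen=True)
class ColumnRecord:
    """One Table-style summary row: a group of `n` replicate columns."""

    id: str
    n: int
    roip_pv_fraction: float
    percent_roip: float
    substrates: str = ""
    inoculum: str = "none"
    od600: float = 0.0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("multiplicity must be >= 1")


def pore_volume(dry_mass: float, saturated_mass: float, brine_density: float = 1.0) -> float:
    """PV (mL) from dry vs brine-saturated column mass (g) and brine density (g/mL)."""
    if brine_density <= 0:
        raise ValueError("brine density must be positive")
    diff = saturated_mass - dry_mass
    if diff <= 0:
        raise ValueError("saturated mass must exceed dry mass")
    return diff / brine_density


def oil_volume_from_A600(sample: EffluentSample, calib: CalibrationCurve) -> float:
    """Invert the linear calibration: mL oil in one effluent sample, floored at 0."""
    if calib.max_a600 is not None and sample.extract_A600 > calib.max_a600:
        warnings.warn(
            f"A600={sample.extract_A600} above calibrated range (max {calib.max_a600})"
        )
    oil_per_solvent = (sample.extract_A600 - calib.intercept) / calib.slope
    return max(0.0, sample.solvent_volume * oil_per_solvent)


def _stage_oil(samples: Iterable[EffluentSample], stage: str, calib: CalibrationCurve) -> float:
    total = 0.0
    for s in samples:
        if s.stage != stage:
            raise ValueError(f"expected stage {stage!r}, got {s.stage!r}")
        total += oil_volume_from_A600(s, calib)
    return total


def compute_roip(
    spec: ColumnSpec,
    waterflood_samples: Sequence[EffluentSample],
    calib: CalibrationCurve,
) -> RecoveryResult:
    """Residual oil in place after waterflood: injected minus produced oil."""
    produced = _stage_oil(waterflood_samples, "waterflood", calib)
    roip = spec.oil_injected - produced
    if roip < 0:
        raise ValueError(
            f"column {spec.id}: waterflood production {produced:.2f} mL exceeds "
            f"injected oil {spec.oil_injected:.2f} mL"
        )
    return RecoveryResult(
        column_id=spec.id, ROIP=roip, roip_pv_fraction=roip / spec.PV
    )


def percent_roip(
    result: RecoveryResult,
    meor_samples: Sequence[EffluentSample],
    calib: CalibrationCurve,
) -> RecoveryResult:
    """Oil produced in the treatment stage as percent of ROIP."""
    if result.ROIP <= 0:
        raise ValueError("percent ROIP undefined for zero residual oil")
    meor_oil = _stage_oil(meor_samples, "MEOR", calib)
    return replace(
        result, meor_oil=meor_oil, percent_roip=100.0 * meor_oil / result.ROIP
    )


def net_recovery(percent: float, control_percents: Sequence[float]) -> float:
    """Percent ROIP above the mean of negative-control columns."""
    if len(control_percents) == 0:
        raise ValueError("control list must be non-empty")
    return percent - sum(control_percents) / len(control_percents)


def summarize_columns(rows: Sequence[ColumnRecord]) -> dict:
    """Aggregate replicate-group rows: overall ROIP/PV mean +- SD (weighted by
    multiplicity) and per-substrate-group percent-ROIP means.

    Returns a dict with keys ``n_columns``, ``roip_pv_mean``, ``roip_pv_sd``
    and ``groups`` (a DataFrame indexed by substrate tag).
    """
    if not rows:
        raise ValueError("no rows to summarize")
    n_total = sum(r.n for r in rows)
    mean = sum(r.n * r.roip_pv_fraction for r in rows) / n_total
    if n_total > 1:
        ss = sum(r.n * (r.roip_pv_fraction - mean) ** 2 for r in rows)
        sd = math.sqrt(ss / (n_total - 1))
    else:
        sd = 0.0
    df = pd.DataFrame(
        {
            "substrates": [r.substrates for r in rows],
            "n": [r.n for r in rows],
            "percent_roip": [r.percent_roip for r in rows],
        }
    )
    groups = (
        df.groupby("substrates")
        .apply(
            lambda g: pd.Series(
                {
                    "n": g["n"].sum(),
                    "percent_roip_mean": (g["n"] * g["percent_roip"]).sum() / g["n"].sum(),
                }
            ),
            include_groups=False,
        )
    )
    return {
        "n_columns": n_total,
        "roip_pv_mean": mean,
        "roip_pv_sd": sd,
        "groups": groups,
    }
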