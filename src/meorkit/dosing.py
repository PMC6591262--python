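"""Two-phase donor dosing arithmetic.

Hydrophobic donors (toluene, ethylbenzene) are dosed dissolved in an inert
carrier phase (heptamethylnonane, HMN) floating on the aqueous medium, or
directly in the aqueous phase below their solubility limit.  All bookkeeping
is electron-based: a dose is sufficient when the donor's electron content
covers the nitrate demand of the aqueous phase.

Units: concentrations in mM, volumes in mL, amounts in mmol (mM*mL/1000).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

from .stoichiometry import (
    NO3_TO_N2,
    AcceptorCouple,
    ChemicalSpecies,
    electron_equivalents,
    resolve_donor,
)

__all__ = [
    "Compartment",
    "TwoPhaseDose",
    "DoseAssessment",
    "SOLUBILITY_MM_20C",
    "required_carrier_conc",
    "assess_dose",
    "saturation_check",
    "reducible_fraction",
    "assimilated_fraction",
]

#: Aqueous solubilities at 20 degC, mM.
SOLUBILITY_MM_20C: Mapping[str, float] = {"ethylbenzene": 1.5, "toluene": 5.6}

_PHASES = ("aqueous", "oil", "carrier", "headspace")


@dataclass(frozen=True)
class Compartment:
    phase: str
    volume: float  # mL

    def __post_init__(self) -> None:
        if self.phase not in _PHASES:
            raise ValueError(f"unknown phase {self.phase!r}")
        if self.volume <= 0:
            raise ValueError("compartment volume must be positive")


@dataclass(frozen=True)
class TwoPhaseDose:
    donor: ChemicalSpecies
    carrier: Compartment
    aqueous: Compartment
    conc_in_carrier: float  # mM in the carrier phase
    aqueous_solubility: float | None = None  # mM at `temperature`
    temperature: float = 20.0  # degC

    def __post_init__(self) -> None:
        if self.conc_in_carrier < 0:
            raise ValueError("conc_in_carrier must be non-negative")
        if self.aqueous_solubility is not None and self.aqueous_solubility <= 0:
            raise ValueError("aqueous_solubility must be positive when given")


@dataclass(frozen=True)
class DoseAssessment:
    required_mmol: float
    dosed_mmol: float
    margin_percent: float  # (dosed - required)/required * 100
    sufficient: bool
    reducible_nitrate_percent: float  # capped at 100
    reducible_nitrate_percent_raw: float  # uncapped


def _gamma(donor: str | ChemicalSpecies) -> tuple[ChemicalSpecies, int]:
    sp = resolve_donor(donor)
    g = electron_equivalents(sp).gamma
    if g <= 0:
        raise ValueError(f"{sp.name}: not an electron donor")
    return sp, g


def required_carrier_conc(
    nitrate_mM: float,
    aqueous: Compartment,
    carrier: Compartment,
    donor: str | ChemicalSpecies,
    endpoint: AcceptorCouple = NO3_TO_N2,
) -> float:
    """Donor concentration (mM) needed in the carrier to cover the aqueous nitrate.

    nitrate_mM * V_aq * e_per_N / gamma / V_carrier.
    """
    if nitrate_mM < 0:
        raise ValueError("nitrate_mM must be non-negative")
    _, g = _gamma(donor)
    return nitrate_mM * aqueous.volume * endpoint.e_per_N / g / carrier.volume


def assess_dose(
    dose: TwoPhaseDose,
    nitrate_mM: float,
    endpoint: AcceptorCouple = NO3_TO_N2,
) -> DoseAssessment:
    """Compare a dosed carrier-phase donor amount against the aqueous nitrate demand."""
    _, g = _gamma(dose.donor)
    required_mmol = nitrate_mM * dose.aqueous.volume * endpoint.e_per_N / g / 1000.0
    dosed_mmol = dose.conc_in_carrier * dose.carrier.volume / 1000.0
    if required_mmol == 0:
        margin = float("inf") if dosed_mmol > 0 else 0.0
    else:
        margin = (dosed_mmol - required_mmol) / required_mmol * 100.0
    raw = reducible_fraction(
        dosed_mmol, nitrate_mM * dose.aqueous.volume / 1000.0, endpoint, donor=dose.donor
    ) if nitrate_mM > 0 else (100.0, 100.0)
    return DoseAssessment(
        required_mmol=required_mmol,
        dosed_mmol=dosed_mmol,
        margin_percent=margin,
        sufficient=margin >= 0,
        reducible_nitrate_percent=raw[0],
        reducible_nitrate_percent_raw=raw[1],
    )


def saturation_check(
    aqueous_conc_mM: float,
    donor: str | ChemicalSpecies,
    solubility_mM: float | None = None,
    rel_tol: float = 1e-9,
) -> tuple[str, float | None]:
    """Flag an aqueous donor concentration against its solubility.

    Returns ``(flag, headroom_mM)`` with flag in {"below", "at", "above",
    "unknown"}; headroom is solubility minus concentration (None if unknown).
    """
    sp = resolve_donor(donor)
    sol = solubility_mM if solubility_mM is not None else SOLUBILITY_MM_20C.get(sp.name)
    if sol is None:
        warnings.warn(f"no registered solubility for {sp.name}; flagging unknown")
        return "unknown", None
    headroom = sol - aqueous_conc_mM
    if abs(headroom) <= rel_tol * sol:
        return "at", 0.0
    return ("below" if headroom > 0 else "above"), headroom


def reducible_fraction(
    donor_mmol: float,
    nitrate_mmol: float,
    endpoint: AcceptorCouple = NO3_TO_N2,
    donor: str | ChemicalSpecies = "ethylbenzene",
) -> tuple[float, float]:
    """Percent of a nitrate amount reducible with the dosed donor electrons.

    Returns ``(capped, raw)``: raw = 100 * donor_mmol*gamma / (nitrate_mmol*e_per_N),
    capped at 100.
    """
    if donor_mmol < 0 or nitrate_mmol < 0:
        raise ValueError("amounts must be non-negative")
    if nitrate_mmol == 0:
        raise ValueError("reducible fraction undefined for zero nitrate")
    _, g = _gamma(donor)
    raw = 100.0 * donor_mmol * g / (nitrate_mmol * endpoint.e_per_N)
    return min(100.0, raw), raw


def assimilated_fraction(
    dosed_donor_mmol: float,
    donor: str | ChemicalSpecies,
    nitrate_reduced_to_nitrite_mM: float,
    nitrite_reduced_to_n2_mM: float,
    aqueous_volume: float,
) -> float:
    """Fraction of dosed donor electrons not accounted for by N-oxyanion reduction.

    The remainder is attributed to assimilation into biomass and exopolymer:
    1 - (2*dNO3->NO2 + 3*dNO2->N2) * V/1000 / (dosed_mmol * gamma).
    Negative values (measurement noise) are clamped to 0 with a warning.
    """
    if aqueous_volume <= 0:
        raise ValueError("aqueous_volume must be positive")
    if dosed_donor_mmol <= 0:
        raise ValueError("dosed_donor_mmol must be positive")
    _, g = _gamma(donor)
    accepted = (
        2.0 * nitrate_reduced_to_nitrite_mM + 3.0 * nitrite_reduced_to_n2_mM
    ) * aqueous_volume / 1000.0
    frac = 1.0 - accepted / (dosed_donor_mmol * g)
    if frac < 0:
        warnings.warn(
            f"electron balance over-closed by {-frac:.3f}; clamping to 0"
        )
        return 0.0
    return frac
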