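"""Mechanism models for nitrate-mediated oil recovery.

Three candidate mechanisms are quantified for denitrifying cultures in
oil-bearing porous media:

* **Gas drive** — denitrification produces N2 (and CO2); the ideal-gas molar
  volume RT/P says how much volume that gas occupies at column pressure.
  At 27.2 atm a mole of gas occupies under a litre, so gas drive is weak.
* **Emulsification** — cells adhering to oil as a monolayer can stabilize
  emulsion droplets.  For monodisperse droplets of diameter d, total droplet
  surface A = N_cells * footprint / coverage, droplet count n = A/(pi d^2),
  and emulsified oil volume V = n * pi d^3 / 6 = (d/6) * N_cells * footprint
  / coverage.
* **Pore plugging** — at fixed flow Q = A_eff * k * dP / (mu * L), a rise in
  differential pressure is read as a proportional fall in the effective flow
  area (plugging by biomass and emulsion droplets).
"""

from __future__ import annotations

from dataclasses import dataclass

from .stoichiometry import BalancedReaction

__all__ = [
    "GAS_CONSTANT_L_ATM",
    "GasConditions",
    "EmulsionModel",
    "DarcyState",
    "molar_volume",
    "gas_yield",
    "gas_volume_per_donor",
    "emulsifiable_oil_volume",
    "biomass_volume_fraction",
    "darcy_area_ratio",
]

#: Gas constant in L*atm/(mol*K).
GAS_CONSTANT_L_ATM = 0.082057

_UM2_TO_CM2 = 1e-8
_UM_TO_CM = 1e-4
_UM3_TO_CM3 = 1e-12


@dataclass(frozen=True)
class GasConditions:
    T: float  # K
    P: float  # atm
    R: float = GAS_CONSTANT_L_ATM

    def __post_init__(self) -> None:
        if self.T <= 0 or self.P <= 0:
            raise ValueError("temperature and pressure must be positive")


@dataclass(frozen=True)
class EmulsionModel:
    """Cell-monolayer emulsification geometry.

    Defaults for ``cell_footprint`` (1.7 um^2 of droplet surface per adhered
    cell) and ``cell_volume`` (3.1 um^3) are plausible rod-shaped-cell values;
    both are explicit parameters, never baked into formulas.
    """

    cell_density: float  # cells per cm^3 aqueous phase
    aqueous_volume: float  # cm^3
    droplet_diameter: float  # um
    cell_footprint: float = 1.7  # um^2 per adhered cell
    coverage: float = 1.0  # fraction of droplet surface covered
    cell_volume: float = 3.1  # um^3

    def __post_init__(self) -> None:
        if self.cell_density < 0:
            raise ValueError("cell_density must be non-negative")
        for name in ("aqueous_volume", "droplet_diameter", "cell_footprint",
                     "cell_volume"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.coverage <= 1:
            raise ValueError("coverage must lie in (0, 1]")


@dataclass(frozen=True)
class DarcyState:
    """State of a column obeying Q = A*k*dP/(mu*L)."""

    Q: float
    mu: float
    L: float
    k: float
    dP: float


def molar_volume(cond: GasConditions) -> float:
    """Ideal-gas molar volume R*T/P in L/mol."""
    return cond.R * cond.T / cond.P


def gas_yield(rxn: BalancedReaction, co2_gas_fraction: float = 0.0) -> float:
    """Mol gas produced per mol donor: N2 plus the gaseous share of CO2.

    At reservoir pH most CO2 stays as bicarbonate, hence the default
    ``co2_gas_fraction`` of 0.
    """
    if not 0 <= co2_gas_fraction <= 1:
        raise ValueError("co2_gas_fraction must lie in [0, 1]")
    n2 = float(max(rxn.coefficient("N2"), 0))
    co2 = float(max(rxn.coefficient("CO2"), 0))
    return n2 + co2_gas_fraction * co2


def gas_volume_per_donor(
    rxn: BalancedReaction, cond: GasConditions, co2_gas_fraction: float = 0.0
) -> float:
    """Litres of gas per mol donor oxidized at the given conditions."""
    return gas_yield(rxn, co2_gas_fraction) * molar_volume(cond)


def emulsifiable_oil_volume(model: EmulsionModel) -> float:
    """Oil volume (cm^3) a cell monolayer can hold as emulsion droplets.

    V = (d/6) * N_cells * footprint / coverage, with d and footprint converted
    from um to cm.  Linear in cell density, aqueous volume, footprint and
    droplet diameter.
    """
    n_cells = model.cell_density * model.aqueous_volume
    total_surface_cm2 = n_cells * model.cell_footprint * _UM2_TO_CM2 / model.coverage
    d_cm = model.droplet_diameter * _UM_TO_CM
    return d_cm / 6.0 * total_surface_cm2


def biomass_volume_fraction(cell_density: float, cell_volume: float) -> float:
    """Percent of the aqueous phase occupied by cells.

    ``cell_density`` in cells/cm^3, ``cell_volume`` in um^3.
    """
    if cell_density < 0 or cell_volume < 0:
        raise ValueError("inputs must be non-negative")
    return cell_density * cell_volume * _UM3_TO_CM3 * 100.0


def darcy_area_ratio(dP_before: float, dP_after: float) -> float:
    """Effective-flow-area ratio A_after/A_before at fixed Q, mu, L, k.

    From Q = A*k*dP/(mu*L): holding everything but A and dP fixed,
    A_after/A_before = dP_before/dP_after.
    """
    if dP_before <= 0 or dP_after <= 0:
        raise ValueError("differential pressures must be positive")
    return dP_before / dP_after
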