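"""Electron-balance engine for denitrification coupled to organic-donor oxidation.

Nitrate-reducing bacteria oxidize an organic electron donor (acetate,
benzoate, toluene, ethylbenzene, ...) completely to CO2 and pass the
electrons to nitrate.  The number of electrons a donor CxHyOz^q releases on
complete oxidation is its degree of reduction

    gamma = 4*nC + nH - 2*nO - z

(an anionic charge of -1 contributes one extra electron).  Nitrate accepts
2 e- per N when reduced to nitrite, nitrite accepts 3 e- per N when reduced
to N2, and the full couple NO3- -> 1/2 N2 accepts 5 e- per N.  Coupling a
donor to an acceptor couple is then pure electron bookkeeping:

    donor_mM = nitrate_mM * e_per_N / gamma

All stoichiometric coefficients are kept as exact :class:`fractions.Fraction`
internally and rounded (half-up) only for presentation.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from fractions import Fraction
from pathlib import Path
from typing import Mapping

__all__ = [
    "ChemicalSpecies",
    "ElectronEquivalents",
    "AcceptorCouple",
    "BalancedReaction",
    "CoupledDemand",
    "FormulaError",
    "StoichiometryError",
    "NO3_TO_NO2",
    "NO2_TO_N2",
    "NO3_TO_N2",
    "COUPLES",
    "DEFAULT_SPECIES",
    "PAPER_COMPAT_ELECTRONS",
    "parse_formula",
    "electron_equivalents",
    "donor_demand",
    "balance_reaction",
    "verify_balance",
    "load_species_registry",
    "round_half_up",
]


class FormulaError(ValueError):
    """A chemical formula string could not be parsed."""


class StoichiometryError(ValueError):
    """A species cannot play the requested stoichiometric role."""


def round_half_up(x: float, decimals: int = 2) -> float:
    """Round with ties away from zero (presentation-layer policy)."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ChemicalSpecies:
    """A donor, acceptor or inert species with C/H/O/N composition and charge."""

    name: str
    nC: int = 0
    nH: int = 0
    nO: int = 0
    nN: int = 0
    z: int = 0
    role: str = "donor"

    _ROLES = ("donor", "acceptor", "product", "inert")

    def __post_init__(self) -> None:
        counts = (self.nC, self.nH, self.nO, self.nN)
        if any(c < 0 for c in counts):
            raise ValueError(f"{self.name}: atom counts must be non-negative")
        if all(c == 0 for c in counts):
            raise ValueError(f"{self.name}: at least one atom required")
        if not -3 <= self.z <= 3:
            raise ValueError(f"{self.name}: charge {self.z} outside [-3, 3]")
        if self.role not in self._ROLES:
            raise ValueError(f"{self.name}: unknown role {self.role!r}")

    @property
    def gamma(self) -> int:
        """Electrons released per mol on complete oxidation of C to CO2."""
        return 4 * self.nC + self.nH - 2 * self.nO - self.z


@dataclass(frozen=True)
class ElectronEquivalents:
    species: ChemicalSpecies
    gamma: int

    def __post_init__(self) -> None:
        if self.species.role == "donor" and self.gamma < 0:
            raise StoichiometryError(
                f"{self.species.name}: negative electron count for a donor"
            )


@dataclass(frozen=True)
class AcceptorCouple:
    """A nitrogen-oxyanion reduction couple and its electrons accepted per N."""

    name: str
    e_per_N: int

    def __post_init__(self) -> None:
        valid = {"NO3_to_NO2": 2, "NO2_to_N2": 3, "NO3_to_N2": 5}
        if valid.get(self.name) != self.e_per_N:
            raise ValueError(
                f"couple {self.name!r} must carry e_per_N={valid.get(self.name)}"
            )


NO3_TO_NO2 = AcceptorCouple("NO3_to_NO2", 2)
NO2_TO_N2 = AcceptorCouple("NO2_to_N2", 3)
NO3_TO_N2 = AcceptorCouple("NO3_to_N2", 5)
COUPLES: Mapping[str, AcceptorCouple] = {
    c.name: c for c in (NO3_TO_NO2, NO2_TO_N2, NO3_TO_N2)
}


@dataclass(frozen=True)
class BalancedReaction:
    """A fully balanced redox reaction on a 1-mol-donor basis.

    ``coefficients`` maps species labels (``NO3-``, ``NO2-``, ``H+``, ``H2O``,
    ``CO2``, ``N2`` and the donor name) to signed exact stoichiometric
    numbers: negative for consumed, positive for produced.
    """

    donor: ChemicalSpecies
    couple: AcceptorCouple
    coefficients: Mapping[str, Fraction]

    def coefficient(self, label: str) -> Fraction:
        return self.coefficients.get(label, Fraction(0))

    def __str__(self) -> str:
        def fmt(side: int) -> str:
            parts = []
            for label, c in self.coefficients.items():
                if (c < 0 and side < 0) or (c > 0 and side > 0):
                    mag = abs(c)
                    num = "" if mag == 1 else f"{float(mag):g} "
                    parts.append(f"{num}{label}")
            return " + ".join(parts)

        return f"{fmt(-1)} -> {fmt(+1)}"


@dataclass(frozen=True)
class CoupledDemand:
    """Donor concentration whose electrons exactly match a nitrate demand."""

    nitrate_mM: float
    donor_mM: float
    endpoint: AcceptorCouple
    donor: ChemicalSpecies
    donor_mM_exact: Fraction = field(compare=False, default=Fraction(0))

    def __post_init__(self) -> None:
        if self.nitrate_mM < 0 or self.donor_mM < 0:
            raise ValueError("concentrations must be non-negative")


_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)|(\d*)([+−-])$|(.)")


def parse_formula(text: str) -> ChemicalSpecies:
    """Parse an element-count formula over C, H, O, N with optional charge suffix.

    Accepts e.g. ``"C8H10"``, ``"C2H3O2-"`` or ``"NO3-"``; formulas with
    elements outside C/H/O/N are rejected.  The charge suffix is an optional
    count followed by ``+`` or ``-`` (ASCII hyphen or true minus sign).
    """
    s = text.strip().replace(" ", "")
    if not s:
        raise FormulaError("empty formula")
    counts = {"C": 0, "H": 0, "O": 0, "N": 0}
    charge = 0
    i = 0
    while i < len(s):
        m = _TOKEN.match(s, i)
        if m is None:  # pragma: no cover - regex always matches one char
            raise FormulaError(f"cannot tokenize {s[i:]!r} in {text!r}")
        if m.group(1):
            elem, count = m.group(1), m.group(2)
            if elem not in counts:
                raise FormulaError(f"unknown element {elem!r} in {text!r}")
            counts[elem] += int(count) if count else 1
        elif m.group(4):
            n = int(m.group(3)) if m.group(3) else 1
            charge = n if m.group(4) == "+" else -n
        else:
            raise FormulaError(f"unexpected token {m.group(5)!r} in {text!r}")
        i = m.end()
    return ChemicalSpecies(
        name=text.strip(),
        nC=counts["C"],
        nH=counts["H"],
        nO=counts["O"],
        nN=counts["N"],
        z=charge,
    )


def _with_role(sp: ChemicalSpecies, name: str, role: str) -> ChemicalSpecies:
    return ChemicalSpecies(name, sp.nC, sp.nH, sp.nO, sp.nN, sp.z, role)


DEFAULT_SPECIES: Mapping[str, ChemicalSpecies] = {
    "acetate": _with_role(parse_formula("C2H3O2-"), "acetate", "donor"),
    "benzoate": _with_role(parse_formula("C7H5O2-"), "benzoate", "donor"),
    "toluene": _with_role(parse_formula("C7H8"), "toluene", "donor"),
    "ethylbenzene": _with_role(parse_formula("C8H10"), "ethylbenzene", "donor"),
    "hmn": _with_role(parse_formula("C16H34"), "hmn", "inert"),
    "nitrate": _with_role(parse_formula("NO3-"), "nitrate", "acceptor"),
    "nitrite": _with_role(parse_formula("NO2-"), "nitrite", "acceptor"),
}

#: Electron counts matching the source study's printed coupling coefficients
#: where they differ from charge-balanced chemistry.  Benzoate (C7H5O2-) has
#: gamma = 30 by the degree-of-reduction formula; the printed coupling of
#: 10 mM nitrate to 1.72 mM benzoate implies 29 e-/mol.  Pass this mapping as
#: ``overrides`` to reproduce that figure; the default is correct chemistry.
PAPER_COMPAT_ELECTRONS: Mapping[str, int] = {"benzoate": 29}


def load_species_registry(path: str | Path) -> dict[str, ChemicalSpecies]:
    """Read a TSV registry with columns name, formula, charge, role.

    ``charge`` may be blank when already encoded in the formula suffix.
    """
    registry: dict[str, ChemicalSpecies] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"name", "formula", "role"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise ValueError(f"registry {path}: needs columns {sorted(required)}")
        for row in reader:
            sp = parse_formula(row["formula"])
            z = int(row["charge"]) if row.get("charge") else sp.z
            registry[row["name"]] = ChemicalSpecies(
                row["name"], sp.nC, sp.nH, sp.nO, sp.nN, z, row["role"]
            )
    return registry


def resolve_donor(donor: str | ChemicalSpecies) -> ChemicalSpecies:
    """Accept a registry name, a formula string, or a species object."""
    if isinstance(donor, ChemicalSpecies):
        return donor
    key = donor.strip().lower()
    if key in DEFAULT_SPECIES:
        return DEFAULT_SPECIES[key]
    return _with_role(parse_formula(donor), donor.strip(), "donor")


def electron_equivalents(
    species: ChemicalSpecies,
    overrides: Mapping[str, int] | None = None,
) -> ElectronEquivalents:
    """Degree of reduction: electrons released per mol on oxidation of C to CO2.

    ``overrides`` maps species names to replacement electron counts (see
    :data:`PAPER_COMPAT_ELECTRONS`).
    """
    if species.nN > 0 and species.role == "donor":
        raise StoichiometryError(
            f"{species.name}: nitrogen-containing donors are not supported"
        )
    gamma = species.gamma
    if overrides and species.name in overrides:
        gamma = overrides[species.name]
    return ElectronEquivalents(species, gamma)


def donor_demand(
    nitrate_mM: float,
    donor: str | ChemicalSpecies,
    endpoint: AcceptorCouple = NO3_TO_N2,
    decimals: int = 2,
    overrides: Mapping[str, int] | None = None,
) -> CoupledDemand:
    """Donor concentration whose complete oxidation reduces ``nitrate_mM`` of nitrate.

    donor_mM = nitrate_mM * e_per_N / gamma.  The returned ``donor_mM`` is
    rounded half-up to ``decimals``; the exact rational is kept alongside.
    """
    if nitrate_mM < 0:
        raise ValueError("nitrate_mM must be non-negative")
    sp = resolve_donor(donor)
    gamma = electron_equivalents(sp, overrides).gamma
    if gamma <= 0:
        raise StoichiometryError(f"{sp.name}: no electrons to donate (gamma={gamma})")
    exact = Fraction(nitrate_mM).limit_denominator(10**9) * endpoint.e_per_N / gamma
    return CoupledDemand(
        nitrate_mM=nitrate_mM,
        donor_mM=round_half_up(float(exact), decimals),
        endpoint=endpoint,
        donor=sp,
        donor_mM_exact=exact,
    )


def balance_reaction(
    donor: str | ChemicalSpecies,
    endpoint: AcceptorCouple = NO3_TO_N2,
) -> BalancedReaction:
    """Balance donor oxidation against a nitrogen couple on a 1-mol-donor basis.

    Carbon goes to CO2; H+ and H2O close the hydrogen/oxygen/charge balance.
    Coefficients are exact rationals; every result satisfies
    :func:`verify_balance` with zero residuals.
    """
    sp = resolve_donor(donor)
    gamma = electron_equivalents(sp).gamma
    if gamma <= 0:
        raise StoichiometryError(f"{sp.name}: not an electron donor (gamma={gamma})")

    n_acc = Fraction(gamma, endpoint.e_per_N)  # mol N-oxyanion consumed
    coeffs: dict[str, Fraction] = {sp.name: Fraction(-1), "CO2": Fraction(sp.nC)}

    if endpoint.name == "NO3_to_NO2":
        coeffs["NO3-"] = -n_acc
        coeffs["NO2-"] = n_acc
        h_plus = Fraction(-sp.z)  # consumed when positive
    elif endpoint.name == "NO2_to_N2":
        coeffs["NO2-"] = -n_acc
        coeffs["N2"] = n_acc / 2
        h_plus = n_acc - sp.z
    else:  # NO3_to_N2
        coeffs["NO3-"] = -n_acc
        coeffs["N2"] = n_acc / 2
        h_plus = n_acc - sp.z

    coeffs["H+"] = -h_plus
    coeffs["H2O"] = (Fraction(sp.nH) + h_plus) / 2

    rxn = BalancedReaction(sp, endpoint, coeffs)
    residuals = verify_balance(rxn)
    bad = {k: v for k, v in residuals.items() if v != 0}
    if bad:  # pragma: no cover - construction guarantees balance
        raise StoichiometryError(f"{sp.name}: unbalanceable, residuals {bad}")
    # H2O/H+ may sit on either side; gas and oxyanion products must not
    products = {"CO2", "N2"} | ({"NO2-"} if endpoint.name == "NO3_to_NO2" else set())
    for label in products:
        if coeffs.get(label, Fraction(0)) < 0:
            raise StoichiometryError(f"{sp.name}: negative product {label}")
    return rxn


_COMPOSITION: Mapping[str, tuple[int, int, int, int, int]] = {
    # label -> (nC, nH, nO, nN, z)
    "NO3-": (0, 0, 3, 1, -1),
    "NO2-": (0, 0, 2, 1, -1),
    "H+": (0, 1, 0, 0, 1),
    "H2O": (0, 2, 1, 0, 0),
    "CO2": (1, 0, 2, 0, 0),
    "N2": (0, 0, 0, 2, 0),
}


def verify_balance(rxn: BalancedReaction) -> dict[str, Fraction]:
    """Per-element (C, H, O, N) and charge residuals; all zero iff balanced."""
    residuals = {k: Fraction(0) for k in ("C", "H", "O", "N", "charge")}
    for label, coeff in rxn.coefficients.items():
        if label == rxn.donor.name:
            comp = (rxn.donor.nC, rxn.donor.nH, rxn.donor.nO, rxn.donor.nN, rxn.donor.z)
        elif label in _COMPOSITION:
            comp = _COMPOSITION[label]
        else:
            raise StoichiometryError(f"unknown reaction species {label!r}")
        for key, atoms in zip(("C", "H", "O", "N", "charge"), comp):
            residuals[key] += coeff * atoms
    return residuals
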