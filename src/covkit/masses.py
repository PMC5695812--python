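"""Exact-mass arithmetic for formulas, ions, covalent adducts and peptides.

The bookkeeping implemented here covers what a covalent-inhibitor study
needs from a mass calculator: monoisotopic/average masses of molecular
formulas, m/z of simple adduct ions ([M+H]+, [M+Na]+, [M+nH]n+), the mass
shift a warhead leaves on its target after loss of a leaving group (for a
chloroacetamide alkylating a cysteine the leaving group is HCl), and
neutral masses of peptides carrying positional modifications.

No electron-mass correction is applied anywhere (see
:mod:`covkit._masstables`); no isotope envelopes or fragment ladders are
produced.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence, Union

from ._masstables import (
    ELEMENT_MASSES,
    PROTON_MASS,
    PROTON_SYMBOL,
    RESIDUE_MASSES,
)

MassType = Literal["monoisotopic", "average"]

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")

__all__ = [
    "Formula",
    "PeptideSpec",
    "IonSpec",
    "parse_formula",
    "formula_mass",
    "ion_mz",
    "peptide_neutral_mass",
    "adduct_mass_shift",
    "WATER",
    "HCL",
    "CARBAMIDOMETHYL",
]


@dataclass(frozen=True)
class Formula:
    """An elemental composition: element symbol -> positive atom count."""

    composition: Mapping[str, int]

    def __post_init__(self) -> None:
        comp = dict(self.composition)
        if not comp:
            raise ValueError("empty formula")
        for symbol, count in comp.items():
            if symbol not in ELEMENT_MASSES:
                raise ValueError(f"unknown element symbol: {symbol!r}")
            if not isinstance(count, int) or count < 1:
                raise ValueError(f"count for {symbol} must be a positive integer, got {count!r}")
        object.__setattr__(self, "composition", comp)

    def __add__(self, other: "Formula") -> "Formula":
        comp = dict(self.composition)
        for symbol, count in other.composition.items():
            comp[symbol] = comp.get(symbol, 0) + count
        return Formula(comp)

    def __sub__(self, other: "Formula") -> "Formula":
        comp = dict(self.composition)
        for symbol, count in other.composition.items():
            new = comp.get(symbol, 0) - count
            if new < 0:
                raise ValueError(
                    f"subtraction gives negative count for {symbol} "
                    f"({comp.get(symbol, 0)} - {count})"
                )
            if new == 0:
                del comp[symbol]
            else:
                comp[symbol] = new
        return Formula(comp)

    def __str__(self) -> str:
        return "".join(
            f"{sym}{n if n > 1 else ''}" for sym, n in sorted(self.composition.items())
        )


WATER = Formula({"H": 2, "O": 1})
HCL = Formula({"H": 1, "Cl": 1})
#: cysteine carbamidomethylation (iodoacetamide alkylation), +57.0215 Da
CARBAMIDOMETHYL = Formula({"C": 2, "H": 3, "N": 1, "O": 1})

ModShift = Union[float, Formula]


@dataclass(frozen=True)
class PeptideSpec:
    """A peptide sequence with optional positional modifications.

    Modifications are ``(position, shift)`` pairs with 1-based positions
    into the sequence; a shift is either a raw mass delta in Da (used
    verbatim, never rounded) or a :class:`Formula` delta evaluated under
    the requested mass type.
    """

    sequence: str
    modifications: Sequence[tuple[int, ModShift]] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("empty peptide sequence")
        for residue in self.sequence:
            if residue not in RESIDUE_MASSES:
                raise ValueError(f"unknown residue code: {residue!r}")
        seen: set[int] = set()
        for pos, _shift in self.modifications:
            if not 1 <= pos <= len(self.sequence):
                raise ValueError(
                    f"modification position {pos} outside sequence of length {len(self.sequence)}"
                )
            if pos in seen:
                raise ValueError(f"position {pos} carries more than one modification")
            seen.add(pos)
        object.__setattr__(self, "modifications", tuple(self.modifications))


@dataclass(frozen=True)
class IonSpec:
    """Charge-carrier description of an adduct ion.

    ``species`` lists one charge carrier per unit charge: an element
    symbol ("H", "Na", "K", ...) whose atomic mass is added, or "H+" for
    a bare proton. The number of carriers must equal the charge.
    """

    species: tuple[str, ...]
    charge: int

    def __post_init__(self) -> None:
        if self.charge < 1:
            raise ValueError(f"charge must be >= 1, got {self.charge}")
        if len(self.species) != self.charge:
            raise ValueError(
                f"number of charge carriers ({len(self.species)}) must equal charge ({self.charge})"
            )
        for sym in self.species:
            if sym != PROTON_SYMBOL and sym not in ELEMENT_MASSES:
                raise ValueError(f"unknown adduct species: {sym!r}")
        object.__setattr__(self, "species", tuple(self.species))

    @classmethod
    def protonated(cls, charge: int = 1, bare_proton: bool = False) -> "IonSpec":
        sym = PROTON_SYMBOL if bare_proton else "H"
        return cls((sym,) * charge, charge)

    @classmethod
    def sodiated(cls) -> "IonSpec":
        return cls(("Na",), 1)


def parse_formula(text: str) -> Formula:
    """Parse Hill-style notation like ``"C21H19N2O5Cl"`` into a Formula.

    An omitted count means 1. Unknown symbols, explicit zero counts and
    empty strings raise ``ValueError``.
    """
    if not text:
        raise ValueError("empty formula string")
    composition: dict[str, int] = {}
    pos = 0
    while pos < len(text):
        match = _FORMULA_TOKEN.match(text, pos)
        if match is None or match.start() != pos or not match.group(1):
            raise ValueError(f"cannot parse formula {text!r} at position {pos}")
        symbol, digits = match.group(1), match.group(2)
        if symbol not in ELEMENT_MASSES:
            raise ValueError(f"unknown element symbol {symbol!r} in {text!r}")
        count = int(digits) if digits else 1
        if count == 0:
            raise ValueError(f"zero count for {symbol} in {text!r}")
        composition[symbol] = composition.get(symbol, 0) + count
        pos = match.end()
    return Formula(composition)


def _element_mass(symbol: str, mass_type: MassType) -> float:
    mono, avg = ELEMENT_MASSES[symbol]
    return mono if mass_type == "monoisotopic" else avg


def formula_mass(formula: Formula, mass_type: MassType = "monoisotopic") -> float:
    """Sum of count x atomic mass over the composition, in Da."""
    return sum(n * _element_mass(sym, mass_type) for sym, n in formula.composition.items())


def ion_mz(neutral_mass: float, ion: IonSpec, mass_type: MassType = "monoisotopic") -> float:
    """m/z of ``neutral_mass`` carrying the given adduct species.

    (neutral mass + sum of carrier masses) / charge. Element carriers use
    atomic masses (the HRMS "calcd" convention); the "H+" carrier uses the
    bare proton mass.
    """
    if neutral_mass <= 0:
        raise ValueError(f"neutral mass must be positive, got {neutral_mass}")
    carriers = sum(
        PROTON_MASS if sym == PROTON_SYMBOL else _element_mass(sym, mass_type)
        for sym in ion.species
    )
    return (neutral_mass + carriers) / ion.charge


def peptide_neutral_mass(spec: PeptideSpec, mass_type: MassType = "monoisotopic") -> float:
    """Neutral mass: residue sum + one water + modification shifts, in Da."""
    idx = 0 if mass_type == "monoisotopic" else 1
    total = sum(RESIDUE_MASSES[res][idx] for res in spec.sequence)
    total += formula_mass(WATER, mass_type)
    for _pos, shift in spec.modifications:
        if isinstance(shift, Formula):
            total += formula_mass(shift, mass_type)
        else:
            total += float(shift)
    return total


def adduct_mass_shift(
    inhibitor: Formula,
    leaving_group: Formula | None,
    mass_type: MassType = "monoisotopic",
) -> float:
    """Mass delta a covalent warhead adds to its target residue.

    formula_mass(inhibitor) - formula_mass(leaving_group); the subtraction
    is validated at the composition level so an impossible leaving group
    raises rather than producing a negative-count formula. ``None`` (or an
    empty leaving group) returns the inhibitor mass unchanged.
    """
    if leaving_group is None:
        return formula_mass(inhibitor, mass_type)
    inhibitor - leaving_group  # raises if any count would go negative
    return formula_mass(inhibitor, mass_type) - formula_mass(leaving_group, mass_type)
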