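"""Monoisotopic mass constants.

All masses in Da, stated to six decimals. Residue masses are the standard
IUPAC monoisotopic values for the 20 canonical amino-acid residues
(i.e. the amino acid minus water, as incorporated in a peptide chain).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from types import MappingProxyType
from typing import Mapping

RESIDUE_MONOISOTOPIC: Mapping[str, float] = MappingProxyType({
    "G": 57.021464,
    "A": 71.037114,
    "S": 87.032028,
    "P": 97.052764,
    "V": 99.068414,
    "T": 101.047679,
    "C": 103.009185,
    "L": 113.084064,
    "I": 113.084064,
    "N": 114.042927,
    "D": 115.026943,
    "Q": 128.058578,
    "K": 128.094963,
    "E": 129.042593,
    "M": 131.040485,
    "H": 137.058912,
    "F": 147.068414,
    "R": 156.101111,
    "Y": 163.063329,
    "W": 186.079313,
})

WATER = 18.010565          # H2O
PROTON = 1.007276          # H+
CO = 27.994915             # carbon monoxide (b -> a ion offset)

# Atomic monoisotopic masses used to derive the linker mass.
MASS_H = 1.007825
MASS_C = 12.000000
MASS_O = 15.994915

# Methylene bridge left by formaldehyde cross-linking: condensation of
# CH2O with loss of H2O adds exactly one carbon-12 per bridge.
LINKER_SINGLE = (MASS_C + 2 * MASS_H + MASS_O) - (2 * MASS_H + MASS_O)
LINKER_DOUBLE = 2 * LINKER_SINGLE

CARBAMIDOMETHYL = 57.021464  # fixed Cys alkylation (chloroacetamide)

# Residues formaldehyde reacts with, in decreasing order of reactivity.
REACTIVE_RESIDUES = ("K", "R", "N", "H", "D", "Y", "Q")


@dataclass(frozen=True)
class MassConstants:
    """Bundle of masses used throughout digestion, fragment and precursor math."""

    residue_monoisotopic: Mapping[str, float] = field(
        default_factory=lambda: RESIDUE_MONOISOTOPIC
    )
    water: float = WATER
    proton: float = PROTON
    linker_single: float = LINKER_SINGLE
    linker_double: float = LINKER_DOUBLE
    fixed_mods: Mapping[str, float] = field(
        default_factory=lambda: MappingProxyType({"C": CARBAMIDOMETHYL})
    )

    def __post_init__(self) -> None:
        if abs(self.linker_double - 2 * self.linker_single) > 1e-9:
            raise ValueError("double linker mass must be twice the single linker mass")
        if self.water <= 0 or self.proton <= 0 or self.linker_single <= 0:
            raise ValueError("masses must be positive")

    def residue_mass(self, residue: str) -> float:
        """Monoisotopic residue mass including any fixed modification."""
        try:
            base = self.residue_monoisotopic[residue]
        except KeyError:
            raise KeyError(f"unknown residue {residue!r}") from None
        return base + self.fixed_mods.get(residue, 0.0)


DEFAULT_CONSTANTS = MassConstants()
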