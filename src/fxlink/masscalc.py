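"""Deterministic peptide chemistry.

Tryptic digestion (trypsin/P: cleavage C-terminal of K/R, also before
proline), monoisotopic peptide masses with fixed modifications, theoretical
a/b/y fragment ions including the +12 Da formaldehyde-shifted series, and
ppm mass comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .constants import CO, DEFAULT_CONSTANTS, MassConstants

__all__ = [
    "Peptide",
    "FragmentIon",
    "digest",
    "peptide_mass",
    "fragment_ions",
    "fragment_neutral_masses",
    "ppm_delta",
    "ppm_match",
    "validate_sequence",
]

CANONICAL = frozenset("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class Peptide:
    """A tryptic peptide located within its parent protein (1-based start)."""

    sequence: str
    protein_id: str = ""
    start: int = 1
    missed_cleavages: int = 0
    is_decoy: bool = False

    def __post_init__(self) -> None:
        validate_sequence(self.sequence)
        if self.start < 1:
            raise ValueError("start must be >= 1")
        if self.missed_cleavages < 0:
            raise ValueError("missed_cleavages must be >= 0")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def end(self) -> int:
        """1-based index of the last residue in the parent protein."""
        return self.start + len(self.sequence) - 1


@dataclass(frozen=True)
class FragmentIon:
    """One theoretical fragment ion; ``shifted`` ions carry the +12 Da remnant."""

    series: str
    index: int
    charge: int
    shifted: bool
    mz: float

    def __post_init__(self) -> None:
        if self.series not in ("a", "b", "y"):
            raise ValueError(f"unsupported ion series {self.series!r}")
        if self.index < 1 or self.charge < 1 or self.mz <= 0:
            raise ValueError("invalid fragment ion")

    @property
    def label(self) -> str:
        shift = "+12" if self.shifted else ""
        return f"{self.series}{self.index}{shift}^{self.charge}"


def validate_sequence(sequence: str) -> None:
    """Reject empty or non-canonical sequences, naming the offending position."""
    if not sequence:
        raise ValueError("empty peptide/protein sequence")
    for pos, ch in enumerate(sequence, start=1):
        if ch not in CANONICAL:
            raise ValueError(
                f"non-canonical residue {ch!r} at position {pos}"
            )


def cleavage_sites(sequence: str) -> list[int]:
    """0-based indices i such that trypsin/P cuts between sequence[i] and [i+1].

    Trypsin/P cuts C-terminal of every K and R, including before proline.
    """
    return [i for i in range(len(sequence) - 1) if sequence[i] in "KR"]


def digest(
    protein_sequence: str,
    max_missed: int = 4,
    length_range: tuple[int, int] = (5, 60),
    protein_id: str = "",
    is_decoy: bool = False,
) -> list[Peptide]:
    """Tryptic (trypsin/P) digestion with up to ``max_missed`` missed cleavages.

    Returns peptides in order of start position; peptides whose length falls
    outside ``length_range`` (inclusive) are excluded.
    """
    validate_sequence(protein_sequence)
    if max_missed < 0:
        raise ValueError("max_missed must be >= 0")
    lo, hi = length_range
    cuts = cleavage_sites(protein_sequence)
    # fragment boundaries: [start, end) pairs of the 0-missed-cleavage pieces
    bounds = [0] + [c + 1 for c in cuts] + [len(protein_sequence)]
    peptides: list[Peptide] = []
    n_pieces = len(bounds) - 1
    for i in range(n_pieces):
        for m in range(max_missed + 1):
            j = i + m + 1
            if j > n_pieces:
                break
            start, end = bounds[i], bounds[j]
            if not (lo <= end - start <= hi):
                continue
            peptides.append(
                Peptide(
                    sequence=protein_sequence[start:end],
                    protein_id=protein_id,
                    start=start + 1,
                    missed_cleavages=m,
                    is_decoy=is_decoy,
                )
            )
    peptides.sort(key=lambda p: (p.start, len(p.sequence)))
    return peptides


def peptide_mass(
    peptide: Peptide | str, constants: MassConstants = DEFAULT_CONSTANTS
) -> float:
    """Neutral monoisotopic mass: residue sum + water + fixed modifications."""
    sequence = peptide.sequence if isinstance(peptide, Peptide) else peptide
    validate_sequence(sequence)
    return sum(constants.residue_mass(r) for r in sequence) + constants.water


def fragment_neutral_masses(
    sequence: str, constants: MassConstants = DEFAULT_CONSTANTS
) -> dict[str, np.ndarray]:
    """Neutral fragment masses per series, index 1..n-1 (array position i-1)."""
    validate_sequence(sequence)
    n = len(sequence)
    if n < 2:
        raise ValueError("fragment ions require peptide length >= 2")
    res = np.array([constants.residue_mass(r) for r in sequence])
    prefix = np.cumsum(res)[:-1]            # b_i neutral masses
    suffix = np.cumsum(res[::-1])[:-1] + constants.water  # y_i neutral masses
    return {"b": prefix, "a": prefix - CO, "y": suffix}


def fragment_ions(
    peptide: Peptide | str,
    series: Iterable[str] = ("a", "b", "y"),
    charges: Iterable[int] = (1,),
    include_shifted: bool = True,
    constants: MassConstants = DEFAULT_CONSTANTS,
) -> list[FragmentIon]:
    """Theoretical fragment ions for the requested series and charge states.

    When ``include_shifted`` is set, every ion gets a +12 Da twin (the
    formaldehyde linker remnant), offset by ``linker_single/charge`` in m/z.
    """
    sequence = peptide.sequence if isinstance(peptide, Peptide) else peptide
    neutrals = fragment_neutral_masses(sequence, constants)
    shift_states = (False, True) if include_shifted else (False,)
    ions: list[FragmentIon] = []
    for s in series:
        masses = neutrals[s]
        for z in charges:
            for shifted in shift_states:
                shift = constants.linker_single if shifted else 0.0
                mzs = (masses + shift + z * constants.proton) / z
                ions.extend(
                    FragmentIon(series=s, index=i + 1, charge=z, shifted=shifted, mz=mz)
                    for i, mz in enumerate(mzs)
                )
    return ions


def ppm_delta(observed_mz: float, theoretical_mz: float) -> float:
    """Signed relative mass error in parts per million."""
    if observed_mz <= 0 or theoretical_mz <= 0:
        raise ValueError("m/z values must be positive")
    return 1e6 * (observed_mz - theoretical_mz) / theoretical_mz


def ppm_match(observed_mz: float, theoretical_mz: float, tolerance_ppm: float) -> bool:
    """Inclusive tolerance check: |ppm| <= tolerance."""
    return abs(ppm_delta(observed_mz, theoretical_mz)) <= tolerance_ppm
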