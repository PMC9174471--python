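"""Mapping cross-links onto structures and Cα distance restraint checks.

Cross-links report residue pairs in protein (UniProt-like) coordinates; this
module aligns protein sequences to structure chains (ungapped sliding
alignment, sufficient for identical-sequence chains), resolves homo-oligomer
chain copies, and classifies the minimal Cα–Cα Euclidean distance against the
30 Å restraint expected for a formaldehyde bridge plus side-chain flexibility.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import gemmi
import numpy as np
import pandas as pd

from .xl_consensus import ConsensusCrossLink

__all__ = [
    "ChainModel",
    "StructureModel",
    "ChainAssignment",
    "DistanceAssessment",
    "load_structure",
    "map_protein_to_chains",
    "min_ca_distance",
    "restraint_summary",
    "assessments_to_table",
]

SATISFIED = "satisfied"
OVER_LENGTH = "over_length"
UNMAPPED = "unmapped"

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}


@dataclass
class ChainModel:
    """One polymer chain: sequence, per-residue Cα coordinates, author numbers."""

    chain_id: str
    sequence: str
    ca_xyz: np.ndarray       # (n, 3); NaN rows mark residues without observed Cα
    author_numbers: np.ndarray  # (n,) author seq ids aligned with sequence

    def __post_init__(self) -> None:
        self.ca_xyz = np.asarray(self.ca_xyz, dtype=float).reshape(-1, 3)
        self.author_numbers = np.asarray(self.author_numbers, dtype=int)
        if len(self.sequence) != len(self.ca_xyz):
            raise ValueError("sequence and coordinate lengths differ")


@dataclass
class StructureModel:
    structure_id: str
    chains: list[ChainModel]


@dataclass(frozen=True)
class ChainAssignment:
    """Alignment of a protein to one chain.

    ``protein_start`` is the 1-based protein residue aligned with the chain's
    first residue; protein residue r maps to chain index r - protein_start.
    ``offset`` is the author-number minus protein-number shift.
    """

    chain_id: str
    protein_start: int
    identity: float
    offset: int


@dataclass
class DistanceAssessment:
    link: ConsensusCrossLink
    structure_id: str
    chain_pair_best: tuple[str, str] | None
    ca_distance: float  # Å; NaN when unmapped
    verdict: str
    reason: str = ""


def load_structure(path: str | Path, structure_id: str | None = None) -> StructureModel:
    """Read an mmCIF or PDB file into a CA-trace model (first model only)."""
    st = gemmi.read_structure(str(path))
    st.setup_entities()
    model = st[0]
    chains: list[ChainModel] = []
    for chain in model:
        seq, coords, numbers = [], [], []
        for res in chain:
            one = THREE_TO_ONE.get(res.name.upper())
            if one is None:
                continue  # ligands, water, nucleic acids
            ca = res.find_atom("CA", "*")
            seq.append(one)
            numbers.append(res.seqid.num)
            if ca is not None:
                coords.append([ca.pos.x, ca.pos.y, ca.pos.z])
            else:
                coords.append([np.nan, np.nan, np.nan])
        if seq:
            chains.append(
                ChainModel(chain.name, "".join(seq), np.array(coords), np.array(numbers))
            )
    if not chains:
        raise ValueError(f"no polymer chains with Cα atoms in {path}")
    return StructureModel(structure_id or Path(path).stem, chains)


def map_protein_to_chains(
    protein_sequence: str,
    model: StructureModel,
    min_identity: float = 0.9,
    min_overlap: int = 10,
) -> list[ChainAssignment]:
    """Ungapped sliding alignment of each chain against the protein.

    Every chain whose best full-chain placement reaches ``min_identity`` over
    the aligned span is returned (homo-oligomers yield several assignments).
    """
    prot = np.frombuffer(protein_sequence.encode(), dtype="S1")
    out: list[ChainAssignment] = []
    for chain in model.chains:
        ch = np.frombuffer(chain.sequence.encode(), dtype="S1")
        best = None
        # protein_start s (1-based) such that chain[0] pairs with protein[s]
        for s in range(1 - len(ch) + min_overlap, len(prot) - min_overlap + 2):
            p0 = max(0, s - 1)
            c0 = p0 - (s - 1)
            span = min(len(prot) - p0, len(ch) - c0)
            if span < min_overlap:
                continue
            ident = float(np.mean(prot[p0 : p0 + span] == ch[c0 : c0 + span]))
            if best is None or ident > best[0]:
                best = (ident, s)
        if best is not None and best[0] >= min_identity:
            s = best[1]
            offset = int(chain.author_numbers[0]) - s
            out.append(ChainAssignment(chain.chain_id, s, best[0], offset))
    return out


def _ca_for_protein_residue(
    chain: ChainModel, assignment: ChainAssignment, residue: int
) -> np.ndarray | None:
    idx = residue - assignment.protein_start
    if idx < 0 or idx >= len(chain.sequence):
        return None
    xyz = chain.ca_xyz[idx]
    if np.any(np.isnan(xyz)):
        return None
    return xyz


def min_ca_distance(
    link: ConsensusCrossLink,
    model: StructureModel,
    assignments_a: Sequence[ChainAssignment],
    assignments_b: Sequence[ChainAssignment],
    threshold: float = 30.0,
) -> DistanceAssessment:
    """Minimal Cα–Cα distance over all chain-copy combinations.

    For homo-multimer links only distinct chain copies are allowed (the link
    is evidence of two protein copies, so the trivial same-chain same-residue
    pairing is excluded). Exactly ``threshold`` counts as satisfied; strictly
    greater is over-length.
    """
    chain_by_id = {c.chain_id: c for c in model.chains}
    if not assignments_a or not assignments_b:
        return DistanceAssessment(link, model.structure_id, None, float("nan"),
                                  UNMAPPED, "no chain assignment")
    best: tuple[float, tuple[str, str]] | None = None
    missing = False
    for asg_a in assignments_a:
        xyz_a = _ca_for_protein_residue(chain_by_id[asg_a.chain_id], asg_a, link.site_a)
        if xyz_a is None:
            missing = True
            continue
        for asg_b in assignments_b:
            same_chain = asg_a.chain_id == asg_b.chain_id
            if link.homomultimer_flag and same_chain:
                continue
            if same_chain and link.protein_a == link.protein_b and link.site_a == link.site_b:
                continue  # a residue cannot cross-link to itself in one copy
            xyz_b = _ca_for_protein_residue(chain_by_id[asg_b.chain_id], asg_b, link.site_b)
            if xyz_b is None:
                missing = True
                continue
            d = float(np.linalg.norm(xyz_a - xyz_b))
            if best is None or d < best[0]:
                best = (d, (asg_a.chain_id, asg_b.chain_id))
    if best is None:
        reason = "site not observed in model" if missing else "no admissible chain pair"
        return DistanceAssessment(link, model.structure_id, None, float("nan"),
                                  UNMAPPED, reason)
    distance, pair = best
    verdict = OVER_LENGTH if distance > threshold else SATISFIED
    return DistanceAssessment(link, model.structure_id, pair, distance, verdict)


def assess_links(
    links: Sequence[ConsensusCrossLink],
    model: StructureModel,
    protein_sequences: dict[str, str],
    threshold: float = 30.0,
    min_identity: float = 0.9,
) -> list[DistanceAssessment]:
    """Map every link's proteins onto the model and assess the restraint."""
    cache: dict[str, list[ChainAssignment]] = {}

    def assignments(acc: str) -> list[ChainAssignment]:
        if acc not in cache:
            seq = protein_sequences.get(acc)
            cache[acc] = (
                map_protein_to_chains(seq, model, min_identity) if seq else []
            )
        return cache[acc]

    return [
        min_ca_distance(link, model, assignments(link.protein_a),
                        assignments(link.protein_b), threshold)
        for link in links
    ]


def restraint_summary(assessments: Sequence[DistanceAssessment]) -> pd.DataFrame:
    """(satisfied, over_length, unmapped) tallies per condition and structure."""
    keys = sorted({(a.link.condition, a.structure_id) for a in assessments})
    rows = []
    for cond, sid in keys:
        group = [a for a in assessments if (a.link.condition, a.structure_id) == (cond, sid)]
        rows.append(
            {
                "condition": cond,
                "structure_id": sid,
                "satisfied": sum(a.verdict == SATISFIED for a in group),
                "over_length": sum(a.verdict == OVER_LENGTH for a in group),
                "unmapped": sum(a.verdict == UNMAPPED for a in group),
            }
        )
    if not rows:
        rows = [{"condition": "", "structure_id": "", "satisfied": 0,
                 "over_length": 0, "unmapped": 0}]
    return pd.DataFrame(rows)


def assessments_to_table(assessments: Sequence[DistanceAssessment]) -> pd.DataFrame:
    rows = []
    for a in assessments:
        rows.append(
            {
                "structure_id": a.structure_id,
                "condition": a.link.condition,
                "protein_a": a.link.protein_a,
                "protein_b": a.link.protein_b,
                "site_a": a.link.site_a,
                "site_b": a.link.site_b,
                "chain_a": a.chain_pair_best[0] if a.chain_pair_best else "",
                "chain_b": a.chain_pair_best[1] if a.chain_pair_best else "",
                "ca_distance": round(a.ca_distance, 3) if np.isfinite(a.ca_distance) else "",
                "verdict": a.verdict,
                "reason": a.reason,
            }
        )
    return pd.DataFrame(rows)
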