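"""Replicate consensus for residue-pair cross-links.

Per-replicate hits are merged into residue-pair cross-links, ranked with the
1..7 replicate-evidence score (1 = high confidence in all three replicates,
7 = intermediate in a single replicate) and accepted when the score is <= 4.
Intra-protein links whose supporting peptides overlap in protein coordinates
are flagged as homo-multimer links (two copies of the same protein).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .xl_search import HIGH, INTERMEDIATE, CrossLinkHit

__all__ = [
    "ConsensusCrossLink",
    "consensus_score",
    "accept",
    "build_consensus",
    "flag_homomultimer",
    "build_network",
]

ABSENT = "absent"

INTER = "inter_protein"
INTRA = "intra_protein"


@dataclass
class ConsensusCrossLink:
    """A residue-pair cross-link aggregated over the replicates of a condition."""

    protein_a: str
    protein_b: str
    site_a: int
    site_b: int
    per_replicate: dict[str, str]
    score: int
    condition: str = ""
    homomultimer_flag: bool = False
    supporting_hits: tuple[CrossLinkHit, ...] = ()

    @property
    def link_type(self) -> str:
        return INTRA if self.protein_a == self.protein_b else INTER


def consensus_score(per_replicate: Iterable[str] | Mapping[str, str]) -> int | None:
    """The 1..7 replicate-evidence score.

    1: high in three replicates; 2: high in two; 3: high in one plus at least
    one intermediate; 4: intermediate in three; 5: intermediate in two;
    6: high in one; 7: intermediate in one. With more than three replicates
    the category counts generalise (>=3 high -> 1, etc.). No evidence at all
    yields None (no consensus record).
    """
    states = list(per_replicate.values()) if isinstance(per_replicate, Mapping) else list(per_replicate)
    for s in states:
        if s not in (HIGH, INTERMEDIATE, ABSENT):
            raise ValueError(f"unknown evidence state {s!r}")
    n_high = states.count(HIGH)
    n_int = states.count(INTERMEDIATE)
    if n_high >= 3:
        return 1
    if n_high == 2:
        return 2
    if n_high == 1 and n_int >= 1:
        return 3
    if n_int >= 3:
        return 4
    if n_int == 2:
        return 5
    if n_high == 1:
        return 6
    if n_int == 1:
        return 7
    return None


def accept(link: ConsensusCrossLink) -> bool:
    """Acceptance rule: replicate score <= 4."""
    return link.score <= 4


def _canonical_hit_key(hit: CrossLinkHit) -> tuple:
    """Orientation-free identity pieces of a hit in protein coordinates."""
    a = (hit.peptide_a.protein_id, hit.site_in_protein("a"), hit.interval_in_protein("a"),
         (hit.peptide_a.start, hit.peptide_a.end))
    b = (hit.peptide_b.protein_id, hit.site_in_protein("b"), hit.interval_in_protein("b"),
         (hit.peptide_b.start, hit.peptide_b.end))
    return (a, b) if a <= b else (b, a)


def _intervals_overlap(x: tuple[int, int], y: tuple[int, int]) -> bool:
    return x[0] <= y[1] and y[0] <= x[1]


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        self.parent[self.find(i)] = self.find(j)


def build_consensus(
    hits_by_replicate: Mapping[str, Sequence[CrossLinkHit]],
    condition: str = "",
    merge: str = "residue",
) -> list[ConsensusCrossLink]:
    """Aggregate per-replicate hits into scored residue-pair cross-links.

    Identity of a cross-link across replicates is the canonically ordered
    (protein_a, protein_b, site_a, site_b); hits whose assigned sites differ
    but whose site-uncertainty intervals overlap on both ends are merged, the
    consensus site being the middle of the interval intersection
    (``merge="residue"``, default). ``merge="peptide"`` groups by peptide-pair
    identity instead.
    """
    if merge not in ("residue", "peptide"):
        raise ValueError("merge must be 'residue' or 'peptide'")
    records: list[tuple[str, CrossLinkHit, tuple]] = []
    for rep, hits in hits_by_replicate.items():
        for hit in hits:
            if hit.confidence not in (HIGH, INTERMEDIATE):
                continue
            records.append((rep, hit, _canonical_hit_key(hit)))
    if not records:
        return []

    uf = _UnionFind(len(records))
    for i in range(len(records)):
        (pa_i, pb_i) = records[i][2][0][0], records[i][2][1][0]
        for j in range(i + 1, len(records)):
            (pa_j, pb_j) = records[j][2][0][0], records[j][2][1][0]
            if (pa_i, pb_i) != (pa_j, pb_j):
                continue
            if merge == "peptide":
                same = records[i][2][0][3] == records[j][2][0][3] and \
                    records[i][2][1][3] == records[j][2][1][3]
                if same:
                    uf.union(i, j)
            else:
                ia_i, ib_i = records[i][2][0][2], records[i][2][1][2]
                ia_j, ib_j = records[j][2][0][2], records[j][2][1][2]
                if _intervals_overlap(ia_i, ia_j) and _intervals_overlap(ib_i, ib_j):
                    uf.union(i, j)

    groups: dict[int, list[tuple[str, CrossLinkHit, tuple]]] = {}
    for i, rec in enumerate(records):
        groups.setdefault(uf.find(i), []).append(rec)

    replicate_ids = list(hits_by_replicate)
    links: list[ConsensusCrossLink] = []
    for members in groups.values():
        per_rep = {rep: ABSENT for rep in replicate_ids}
        for rep, hit, _ in members:
            state = hit.confidence
            if state == HIGH or per_rep[rep] == ABSENT:
                per_rep[rep] = state
            elif per_rep[rep] != HIGH:
                per_rep[rep] = state
        score = consensus_score(per_rep)
        if score is None:
            continue
        # consensus coordinates: intersection (or min-bound) of member intervals
        keys = [m[2] for m in members]
        prot_a, prot_b = keys[0][0][0], keys[0][1][0]
        int_a = _intersect_intervals([k[0][2] for k in keys])
        int_b = _intersect_intervals([k[1][2] for k in keys])
        site_a = int_a[0] + (int_a[1] - int_a[0]) // 2
        site_b = int_b[0] + (int_b[1] - int_b[0]) // 2
        hits = tuple(m[1] for m in members)
        link = ConsensusCrossLink(
            protein_a=prot_a,
            protein_b=prot_b,
            site_a=site_a,
            site_b=site_b,
            per_replicate=per_rep,
            score=score,
            condition=condition,
            supporting_hits=hits,
        )
        if link.link_type == INTRA:
            link.homomultimer_flag = flag_homomultimer(link, hits)
        links.append(link)
    links.sort(key=lambda l: (l.protein_a, l.protein_b, l.site_a, l.site_b))
    return links


def _intersect_intervals(intervals: list[tuple[int, int]]) -> tuple[int, int]:
    lo = max(i[0] for i in intervals)
    hi = min(i[1] for i in intervals)
    if lo > hi:  # disjoint after merging via chain overlaps; fall back to union
        lo = min(i[0] for i in intervals)
        hi = max(i[1] for i in intervals)
    return lo, hi


def flag_homomultimer(
    link: ConsensusCrossLink, supporting_hits: Sequence[CrossLinkHit]
) -> bool:
    """True when any supporting hit's peptides overlap in protein coordinates.

    Overlapping peptide sequences within one protein can only cross-link if
    two copies of the protein are present (closed-interval convention: a
    shared boundary residue counts as overlap).
    """
    if link.link_type != INTRA:
        warnings.warn("homo-multimer flag requested for inter-protein link", stacklevel=2)
        return False
    for hit in supporting_hits:
        a = (hit.peptide_a.start, hit.peptide_a.end)
        b = (hit.peptide_b.start, hit.peptide_b.end)
        if hit.peptide_a.protein_id == hit.peptide_b.protein_id and _intervals_overlap(a, b):
            return True
    return False


def build_network(
    accepted_links: Sequence[ConsensusCrossLink],
    detailed: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Edge table over conditions plus per-condition inter/intra tallies.

    Default granularity is one edge per unordered protein pair with the count
    of supporting residue pairs as multiplicity; ``detailed=True`` emits one
    edge per residue pair. Edges are independent of input ordering (canonical
    accession ordering within each edge).
    """
    conditions = sorted({l.condition for l in accepted_links})
    edges: dict[tuple, dict] = {}
    for link in accepted_links:
        pa, pb = sorted((link.protein_a, link.protein_b))
        if detailed:
            sa, sb = (link.site_a, link.site_b) if (pa, pb) == (link.protein_a, link.protein_b) \
                else (link.site_b, link.site_a)
            key = (pa, pb, sa, sb)
        else:
            key = (pa, pb)
        entry = edges.setdefault(
            key,
            {
                "source": pa,
                "target": pb,
                "link_type": link.link_type,
                "multiplicity": 0,
                "conditions": set(),
                "min_score": link.score,
            },
        )
        if detailed and "site_a" not in entry:
            entry["site_a"], entry["site_b"] = key[2], key[3]
        entry["multiplicity"] += 1
        entry["conditions"].add(link.condition)
        entry["min_score"] = min(entry["min_score"], link.score)
    rows = []
    for key in sorted(edges):
        e = dict(edges[key])
        e["conditions"] = ",".join(sorted(e["conditions"]))
        rows.append(e)
    edge_df = pd.DataFrame(rows)

    tally_rows = []
    for cond in conditions:
        in_cond = [l for l in accepted_links if l.condition == cond]
        n_inter = sum(l.link_type == INTER for l in in_cond)
        n_intra = sum(l.link_type == INTRA for l in in_cond)
        tally_rows.append(
            {"condition": cond, "inter_protein": n_inter, "intra_protein": n_intra,
             "total": n_inter + n_intra}
        )
    return edge_df, pd.DataFrame(tally_rows)
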