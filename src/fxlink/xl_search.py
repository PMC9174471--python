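"""Identification of formaldehyde cross-linked peptide pairs in MS2 spectra.

A precursor with charge 4+..7+ is matched against all peptide pairs whose
summed mass plus the 12 Da (one methylene bridge) or 24 Da (two bridges)
linker mass lies within the MS1 ppm tolerance. Candidates are scored by
counting theoretical a/b/y ions — unshifted and +12 Da shifted — matched by
observed peaks within the MS2 tolerance, classified into high/intermediate
confidence, and the cross-linking site is assigned to the middle of the
residue interval consistent with the shifted/unshifted fragment evidence.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .constants import DEFAULT_CONSTANTS, MassConstants, REACTIVE_RESIDUES
from .masscalc import Peptide, digest, fragment_neutral_masses, peptide_mass, ppm_delta

logger = logging.getLogger(__name__)

__all__ = [
    "SpectrumRecord",
    "SearchParams",
    "CrossLinkHit",
    "PeptideIndex",
    "build_search_database",
    "enumerate_candidates",
    "score_candidate",
    "classify_confidence",
    "assign_site",
    "decoy_report",
    "search_spectrum",
    "search_spectra",
    "hits_to_table",
]

DECOY_PREFIX = "REV_"

HIGH = "high"
INTERMEDIATE = "intermediate"
REJECTED = "rejected"


@dataclass
class SpectrumRecord:
    """One MS2 spectrum: precursor and peak list (sorted by m/z)."""

    spectrum_id: str
    precursor_mz: float
    precursor_charge: int
    peaks: np.ndarray  # (n, 2): m/z, intensity
    replicate_id: str = ""
    condition: str = ""

    def __post_init__(self) -> None:
        self.peaks = np.asarray(self.peaks, dtype=float).reshape(-1, 2)
        if self.peaks.size and np.any(np.diff(self.peaks[:, 0]) < 0):
            self.peaks = self.peaks[np.argsort(self.peaks[:, 0])]
        if self.peaks.size and np.any(self.peaks[:, 1] < 0):
            raise ValueError("negative peak intensity")

    def neutral_mass(self, constants: MassConstants = DEFAULT_CONSTANTS) -> float:
        z = self.precursor_charge
        return self.precursor_mz * z - z * constants.proton


@dataclass(frozen=True)
class SearchParams:
    """Search configuration; defaults match the Orbitrap acquisition setup."""

    ms1_tol_ppm: float = 6.0
    ms2_tol_ppm: float = 8.0
    max_missed: int = 4
    length_range: tuple[int, int] = (5, 60)
    charge_window: tuple[int, int] = (4, 7)
    series: tuple[str, ...] = ("a", "b", "y")
    include_shifted: bool = True
    ratio_threshold: float = 1.5
    high_floor: int = 18
    intermediate_floor: int = 15
    count_unit: str = "ion"  # "ion": (series,index,charge,shifted); "position": (series,index)


@dataclass
class CrossLinkHit:
    """A scored cross-linked peptide pair for one spectrum."""

    spectrum_id: str
    peptide_a: Peptide
    peptide_b: Peptide
    linker_count: int
    matched_fragments_a: int = 0
    matched_fragments_b: int = 0
    matched_ions_a: tuple = ()
    matched_ions_b: tuple = ()
    confidence: str = REJECTED
    site_a: int = 0
    site_b: int = 0
    interval_a: tuple[int, int] = (0, 0)
    interval_b: tuple[int, int] = (0, 0)
    site_note: str = ""
    replicate_id: str = ""
    condition: str = ""

    @property
    def ratio(self) -> float:
        return (self.matched_fragments_a + self.matched_fragments_b) / (
            len(self.peptide_a) + len(self.peptide_b)
        )

    @property
    def min_fragments(self) -> int:
        return min(self.matched_fragments_a, self.matched_fragments_b)

    @property
    def contains_decoy(self) -> bool:
        return self.peptide_a.is_decoy or self.peptide_b.is_decoy

    def site_in_protein(self, which: str) -> int:
        """Assigned site translated to 1-based parent-protein coordinates."""
        pep = self.peptide_a if which == "a" else self.peptide_b
        site = self.site_a if which == "a" else self.site_b
        return pep.start + site - 1

    def interval_in_protein(self, which: str) -> tuple[int, int]:
        pep = self.peptide_a if which == "a" else self.peptide_b
        lo, hi = self.interval_a if which == "a" else self.interval_b
        return (pep.start + lo - 1, pep.start + hi - 1)


def build_search_database(
    abundance_ranked_proteins: Sequence[tuple[str, str]],
    n_top: int = 800,
    decoy_prefix: str = DECOY_PREFIX,
) -> list[tuple[str, str, bool]]:
    """Restrict the search space to the most abundant proteins plus decoys.

    ``abundance_ranked_proteins`` must be ordered by decreasing mean iBAQ.
    Each retained target contributes one decoy: the full sequence reversed,
    accession prefixed so decoy hits are recognisable downstream.
    """
    if n_top <= 0:
        raise ValueError("n_top must be positive (empty database)")
    if len(abundance_ranked_proteins) < n_top:
        warnings.warn(
            f"only {len(abundance_ranked_proteins)} proteins available, "
            f"requested top {n_top}; using all",
            stacklevel=2,
        )
    targets = list(abundance_ranked_proteins[:n_top])
    db = [(acc, seq, False) for acc, seq in targets]
    db += [(decoy_prefix + acc, seq[::-1], True) for acc, seq in targets]
    return db


class PeptideIndex:
    """Mass-sorted digest of a target+decoy database with cached fragments."""

    def __init__(
        self,
        database: Sequence[tuple[str, str, bool]],
        params: SearchParams = SearchParams(),
        constants: MassConstants = DEFAULT_CONSTANTS,
    ) -> None:
        self.constants = constants
        self.params = params
        peptides: list[Peptide] = []
        for acc, seq, is_decoy in database:
            peptides.extend(
                digest(
                    seq,
                    max_missed=params.max_missed,
                    length_range=params.length_range,
                    protein_id=acc,
                    is_decoy=is_decoy,
                )
            )
        masses = np.array([peptide_mass(p, constants) for p in peptides])
        order = np.argsort(masses, kind="stable")
        self.peptides = [peptides[i] for i in order]
        self.masses = masses[order]
        self._neutral_cache: dict[str, dict[str, np.ndarray]] = {}
        self._ion_cache: dict[tuple[str, int], dict[str, np.ndarray]] = {}

    def __len__(self) -> int:
        return len(self.peptides)

    def fragment_neutrals(self, sequence: str) -> dict[str, np.ndarray]:
        cached = self._neutral_cache.get(sequence)
        if cached is None:
            cached = fragment_neutral_masses(sequence, self.constants)
            self._neutral_cache[sequence] = cached
        return cached

    def theoretical_ions(self, sequence: str, max_charge: int) -> dict[str, np.ndarray]:
        """Concatenated theoretical ion arrays for fast vectorised matching."""
        key = (sequence, max_charge)
        cached = self._ion_cache.get(key)
        if cached is not None:
            return cached
        constants = self.constants
        params = self.params
        neutrals = self.fragment_neutrals(sequence)
        shift_states = (False, True) if params.include_shifted else (False,)
        mz_parts, series_parts, idx_parts, z_parts, sh_parts = [], [], [], [], []
        for series in params.series:
            base = neutrals[series]
            n = base.size
            for z in range(1, max_charge + 1):
                for shifted in shift_states:
                    shift = constants.linker_single if shifted else 0.0
                    mz_parts.append((base + shift + z * constants.proton) / z)
                    series_parts.append(np.full(n, series, dtype="U1"))
                    idx_parts.append(np.arange(1, n + 1, dtype=np.int32))
                    z_parts.append(np.full(n, z, dtype=np.int32))
                    sh_parts.append(np.full(n, shifted, dtype=bool))
        cached = {
            "mz": np.concatenate(mz_parts),
            "series": np.concatenate(series_parts),
            "index": np.concatenate(idx_parts),
            "charge": np.concatenate(z_parts),
            "shifted": np.concatenate(sh_parts),
        }
        self._ion_cache[key] = cached
        return cached


def enumerate_candidates(
    spectrum: SpectrumRecord,
    index: PeptideIndex,
    ms1_tol_ppm: float = 6.0,
) -> list[tuple[Peptide, Peptide, int]]:
    """All unordered peptide pairs compatible with the precursor mass.

    A pair (a, b, linker_count) qualifies when
    |ppm(precursor neutral mass, mass_a + mass_b + linker_count x 12)| <= tol.
    """
    constants = index.constants
    m_obs = spectrum.neutral_mass(constants)
    masses = index.masses
    out: list[tuple[Peptide, Peptide, int]] = []
    if masses.size == 0:
        return out
    for linker_count, linker_mass in ((1, constants.linker_single), (2, constants.linker_double)):
        target = m_obs - linker_mass
        if target < 2 * masses[0]:
            continue
        pad = ms1_tol_ppm * 1e-6 * m_obs * 1.01  # slightly wide, exact recheck below
        lo = np.searchsorted(masses, (target - pad) - masses)
        hi = np.searchsorted(masses, (target + pad) - masses, side="right")
        j0 = np.maximum(lo, np.arange(masses.size))
        for i in np.nonzero((hi > j0) & (masses <= target / 2 + pad))[0]:
            for j in range(int(j0[i]), int(hi[i])):
                theo = masses[i] + masses[j] + linker_mass
                if abs(ppm_delta(m_obs, theo)) <= ms1_tol_ppm:
                    out.append((index.peptides[i], index.peptides[j], linker_count))
    return out


def _match_mask(theo_mz: np.ndarray, peaks_mz: np.ndarray, tol_ppm: float) -> np.ndarray:
    """For each theoretical m/z, is there an observed peak within tolerance?"""
    if peaks_mz.size == 0 or theo_mz.size == 0:
        return np.zeros(theo_mz.shape, dtype=bool)
    idx = np.searchsorted(peaks_mz, theo_mz)
    best = np.full(theo_mz.shape, np.inf)
    for off in (-1, 0):
        j = np.clip(idx + off, 0, peaks_mz.size - 1)
        best = np.minimum(best, np.abs(peaks_mz[j] - theo_mz))
    return best <= tol_ppm * 1e-6 * theo_mz


def _match_peptide(
    sequence: str,
    spectrum: SpectrumRecord,
    index: PeptideIndex,
    ms2_tol_ppm: float,
) -> list[tuple[str, int, int, bool]]:
    """Matched theoretical ions as (series, index, charge, shifted) tuples."""
    peaks_mz = spectrum.peaks[:, 0] if spectrum.peaks.size else np.empty(0)
    max_charge = max(1, spectrum.precursor_charge - 1)
    ions = index.theoretical_ions(sequence, max_charge)
    mask = _match_mask(ions["mz"], peaks_mz, ms2_tol_ppm)
    hit_idx = np.nonzero(mask)[0]
    return [
        (str(ions["series"][k]), int(ions["index"][k]),
         int(ions["charge"][k]), bool(ions["shifted"][k]))
        for k in hit_idx
    ]


def _count_fragments(matched: Iterable[tuple[str, int, int, bool]], unit: str) -> int:
    if unit == "ion":
        return len(set(matched))
    if unit == "position":
        return len({(s, i) for s, i, _, _ in matched})
    raise ValueError(f"unknown counting unit {unit!r}")


def _canonical_pair(pep_a: Peptide, pep_b: Peptide) -> tuple[Peptide, Peptide, bool]:
    key = lambda p: (p.protein_id, p.start, p.sequence)
    if key(pep_a) <= key(pep_b):
        return pep_a, pep_b, False
    return pep_b, pep_a, True


def score_candidate(
    spectrum: SpectrumRecord,
    candidate: tuple[Peptide, Peptide, int],
    index: PeptideIndex,
    ms2_tol_ppm: float = 8.0,
) -> CrossLinkHit:
    """Fill the matched-fragment tallies for one candidate pair.

    Counts distinct matched theoretical ions per peptide over the requested
    series, both shift states, and fragment charges 1..precursor_charge-1.
    Confidence is left unset (``rejected``) until classification.
    """
    pep_a, pep_b, linker_count = candidate
    pep_a, pep_b, _ = _canonical_pair(pep_a, pep_b)
    matched_a = _match_peptide(pep_a.sequence, spectrum, index, ms2_tol_ppm)
    matched_b = _match_peptide(pep_b.sequence, spectrum, index, ms2_tol_ppm)
    unit = index.params.count_unit
    return CrossLinkHit(
        spectrum_id=spectrum.spectrum_id,
        peptide_a=pep_a,
        peptide_b=pep_b,
        linker_count=linker_count,
        matched_fragments_a=_count_fragments(matched_a, unit),
        matched_fragments_b=_count_fragments(matched_b, unit),
        matched_ions_a=tuple(matched_a),
        matched_ions_b=tuple(matched_b),
        replicate_id=spectrum.replicate_id,
        condition=spectrum.condition,
    )


def classify_confidence(
    hit: CrossLinkHit, params: SearchParams = SearchParams()
) -> str:
    """High/intermediate/rejected per the confidence thresholds.

    High: fragment/residue ratio > 1.5 and both peptides' matched-fragment
    counts > 18. Intermediate: both counts > 15. Otherwise rejected.
    """
    if hit.ratio > params.ratio_threshold and hit.min_fragments > params.high_floor:
        return HIGH
    if hit.min_fragments > params.intermediate_floor:
        return INTERMEDIATE
    return REJECTED


def _site_interval(
    matched: Iterable[tuple[str, int, int, bool]], length: int
) -> tuple[int, int]:
    """Residue interval most consistent with the shifted/unshifted evidence.

    A shifted y_i contains the linker remnant, so the site lies in the
    C-terminal i residues; a shifted b_i/a_i bounds it to the N-terminal i
    residues; an unshifted ion excludes the site from its span — but only when
    its shifted twin was not also observed (then it carries no placement
    information). Because isolated coincidental peak matches can contradict
    the true placement, the constraints vote: each distinct (series, index,
    shift-state) piece of evidence supports the positions consistent with it,
    and the returned interval spans the positions of maximal support. With no
    evidence at all this is the whole peptide.
    """
    shifted_positions = {(s, i) for s, i, _, sh in matched if sh}
    constraints: set[tuple[str, int, bool]] = set()
    for series, i, _z, shifted in matched:
        if shifted or (series, i) not in shifted_positions:
            constraints.add((series, i, shifted))
    votes = np.zeros(length, dtype=int)
    for series, i, shifted in constraints:
        if series == "y":
            span = slice(length - i, length) if shifted else slice(0, length - i)
        else:  # a or b
            span = slice(0, i) if shifted else slice(i, length)
        votes[span] += 1
    best = votes.max()
    winners = np.nonzero(votes == best)[0]
    return int(winners[0]) + 1, int(winners[-1]) + 1


def _interval_middle(lo: int, hi: int) -> int:
    # even-width intervals break the tie toward the N-terminus
    return lo + (hi - lo) // 2


def assign_site(hit: CrossLinkHit) -> CrossLinkHit:
    """Assign cross-linking sites (middle-residue convention) with intervals.

    The default site is the middle residue of the peptide; shifted/unshifted
    fragment evidence narrows the interval and the site moves to the middle
    of the narrowed interval. A note records reactive residues (K/R first)
    present in the interval — annotation only, never affects scoring.
    """
    notes = []
    sites, intervals = [], []
    for pep, matched in (
        (hit.peptide_a, hit.matched_ions_a),
        (hit.peptide_b, hit.matched_ions_b),
    ):
        lo, hi = _site_interval(matched, len(pep))
        site = _interval_middle(lo, hi)
        sites.append(site)
        intervals.append((lo, hi))
        span = pep.sequence[lo - 1 : hi]
        for res in REACTIVE_RESIDUES:
            if res in span:
                notes.append(f"{pep.protein_id}:{res} in interval [{lo},{hi}]")
                break
    hit.site_a, hit.site_b = sites
    hit.interval_a, hit.interval_b = intervals
    hit.site_note = "; ".join(notes)
    return hit


def search_spectrum(
    spectrum: SpectrumRecord,
    index: PeptideIndex,
    params: SearchParams | None = None,
) -> CrossLinkHit | None:
    """Best classified hit for one spectrum, or None.

    Spectra with precursor charge outside the configured window are skipped
    (logged, not an error). Ties between candidates are broken by higher
    ratio, then higher minimum fragment count, then lexicographic accession.
    """
    params = params or index.params
    zmin, zmax = params.charge_window
    if not (zmin <= spectrum.precursor_charge <= zmax):
        logger.info(
            "spectrum %s skipped: charge %d outside window %s",
            spectrum.spectrum_id, spectrum.precursor_charge, params.charge_window,
        )
        return None
    candidates = enumerate_candidates(spectrum, index, params.ms1_tol_ppm)
    if not candidates:
        return None
    best: CrossLinkHit | None = None
    best_key: tuple | None = None
    for cand in candidates:
        hit = score_candidate(spectrum, cand, index, params.ms2_tol_ppm)
        key = (
            hit.ratio,
            hit.min_fragments,
            # prefer lexicographically smaller accessions on exact ties
            tuple(-ord(c) for c in hit.peptide_a.protein_id + "\x00" + hit.peptide_b.protein_id),
        )
        if best_key is None or key > best_key:
            best, best_key = hit, key
    assert best is not None
    best.confidence = classify_confidence(best, params)
    if best.confidence != REJECTED:
        assign_site(best)
    else:
        # middle-residue fallback keeps the record self-describing
        best.site_a = _interval_middle(1, len(best.peptide_a))
        best.site_b = _interval_middle(1, len(best.peptide_b))
        best.interval_a = (1, len(best.peptide_a))
        best.interval_b = (1, len(best.peptide_b))
    return best


def search_spectra(
    spectra: Iterable[SpectrumRecord],
    index: PeptideIndex,
    params: SearchParams | None = None,
) -> list[CrossLinkHit]:
    """Search a batch of spectra; one best hit per spectrum where one exists."""
    hits = []
    for spectrum in spectra:
        hit = search_spectrum(spectrum, index, params)
        if hit is not None:
            hits.append(hit)
    return hits


def decoy_report(hits: Sequence[CrossLinkHit]) -> pd.DataFrame:
    """Count and fraction of decoy-containing hits among accepted hits.

    Accepted means classified at least intermediate. Reported per condition
    plus an overall row.
    """
    accepted = [h for h in hits if h.confidence in (HIGH, INTERMEDIATE)]
    rows = []
    conditions = sorted({h.condition for h in accepted})
    groups = [(c, [h for h in accepted if h.condition == c]) for c in conditions]
    groups.append(("all", accepted))
    for label, group in groups:
        n_dec = sum(h.contains_decoy for h in group)
        rows.append(
            {
                "condition": label,
                "n_accepted": len(group),
                "n_decoy": n_dec,
                "decoy_fraction": n_dec / len(group) if group else 0.0,
            }
        )
    return pd.DataFrame(rows)


def hits_to_table(hits: Sequence[CrossLinkHit]) -> pd.DataFrame:
    """One row per hit, import-ready TSV layout (protein coordinates)."""
    rows = []
    for h in hits:
        ia = h.interval_in_protein("a")
        ib = h.interval_in_protein("b")
        rows.append(
            {
                "spectrum_id": h.spectrum_id,
                "condition": h.condition,
                "replicate_id": h.replicate_id,
                "protein_a": h.peptide_a.protein_id,
                "protein_b": h.peptide_b.protein_id,
                "peptide_a": h.peptide_a.sequence,
                "peptide_b": h.peptide_b.sequence,
                "start_a": h.peptide_a.start,
                "start_b": h.peptide_b.start,
                "decoy_a": h.peptide_a.is_decoy,
                "decoy_b": h.peptide_b.is_decoy,
                "linker_count": h.linker_count,
                "matched_a": h.matched_fragments_a,
                "matched_b": h.matched_fragments_b,
                "ratio": round(h.ratio, 4),
                "confidence": h.confidence,
                "site_a_protein": h.site_in_protein("a"),
                "site_b_protein": h.site_in_protein("b"),
                "interval_a_lo": ia[0],
                "interval_a_hi": ia[1],
                "interval_b_lo": ib[0],
                "interval_b_hi": ib[1],
                "contains_decoy": h.contains_decoy,
            }
        )
    return pd.DataFrame(rows)


def hits_from_table(df: pd.DataFrame) -> list[CrossLinkHit]:
    """Rebuild hits from a TSV written by ``hits_to_table``.

    Matched-ion annotations are not round-tripped; counts, confidence, sites
    and intervals are — which is all consensus building needs.
    """
    hits = []
    for row in df.itertuples(index=False):
        pep_a = Peptide(row.peptide_a, row.protein_a, int(row.start_a),
                        missed_cleavages=0, is_decoy=bool(row.decoy_a))
        pep_b = Peptide(row.peptide_b, row.protein_b, int(row.start_b),
                        missed_cleavages=0, is_decoy=bool(row.decoy_b))
        hit = CrossLinkHit(
            spectrum_id=row.spectrum_id,
            peptide_a=pep_a,
            peptide_b=pep_b,
            linker_count=int(row.linker_count),
            matched_fragments_a=int(row.matched_a),
            matched_fragments_b=int(row.matched_b),
            confidence=row.confidence,
            site_a=int(row.site_a_protein) - pep_a.start + 1,
            site_b=int(row.site_b_protein) - pep_b.start + 1,
            interval_a=(int(row.interval_a_lo) - pep_a.start + 1,
                        int(row.interval_a_hi) - pep_a.start + 1),
            interval_b=(int(row.interval_b_lo) - pep_b.start + 1,
                        int(row.interval_b_hi) - pep_b.start + 1),
            replicate_id=str(row.replicate_id),
            condition=str(row.condition),
        )
        hits.append(hit)
    return hits
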