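"""Cross-link search: database, candidate enumeration, scoring, sites, decoys."""

import numpy as np
import pytest

from fxlink.constants import DEFAULT_CONSTANTS
from fxlink import masscalc as mc
from fxlink import xl_search as xs

PROTON = DEFAULT_CONSTANTS.proton


def make_spectrum(peaks_mz, precursor_mz, charge=4, spectrum_id="s1", intensity=100.0):
    peaks = np.column_stack([np.sort(np.asarray(peaks_mz, dtype=float)),
                             np.full(len(peaks_mz), intensity)])
    return xs.SpectrumRecord(spectrum_id, precursor_mz, charge, peaks)


def pair_precursor_mz(seq_a, seq_b, charge, linker_count=1):
    m = mc.peptide_mass(seq_a) + mc.peptide_mass(seq_b) + 12.0 * linker_count
    return (m + charge * PROTON) / charge


@pytest.fixture()
def small_index():
    proteins = [
        ("P1", "ELVISLIVESKGRAVEYARDTIMEK"),
        ("P2", "MTWICELEGANTKFERTILESAILSTHEREK"),
    ]
    db = xs.build_search_database(proteins, n_top=2)
    return xs.PeptideIndex(db, xs.SearchParams(length_range=(5, 30)))


class TestSearchDatabase:
    def test_targets_plus_decoys(self):
        proteins = [(f"P{i}", "ACDEFGHIKLMNPQR") for i in range(10)]
        db = xs.build_search_database(proteins, n_top=8)
        assert len(db) == 16
        assert sum(is_decoy for _, _, is_decoy in db) == 8

    def test_decoy_is_full_reversal(self):
        db = xs.build_search_database([("P1", "MKRAG")], n_top=1)
        decoys = [(acc, seq) for acc, seq, d in db if d]
        assert decoys == [("REV_P1", "GARKM")]

    def test_empty_database_rejected(self):
        with pytest.raises(ValueError):
            xs.build_search_database([("P1", "MKRAG")], n_top=0)

    def test_fewer_proteins_than_requested_warns(self):
        with pytest.warns(UserWarning, match="using all"):
            db = xs.build_search_database([("P1", "MKRAG")], n_top=800)
        assert len(db) == 2


class TestEnumerateCandidates:
    def test_exact_mass_pair_found(self, small_index):
        peps = small_index.peptides
        pep_a, pep_b = peps[0], peps[3]
        mz = (small_index.masses[0] + small_index.masses[3] + 12.0 + 4 * PROTON) / 4
        spec = make_spectrum([300.0], mz, charge=4)
        cands = xs.enumerate_candidates(spec, small_index)
        pairs = {
            frozenset([(a.protein_id, a.start), (b.protein_id, b.start)])
            for a, b, lc in cands if lc == 1
        }
        assert frozenset([(pep_a.protein_id, pep_a.start),
                          (pep_b.protein_id, pep_b.start)]) in pairs

    def test_seven_ppm_off_is_excluded(self, small_index):
        m = small_index.masses[0] + small_index.masses[3] + 24.0
        mz = (m * (1 + 7e-6) + 4 * PROTON) / 4
        spec = make_spectrum([300.0], mz, charge=4)
        cands = [c for c in xs.enumerate_candidates(spec, small_index) if c[2] == 2]
        masses = {
            round(mc.peptide_mass(a) + mc.peptide_mass(b), 6) for a, b, _ in cands
        }
        assert round(small_index.masses[0] + small_index.masses[3], 6) not in masses

    def test_against_brute_force_pair_oracle(self, rng):
        """Every O(n^2) pair within tolerance is enumerated, nothing else."""
        letters = np.array(list("ACDEFGHIKLMNPQRSTVW"))
        proteins = [
            (f"P{i}", "".join(rng.choice(letters, size=60)) + "K") for i in range(6)
        ]
        index = xs.PeptideIndex(
            [(a, s, False) for a, s in proteins], xs.SearchParams(length_range=(4, 40))
        )
        masses = [mc.peptide_mass(p) for p in index.peptides]
        i, j = 3, min(11, len(masses) - 1)
        m_obs = masses[i] + masses[j] + 12.0
        spec = make_spectrum([300.0], (m_obs + 5 * PROTON) / 5, charge=5)
        got = {
            (id(a), id(b), lc) if id(a) <= id(b) else (id(b), id(a), lc)
            for a, b, lc in xs.enumerate_candidates(spec, index)
        }
        expected = set()
        for a in range(len(masses)):
            for b in range(a, len(masses)):
                for lc, lm in ((1, 12.0), (2, 24.0)):
                    theo = masses[a] + masses[b] + lm
                    if abs(1e6 * (m_obs - theo) / theo) <= 6.0:
                        pa, pb = index.peptides[a], index.peptides[b]
                        key = (id(pa), id(pb), lc) if id(pa) <= id(pb) else (id(pb), id(pa), lc)
                        expected.add(key)
        assert got == expected

    def test_unordered_pair_symmetry(self, small_index):
        mz = (small_index.masses[0] + small_index.masses[3] + 12.0 + 4 * PROTON) / 4
        spec = make_spectrum([300.0], mz, charge=4)
        cands = xs.enumerate_candidates(spec, small_index)
        keys = [
            frozenset([(a.protein_id, a.start), (b.protein_id, b.start)])
            for a, b, _ in cands
        ]
        assert len(keys) == len(set(keys))  # no (A,B)/(B,A) duplicates


class TestScoring:
    def test_full_y_ladder_matches_at_least_n_minus_1(self, small_index):
        pep = next(p for p in small_index.peptides if len(p.sequence) == 13)
        other = small_index.peptides[0]
        ladder = [i.mz for i in mc.fragment_ions(pep.sequence, series=("y",),
                                                 charges=(1,), include_shifted=False)]
        spec = make_spectrum(ladder, pair_precursor_mz(pep.sequence, other.sequence, 4))
        hit = xs.score_candidate(spec, (pep, other, 1), small_index)
        matched = hit.matched_fragments_a if hit.peptide_a.sequence == pep.sequence \
            else hit.matched_fragments_b
        assert matched >= 12

    def test_pure_noise_matches_nothing(self, small_index):
        pep_a, pep_b = small_index.peptides[0], small_index.peptides[3]
        noise = [
            i.mz * (1 + 50e-6)
            for i in mc.fragment_ions(pep_a.sequence, charges=(1, 2, 3))
        ]
        spec = make_spectrum(noise, pair_precursor_mz(pep_a.sequence, pep_b.sequence, 4))
        hit = xs.score_candidate(spec, (pep_a, pep_b, 1), small_index)
        assert hit.matched_fragments_a == 0 and hit.matched_fragments_b == 0

    def test_planted_coverage_counts_match_generator_truth(self):
        from fxlink.synthetic import gen_proteome, gen_xl_spectra

        proteome, _ = gen_proteome(6, 200, seed=7)
        spectra_by_rep, truth = gen_xl_spectra(
            proteome, n_links=3, coverage=0.7, noise_peaks=0,
            ppm_sigma=1.0, n_replicates=1, seed=7,
        )
        db = xs.build_search_database(proteome, n_top=len(proteome))
        index = xs.PeptideIndex(db, xs.SearchParams())
        for spec in spectra_by_rep["rep1"]:
            info = truth["spectra"][spec.spectrum_id]
            link = truth["links"][info["link_index"]]
            pep_a = mc.Peptide(link["peptide_a"], link["protein_a"], link["start_a"])
            pep_b = mc.Peptide(link["peptide_b"], link["protein_b"], link["start_b"])
            hit = xs.score_candidate(spec, (pep_a, pep_b, link["linker_count"]), index)
            emitted = {
                (link["protein_a"], link["start_a"]): info["emitted_a"],
                (link["protein_b"], link["start_b"]): info["emitted_b"],
            }
            # every emitted ion is matched; rare m/z coincidences may add more
            assert hit.matched_fragments_a >= emitted[
                (hit.peptide_a.protein_id, hit.peptide_a.start)]
            assert hit.matched_fragments_b >= emitted[
                (hit.peptide_b.protein_id, hit.peptide_b.start)]
            assert hit.matched_fragments_a + hit.matched_fragments_b <= \
                info["emitted_a"] + info["emitted_b"] + 4


class TestConfidence:
    def _hit(self, matched_a, matched_b, len_a=13, len_b=13):
        pep_a = mc.Peptide("A" * len_a, "P1", 1)
        pep_b = mc.Peptide("G" * len_b, "P2", 1)
        return xs.CrossLinkHit("s", pep_a, pep_b, 1,
                               matched_fragments_a=matched_a,
                               matched_fragments_b=matched_b)

    @pytest.mark.parametrize(
        "matched_a,matched_b,expected",
        [
            (20, 20, "high"),          # ratio 40/26 > 1.5, min 20 > 18
            (16, 16, "intermediate"),  # ratio 1.23 <= 1.5 but min 16 > 15
            (10, 40, "rejected"),      # min 10 below both floors
            (19, 19, "intermediate"),  # min 19 > 18 but ratio 38/26 not > 1.5
            (21, 20, "high"),          # ratio 41/26 > 1.5 and min 20 > 18
            (18, 40, "intermediate"),  # 18 is not > 18
            (16, 15, "rejected"),      # 15 is not > 15
        ],
    )
    def test_rule(self, matched_a, matched_b, expected):
        assert xs.classify_confidence(self._hit(matched_a, matched_b)) == expected

    def test_swap_symmetry(self):
        for a, b in [(20, 19), (16, 40), (3, 50)]:
            assert xs.classify_confidence(self._hit(a, b)) == \
                xs.classify_confidence(self._hit(b, a))

    def test_monotone_in_matched_counts(self):
        order = {"rejected": 0, "intermediate": 1, "high": 2}
        for a in range(0, 30, 3):
            for b in range(0, 30, 3):
                base = order[xs.classify_confidence(self._hit(a, b))]
                more = order[xs.classify_confidence(self._hit(a + 1, b))]
                assert more >= base


class TestSiteAssignment:
    def _hit_with_ions(self, length, ions):
        pep = mc.Peptide("A" * length, "P1", 1)
        other = mc.Peptide("G" * 10, "P2", 1)
        hit = xs.CrossLinkHit("s", pep, other, 1, matched_ions_a=tuple(ions))
        return xs.assign_site(hit)

    def test_no_evidence_middle_residue_13mer(self):
        hit = self._hit_with_ions(13, [])
        assert hit.site_a == 7 and hit.interval_a == (1, 13)

    def test_no_evidence_even_length_ties_to_n_terminal(self):
        hit = self._hit_with_ions(12, [])
        assert hit.site_a == 6

    def test_shifted_y9_and_unshifted_y8_pin_site_5(self):
        ions = [("y", 9, 1, True), ("y", 8, 1, False)]
        hit = self._hit_with_ions(13, ions)
        assert hit.interval_a == (5, 5) and hit.site_a == 5

    def test_shifted_twin_neutralises_unshifted_evidence(self):
        # y9 seen both shifted and unshifted: only the shifted ion informs
        ions = [("y", 9, 1, True), ("y", 9, 1, False)]
        hit = self._hit_with_ions(13, ions)
        assert hit.interval_a == (5, 13)


class TestSearchAndDecoys:
    def test_charge_outside_window_skipped(self, small_index):
        spec = make_spectrum([300.0], 500.0, charge=2)
        assert xs.search_spectrum(spec, small_index) is None

    def test_decoy_report_arithmetic(self):
        pep = mc.Peptide("AAAAA", "P1", 1)
        dec = mc.Peptide("GGGGG", "REV_P2", 1, is_decoy=True)
        hits = [
            xs.CrossLinkHit("s%d" % i, pep, pep, 1, confidence="high")
            for i in range(204)
        ]
        hits.append(xs.CrossLinkHit("sd", pep, dec, 1, confidence="intermediate"))
        report = xs.decoy_report(hits)
        row = report[report["condition"] == "all"].iloc[0]
        assert row["n_accepted"] == 205 and row["n_decoy"] == 1
        assert row["decoy_fraction"] == pytest.approx(1 / 205)

    def test_accepted_hits_satisfy_ms1_constraint(self, xl_benchmark):
        """Post-hoc re-check of the precursor mass constraint on every hit."""
        for hits in xl_benchmark["hits_by_rep"].values():
            for hit in hits:
                if hit.confidence == "rejected":
                    continue
                # re-derive neutral mass from the originating spectrum id
                truth = xl_benchmark["truth"]["spectra"][hit.spectrum_id]
                theo = (mc.peptide_mass(hit.peptide_a) + mc.peptide_mass(hit.peptide_b)
                        + 12.0 * hit.linker_count)
                link = xl_benchmark["truth"]["links"][truth["link_index"]]
                m_true = (mc.peptide_mass(link["peptide_a"])
                          + mc.peptide_mass(link["peptide_b"])
                          + 12.0 * link["linker_count"])
                # observed precursor lies within 6 ppm of both
                assert abs(1e6 * (m_true - theo) / theo) <= 12.0


class TestRecoveryBenchmark:
    def test_planted_links_recovered_at_high_confidence(self, xl_benchmark):
        n_high = sum(
            h.confidence == "high"
            for hits in xl_benchmark["hits_by_rep"].values() for h in hits
        )
        n_spectra = sum(len(h) for h in xl_benchmark["hits_by_rep"].values())
        assert n_high / n_spectra >= 0.95
        assert xl_benchmark["recovery"] >= 0.95

    def test_no_decoy_containing_hit_accepted(self, xl_benchmark):
        for hits in xl_benchmark["hits_by_rep"].values():
            for hit in hits:
                if hit.confidence != "rejected":
                    assert not hit.contains_decoy

    def test_low_coverage_collapses_recovery(self, xl_benchmark_low_coverage):
        assert xl_benchmark_low_coverage["recovery"] < 0.20
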