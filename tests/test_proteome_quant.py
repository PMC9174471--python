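"""iBAQ, localisation sums, normalisation, differential abundance, ORA."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from fxlink import proteome_quant as pq
from fxlink.synthetic import gen_abundance


def make_design(conditions, replicates):
    samples, conds = [], []
    for c in conditions:
        for r in range(1, replicates + 1):
            samples.append(f"{c}_{r}")
            conds.append(c)
    return pd.DataFrame({"condition": conds, "replicate": 1},
                        index=pd.Index(samples, name="sample_id"))


class TestIbaq:
    def test_equalising_case(self):
        intensity = pd.DataFrame({"s1": [100.0, 300.0]}, index=["P1", "P2"])
        ibaq = pq.compute_ibaq(intensity, {"P1": 1, "P2": 3})
        assert (ibaq["s1"] == 100.0).all()
        rel = pq.relative_ibaq(ibaq)
        assert rel["s1"].tolist() == [0.5, 0.5]

    def test_single_protein_relative_is_one(self):
        ibaq = pd.DataFrame({"s1": [42.0]}, index=["P1"])
        assert pq.relative_ibaq(ibaq)["s1"].iloc[0] == 1.0

    def test_random_table_columns_sum_to_one(self, rng):
        ibaq = pd.DataFrame(rng.lognormal(size=(50, 4)))
        sums = pq.relative_ibaq(ibaq).sum(axis=0)
        assert np.allclose(sums, 1.0, atol=1e-12)

    def test_zero_count_protein_excluded_with_warning(self):
        intensity = pd.DataFrame({"s1": [100.0, 300.0]}, index=["P1", "P2"])
        with pytest.warns(UserWarning):
            ibaq = pq.compute_ibaq(intensity, {"P1": 1, "P2": 0})
        assert list(ibaq.index) == ["P1"]

    def test_peptide_count_uses_ibaq_digestion_convention(self):
        # 0 missed cleavages, lengths 7..30
        assert pq.theoretical_peptide_count("AAAAAAK" + "GGGGGGR" + "CCC") == 2


class TestLocalisation:
    def test_full_map_partitions_unity(self, rng):
        rel = pq.relative_ibaq(pd.DataFrame(
            rng.lognormal(size=(30, 6)),
            index=[f"P{i}" for i in range(30)],
            columns=make_design(["undiff", "RA"], 3).index,
        ))
        loc = {f"P{i}": pq.COMPARTMENTS[i % 9] for i in range(30)}
        sums, _, _ = pq.localisation_abundance(rel, loc, make_design(["undiff", "RA"], 3))
        assert np.allclose(sums.sum(axis=0), 1.0, atol=1e-12)

    def test_identical_replicates_give_p_one(self):
        design = make_design(["undiff", "RA"], 3)
        rel = pd.DataFrame([[0.5] * 6, [0.5] * 6], index=["P1", "P2"],
                           columns=design.index)
        _, _, tests = pq.localisation_abundance(
            rel, {"P1": "ER", "P2": "cytosol"}, design)
        assert (tests["adj_p"] == 1.0).all()

    def test_planted_er_shift_detected_after_bonferroni(self, rng):
        design = make_design(["undiff", "RA"], 6)
        base = np.full(12, 0.30)
        base[6:] += 0.05  # ER fraction raised in RA
        er = base + rng.normal(0, 0.005, 12)
        rest = 1.0 - er
        rel = pd.DataFrame([er, rest], index=["P1", "P2"], columns=design.index)
        _, _, tests = pq.localisation_abundance(
            rel, {"P1": "ER", "P2": "cytosol"}, design)
        er_p = tests.loc[tests.compartment == "ER", "adj_p"].iloc[0]
        assert er_p < 0.01

    def test_bonferroni_family_is_tests_actually_run(self):
        design = make_design(["undiff", "RA", "RA_PMA"], 3)
        rel = pd.DataFrame([np.linspace(0.4, 0.6, 9), np.linspace(0.6, 0.4, 9)],
                           index=["P1", "P2"], columns=design.index)
        _, _, tests = pq.localisation_abundance(
            rel, {"P1": "ER", "P2": "cytosol"}, design)
        # 2 compartments x 3 condition pairs
        assert len(tests) == 6
        assert np.allclose(tests["adj_p"], np.minimum(tests["p"] * 6, 1.0))


class TestEqualiseMedians:
    def test_two_sample_shift(self):
        table = pd.DataFrame({
            "s1": 2.0 ** np.array([19.0, 20.0, 21.0]),
            "s2": 2.0 ** np.array([21.0, 22.0, 23.0]),
        })
        out = pq.equalise_medians(table)
        assert out["s1"].median() == pytest.approx(21.0)
        assert out["s2"].median() == pytest.approx(21.0)
        assert (out["s1"] - np.log2(table["s1"])).iloc[0] == pytest.approx(1.0)

    def test_identity_when_already_equal(self, rng):
        vals = rng.lognormal(mean=10, size=(21, 1))
        table = pd.DataFrame(np.hstack([vals, vals]), columns=["s1", "s2"])
        out = pq.equalise_medians(table)
        assert np.allclose(out.to_numpy(), np.log2(table.to_numpy()))

    def test_idempotent(self, rng):
        table = pd.DataFrame(rng.lognormal(mean=8, sigma=2, size=(40, 5)))
        once = pq.equalise_medians(table)
        twice = pq.equalise_medians(2.0 ** once)
        assert np.allclose(once.to_numpy(), twice.to_numpy(), atol=1e-12)

    def test_all_missing_sample_errors(self):
        table = pd.DataFrame({"s1": [1.0, 2.0], "s2": [np.nan, np.nan]})
        with pytest.raises(ValueError, match="s2"):
            pq.equalise_medians(table)


class TestDifferentialAbundance:
    def _table(self, rng, n=40):
        design = make_design(["undiff", "RA"], 6)
        data = rng.normal(20, 1, size=(n, 12))
        return pd.DataFrame(data, index=[f"P{i}" for i in range(n)],
                            columns=design.index), design

    def test_identical_groups_unchanged(self):
        design = make_design(["undiff", "RA"], 3)
        table = pd.DataFrame([[20.0] * 3 + [20.0] * 3], index=["P1"],
                             columns=design.index)
        res = pq.differential_abundance(table, design, "RA", "undiff")
        assert res.loc["P1", "log2fc"] == 0.0
        assert res.loc["P1", "call"] == "unchanged"

    def test_log2fc_antisymmetry(self, rng):
        table, design = self._table(rng)
        ab = pq.differential_abundance(table, design, "RA", "undiff")
        ba = pq.differential_abundance(table, design, "undiff", "RA")
        assert np.allclose(ab["log2fc"], -ba["log2fc"])
        assert np.allclose(ab["p"], ba["p"])

    def test_bh_adjustment_matches_step_up_oracle(self, rng):
        """Independent BH step-up reimplementation on the result's raw p."""
        table, design = self._table(rng)
        res = pq.differential_abundance(table, design, "RA", "undiff")
        p = res["p"].to_numpy()
        m = len(p)
        order = np.argsort(p)
        stepped = p[order] * m / np.arange(1, m + 1)
        adj = np.minimum.accumulate(stepped[::-1])[::-1]
        expected = np.empty(m)
        expected[order] = np.minimum(adj, 1.0)
        assert np.allclose(res["adj_p"].to_numpy(), expected)
        assert (res["adj_p"] >= res["p"] - 1e-15).all()

    def test_bh_hand_example(self):
        from statsmodels.stats.multitest import multipletests
        adj = multipletests([0.01, 0.02, 0.03, 0.04], method="fdr_bh")[1]
        assert np.allclose(adj, 0.04)

    def test_min_obs_routing(self):
        design = make_design(["undiff", "RA"], 3)
        table = pd.DataFrame(
            [[20.0, 21.0, np.nan, np.nan, np.nan, np.nan]],
            index=["P1"], columns=design.index)
        res = pq.differential_abundance(table, design, "RA", "undiff")
        assert "P1" not in res.index
        pa = pq.presence_absence(table, design, "undiff", "RA")
        assert pa["undiff"] == ["P1"]


class TestPresenceAbsence:
    def test_floor_rule(self):
        design = make_design(["undiff", "RA"], 6)
        data = np.full((2, 12), np.nan)
        data[0, 6:] = 20.0           # P0: RA-specific 6/6 vs 0/6
        data[1, 6] = 20.0            # P1: only one observation
        table = pd.DataFrame(data, index=["P0", "P1"], columns=design.index)
        pa = pq.presence_absence(table, design, "RA", "undiff", min_obs=2)
        assert pa["RA"] == ["P0"]
        assert pa["undiff"] == []


class TestOraFisher:
    def test_list_equals_background_no_signal(self):
        genes = [f"g{i}" for i in range(10)]
        res = pq.ora_fisher(genes, genes, {"set1": set(genes[:5])})
        assert res["p"].iloc[0] == pytest.approx(1.0)

    def test_disjoint_set_p_one(self):
        res = pq.ora_fisher(["g1"], ["g1", "g2"], {"set1": {"g2"}})
        assert res["p"].iloc[0] == pytest.approx(1.0)

    def test_perfect_enrichment_matches_hypergeometric_oracle(self):
        background = [f"g{i}" for i in range(1000)]
        hits = background[:10]
        res = pq.ora_fisher(hits, background, {"set1": set(hits)})
        expected = stats.hypergeom.sf(9, 1000, 10, 10)
        assert res["p"].iloc[0] == pytest.approx(expected, rel=1e-9)

    def test_list_outside_background_rejected(self):
        with pytest.raises(ValueError):
            pq.ora_fisher(["zzz"], ["g1"], {"s": {"g1"}})


class TestPlantedRecovery:
    def test_volcano_sensitivity_and_fdp(self):
        table, truth = gen_abundance(seed=1)
        res = pq.differential_abundance(
            pq.equalise_medians(table.intensity), table.design, "RA", "undiff")
        planted = set(truth["planted"])
        called = set(res.index[res["call"] != "unchanged"])
        assert len(called & planted) / len(planted) >= 0.9
        assert len(called - planted) / max(len(called), 1) <= 0.1

    def test_planted_effect_estimates_unbiased(self):
        """Mean absolute log2FC error under the stated design, multi-seed."""
        maes = []
        for seed in range(5):
            table, truth = gen_abundance(seed=seed, missing_rate=0.0)
            res = pq.differential_abundance(
                pq.equalise_medians(table.intensity), table.design, "RA", "undiff")
            maes.append(np.mean([
                abs(res.loc[p, "log2fc"] - truth["planted"][p])
                for p in truth["planted"]
            ]))
        assert np.mean(maes) < 0.15

    def test_sign_of_planted_effects_recovered(self):
        table, truth = gen_abundance(seed=2)
        res = pq.differential_abundance(
            pq.equalise_medians(table.intensity), table.design, "RA", "undiff")
        for prot, effect in truth["planted"].items():
            if prot in res.index:
                assert np.sign(res.loc[prot, "log2fc"]) == np.sign(effect)
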