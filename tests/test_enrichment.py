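"""Ranked lists, running-sum enrichment, permutation GSEA, hurdle DE."""

import numpy as np
import pandas as pd
import pytest

from gliaxis.enrichment import (
    enrichment_score,
    hurdle_de,
    preranked_gsea,
    rank_genes,
)

from _oracles import brute_force_enrichment_score


def ranked_series(stats, genes=None):
    genes = genes or [f"g{i}" for i in range(len(stats))]
    s = pd.Series(np.asarray(stats, dtype=float), index=genes)
    order = np.argsort(-s.to_numpy(), kind="stable")
    return s.iloc[order]


class TestRankGenes:
    def test_fourfold_change_gives_log2fc_two(self, matrix_factory):
        # large counts so the 1-CPM pseudocount is negligible; equal library
        # sizes so the ratio reflects the 4x change in gene 0 alone
        x = np.full((4, 6), 1000.0)
        x[0, :3] = 4000.0
        x[1, 3:] = 4000.0
        em = matrix_factory(
            x, obs_meta=pd.DataFrame({"grp": ["A"] * 3 + ["B"] * 3},
                                     index=[f"c{j}" for j in range(6)]),
        )
        ranked = rank_genes(em, "grp")
        # identical library sizes after the shift cancel in the ratio
        assert ranked["g0"] == pytest.approx(2.0, abs=0.15)
        assert ranked.index[0] == "g0"

    def test_equal_means_give_zero(self, matrix_factory):
        x = np.full((3, 4), 10.0)
        em = matrix_factory(
            x, obs_meta=pd.DataFrame({"grp": ["A", "A", "B", "B"]},
                                     index=[f"c{j}" for j in range(4)]),
        )
        assert np.allclose(rank_genes(em, "grp").to_numpy(), 0.0)

    def test_ordering_matches_brute_force_on_toy(self, matrix_factory):
        rng = np.random.default_rng(0)
        x = rng.integers(0, 50, size=(20, 8)).astype(float)
        labels = ["A"] * 4 + ["B"] * 4
        em = matrix_factory(
            x, obs_meta=pd.DataFrame({"grp": labels}, index=[f"c{j}" for j in range(8)])
        )
        ranked = rank_genes(em, "grp")
        cpm = x / x.sum(axis=0) * 1e6
        fc = np.log2((cpm[:, :4].mean(axis=1) + 1) / (cpm[:, 4:].mean(axis=1) + 1))
        expected = [f"g{i}" for i in np.argsort(-fc, kind="stable")]
        assert list(ranked.index) == expected

    def test_one_empty_group_rejected(self, matrix_factory):
        em = matrix_factory(
            np.ones((2, 2)),
            obs_meta=pd.DataFrame({"grp": ["A", "A"]}, index=["c0", "c1"]),
        )
        with pytest.raises(ValueError):
            rank_genes(em, "grp")


class TestEnrichmentScore:
    def test_perfect_front_set(self):
        ranked = ranked_series([10, 9, 8, 7, 6, 5, 4, 3, 2, 1])
        es, leading = enrichment_score(ranked, ["g0", "g1"])
        assert es == pytest.approx(1.0)
        assert leading == ["g0", "g1"]

    def test_bottom_set_hand_enumeration(self):
        # 8 leading misses at -1/8 each: running sum reaches -1 before any hit
        ranked = ranked_series([10, 9, 8, 7, 6, 5, 4, 3, 2, 1])
        es, leading = enrichment_score(ranked, ["g8", "g9"])
        assert es == pytest.approx(-1.0)
        assert set(leading) == {"g8", "g9"}

    def test_unweighted_limit_ignores_statistics(self):
        ranked = ranked_series([100, 50, 10, 5, 1, 0.5])
        flat = ranked_series([1, 1, 1, 1, 1, 1])
        for s in (["g0", "g3"], ["g1", "g4", "g5"]):
            assert enrichment_score(ranked, s, weight_exponent=0.0)[0] == pytest.approx(
                enrichment_score(flat, s, weight_exponent=0.0)[0]
            )

    def test_disjoint_set_rejected(self):
        with pytest.raises(ValueError, match="disjoint"):
            enrichment_score(ranked_series([3, 2, 1]), ["nope"])

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_brute_force_running_sum(self, seed):
        rng = np.random.default_rng(seed)
        g = int(rng.integers(5, 50))
        stats = rng.normal(0, 2, size=g)
        s = int(rng.integers(1, max(2, g // 2)))
        members = rng.choice(g, size=s, replace=False)
        p = float(rng.choice([0.0, 1.0, 2.0]))
        ranked = ranked_series(stats)
        es, _ = enrichment_score(ranked, [f"g{i}" for i in members], p)
        in_set = np.isin([int(name[1:]) for name in ranked.index], members)
        assert es == pytest.approx(
            brute_force_enrichment_score(ranked.to_numpy(), in_set, p), abs=1e-12
        )


class TestPrerankedGsea:
    def test_top_set_hits_permutation_floor(self):
        rng = np.random.default_rng(0)
        stats = np.sort(rng.normal(0, 1, 200))[::-1] + 5
        ranked = ranked_series(stats)
        res = preranked_gsea(
            ranked, {"top": [f"g{i}" for i in range(15)]}, n_perm=1000, seed=1
        )
        row = res.set_index("set").loc["top"]
        assert row["pval"] <= 0.002
        assert row["status"] == "tested"
        assert row["es"] > 0 and row["nes"] > 0

    def test_size_filtered_sets_reported(self):
        ranked = ranked_series(np.arange(100, 0, -1))
        res = preranked_gsea(
            ranked, {"tiny": ["g0", "g1"], "ok": [f"g{i}" for i in range(20)]},
            n_perm=100, seed=0,
        )
        assert set(res["set"]) == {"tiny", "ok"}
        assert res.set_index("set").loc["tiny", "status"] == "filtered"

    def test_scale_invariance_of_pvalues(self):
        rng = np.random.default_rng(3)
        stats = rng.normal(size=80)
        sets = {"a": [f"g{i}" for i in rng.choice(80, 20, replace=False)]}
        r1 = preranked_gsea(ranked_series(stats), sets, n_perm=200, seed=5)
        r2 = preranked_gsea(ranked_series(stats * 7.5), sets, n_perm=200, seed=5)
        assert r1["pval"].tolist() == r2["pval"].tolist()
        assert r1["es"].iloc[0] == pytest.approx(r2["es"].iloc[0])

    def test_fixed_seed_bit_identical(self):
        rng = np.random.default_rng(4)
        stats = rng.normal(size=60)
        sets = {"a": [f"g{i}" for i in range(20)], "b": [f"g{i}" for i in range(30, 50)]}
        r1 = preranked_gsea(ranked_series(stats), sets, n_perm=150, seed=9)
        r2 = preranked_gsea(ranked_series(stats), sets, n_perm=150, seed=9)
        pd.testing.assert_frame_equal(r1, r2)

    def test_adjusted_p_not_below_raw(self):
        rng = np.random.default_rng(6)
        stats = rng.normal(size=100)
        sets = {f"s{k}": [f"g{i}" for i in rng.choice(100, 20, replace=False)]
                for k in range(5)}
        res = preranked_gsea(ranked_series(stats), sets, n_perm=120, seed=2)
        tested = res[res["status"] == "tested"]
        assert (tested["padj"] >= tested["pval"] - 1e-15).all()
        assert np.all(np.sign(tested["nes"]) == np.sign(tested["es"]))


class TestHurdleDe:
    def _labeled(self, matrix_factory, x, labels):
        return matrix_factory(
            x, obs_meta=pd.DataFrame({"grp": labels}, index=[f"c{j}" for j in range(x.shape[1])])
        )

    def test_identical_groups_null_identity(self, matrix_factory):
        rng = np.random.default_rng(0)
        half = rng.integers(0, 6, size=(10, 8)).astype(float)
        x = np.concatenate([half, half], axis=1)
        em = self._labeled(matrix_factory, x, ["A"] * 8 + ["B"] * 8)
        res = hurdle_de(em, "grp")
        testable = res[~res["untestable"]]
        assert np.allclose(testable["stat"], 0.0, atol=1e-10)
        assert np.allclose(testable["pval"], 1.0)

    def test_detection_only_signal_carried_by_part_one(self, matrix_factory):
        rng = np.random.default_rng(1)
        n = 100
        x = np.zeros((2, 2 * n))
        # gene 0: detected in 90% of A, 10% of B, equal positive level when detected
        det_a = rng.random(n) < 0.9
        det_b = rng.random(n) < 0.1
        x[0, :n][det_a] = 5.0
        x[0, n:][det_b] = 5.0
        x[1, :] = rng.integers(1, 10, size=2 * n)  # keeps library sizes positive
        em = self._labeled(matrix_factory, x, ["A"] * n + ["B"] * n)
        res = hurdle_de(em, "grp")
        g0 = res.loc["g0"]
        assert g0["det_rate_diff"] == pytest.approx(0.8, abs=0.1)
        assert g0["pval"] < 1e-10
        # the continuous part is flat: the statistic equals the detection LRT
        ka, kb = det_a.sum(), det_b.sum()
        from scipy.stats import chi2
        p_pool = (ka + kb) / (2 * n)

        def ll(k, m, p):
            return (k * np.log(p) if k else 0.0) + ((m - k) * np.log(1 - p) if m - k else 0.0)

        det_stat = 2 * (ll(ka, n, ka / n) + ll(kb, n, kb / n) - ll(ka + kb, 2 * n, p_pool))
        assert g0["stat"] == pytest.approx(det_stat, rel=0.05)

    def test_never_detected_gene_untestable(self, matrix_factory):
        x = np.zeros((2, 6))
        x[1, :] = 3.0
        em = self._labeled(matrix_factory, x, ["A"] * 3 + ["B"] * 3)
        res = hurdle_de(em, "grp")
        assert bool(res.loc["g0", "untestable"])
        assert np.isnan(res.loc["g0", "pval"])

    def test_bh_controls_false_positives_under_null(self, matrix_factory):
        rng = np.random.default_rng(7)
        n_genes, n = 400, 60
        detected = rng.random((n_genes, 2 * n)) < 0.6
        x = np.where(detected, rng.lognormal(1.0, 0.5, size=(n_genes, 2 * n)), 0.0)
        em = self._labeled(matrix_factory, x, ["A"] * n + ["B"] * n)
        res = hurdle_de(em, "grp")
        assert int((res["padj"] < 0.05).sum()) <= max(3, int(0.01 * n_genes))
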