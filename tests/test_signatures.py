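"""Signature scoring: closed forms, brute-force oracles, invariances."""

import numpy as np
import pandas as pd
import pytest

from gliaxis.signatures import (
    ampar_score,
    auc_score,
    jasmine_score,
    module_score,
    pseudobulk,
    ssgsea_score,
    znorm,
)

from _oracles import brute_force_auc


class TestModuleScore:
    def test_constant_matrix_scores_zero(self, matrix_factory):
        em = matrix_factory(np.full((30, 5), 3.0))
        scores = module_score(em, {"s": ["g0", "g5", "g9"]}, seed=0)
        assert np.allclose(scores["s"], 0.0)

    def test_single_gene_full_bin_closed_form(self, matrix_factory):
        rng = np.random.default_rng(0)
        x = rng.uniform(1, 2, size=(10, 4))
        em = matrix_factory(x)
        # one bin, controls = all 9 non-set genes
        scores = module_score(em, {"s": ["g3"]}, n_bins=1, n_ctrl=9, seed=0, normalize=False)
        others = np.delete(x, 3, axis=0).mean(axis=0)
        assert np.allclose(scores["s"], x[3, :] - others)

    def test_invariant_to_global_constant_shift(self, matrix_factory):
        rng = np.random.default_rng(1)
        x = rng.uniform(0, 5, size=(40, 6))
        s1 = module_score(matrix_factory(x), {"s": ["g1", "g2"]}, seed=3, normalize=False)
        s2 = module_score(matrix_factory(x + 7.5), {"s": ["g1", "g2"]}, seed=3, normalize=False)
        assert np.allclose(s1["s"], s2["s"])

    def test_absent_genes_warn_and_empty_set_is_nan(self, matrix_factory):
        em = matrix_factory(np.ones((5, 3)))
        with pytest.warns(UserWarning, match="absent"):
            scores = module_score(em, {"s": ["g0", "NOPE"]}, seed=0)
        assert scores["s"].notna().all()
        with pytest.warns(UserWarning, match="no genes present"):
            scores = module_score(em, {"void": ["NOPE"]}, seed=0)
        assert scores["void"].isna().all()


class TestAucScore:
    def test_perfect_front_scores_one(self, matrix_factory):
        x = np.array([[9.0], [8.0], [1.0], [0.5], [0.2], [0.1]])
        em = matrix_factory(x)
        scores = auc_score(em, {"s": ["g0", "g1"]}, top_fraction=0.5)
        assert scores["s"].iloc[0] == pytest.approx(1.0)

    def test_bottom_ranked_set_scores_zero(self, matrix_factory):
        x = np.array([[5.0], [4.0], [3.0], [2.0], [0.0], [0.0]])
        em = matrix_factory(x)
        scores = auc_score(em, {"s": ["g4", "g5"]}, top_fraction=0.5)
        assert scores["s"].iloc[0] == 0.0

    def test_step_curve_enumeration_example(self, matrix_factory):
        # 10 genes, window 5, set at ranks 1 and 3
        x = np.arange(10, 0, -1, dtype=float).reshape(-1, 1)
        em = matrix_factory(x)
        scores = auc_score(em, {"s": ["g0", "g2"]}, top_fraction=0.5)
        # cumulative hits (1,1,2,2,2) sum 8; max area (1,2,2,2,2) sum 9
        assert scores["s"].iloc[0] == pytest.approx(8.0 / 9.0)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force_recovery_curve(self, matrix_factory, seed):
        rng = np.random.default_rng(seed)
        n_genes = int(rng.integers(8, 30))
        x = rng.uniform(0, 10, size=(n_genes, 3))
        set_genes = rng.choice(n_genes, size=rng.integers(2, 5), replace=False)
        in_set = np.zeros(n_genes, dtype=bool)
        in_set[set_genes] = True
        frac = float(rng.uniform(0.2, 1.0))
        em = matrix_factory(x)
        scores = auc_score(em, {"s": [f"g{i}" for i in set_genes]}, top_fraction=frac)
        window = int(np.ceil(frac * n_genes))
        for j in range(3):
            assert scores["s"].iloc[j] == pytest.approx(
                brute_force_auc(x[:, j], in_set, window)
            )

    def test_monotone_transform_invariance(self, matrix_factory):
        rng = np.random.default_rng(5)
        x = rng.uniform(0, 4, size=(20, 4))
        sets = {"s": ["g2", "g7", "g11"]}
        s1 = auc_score(matrix_factory(x), sets)
        s2 = auc_score(matrix_factory(np.exp(x)), sets)
        assert np.allclose(s1["s"], s2["s"])

    def test_empty_set_rejected(self, matrix_factory):
        with pytest.raises(ValueError):
            with pytest.warns(UserWarning):
                auc_score(matrix_factory(np.ones((4, 2))), {"s": ["NOPE"]})


class TestSsgseaScore:
    def test_whole_matrix_set_is_zero_by_convention(self, matrix_factory):
        em = matrix_factory(np.arange(8, dtype=float).reshape(4, 2) + 1)
        scores = ssgsea_score(em, {"all": [f"g{i}" for i in range(4)]})
        assert np.allclose(scores["all"], 0.0)

    def test_top_gene_alpha_zero_closed_form(self, matrix_factory):
        # 5 genes, distinct values, set = the top gene, alpha = 0:
        # P_in = 1 everywhere; P_out = (0, 1/4, 2/4, 3/4, 1); ES = 5 - 2.5
        x = np.array([[5.0], [4.0], [3.0], [2.0], [1.0]])
        scores = ssgsea_score(matrix_factory(x), {"s": ["g0"]}, alpha=0.0)
        assert scores["s"].iloc[0] == pytest.approx(2.5)

    @pytest.mark.parametrize("seed", range(20))
    def test_promoting_a_set_gene_never_decreases_score(self, matrix_factory, seed):
        rng = np.random.default_rng(seed)
        n = 8
        x = rng.permutation(np.arange(1.0, n + 1)).reshape(-1, 1)
        set_genes = ["g1", "g5"]
        base = ssgsea_score(matrix_factory(x.copy()), {"s": set_genes}).iloc[0, 0]
        # swap a set gene's value with the next-larger non-set value
        gi = 1 if rng.random() < 0.5 else 5
        larger = np.where(x[:, 0] > x[gi, 0])[0]
        larger = [i for i in larger if i not in (1, 5)]
        if not larger:
            return
        swap = larger[np.argmin(x[larger, 0])]
        x[gi, 0], x[swap, 0] = x[swap, 0], x[gi, 0]
        promoted = ssgsea_score(matrix_factory(x), {"s": set_genes}).iloc[0, 0]
        assert promoted >= base - 1e-12

    def test_constant_column_still_defined(self, matrix_factory):
        em = matrix_factory(np.full((6, 2), 2.0))
        scores = ssgsea_score(em, {"s": ["g0", "g3"]})
        assert np.isfinite(scores["s"]).all()


class TestJasmineScore:
    def test_hand_enumerated_two_cell_example(self, matrix_factory):
        # cell A expresses both set genes at the top ranks, cell B none
        x = np.array(
            [[5.0, 0.0], [3.0, 0.0], [1.0, 4.0], [0.0, 1.0], [2.0, 0.0], [0.0, 2.0]]
        )
        em = matrix_factory(x)
        scores = jasmine_score(em, {"s": ["g0", "g1"]})
        # A: mean rank (4+3)/2 / 4 expressed = 0.875; OR (2.5/0.5)/(2.5/2.5) = 5
        # B: no set gene expressed -> 0; OR (0.5/2.5)/(3.5/1.5)
        # min-max over the two cells -> 1 and 0
        assert scores["s"].tolist() == pytest.approx([1.0, 0.0])

    def test_ordering_by_set_expression(self, matrix_factory):
        rng = np.random.default_rng(2)
        x = rng.integers(0, 3, size=(20, 2)).astype(float)
        x[[1, 4, 7], 0] = 50.0  # set strongly expressed in cell 0 only
        x[[1, 4, 7], 1] = 0.0
        scores = jasmine_score(matrix_factory(x), {"s": ["g1", "g4", "g7"]})
        assert scores["s"].iloc[0] > scores["s"].iloc[1]

    def test_identical_cells_degenerate_to_zero(self, matrix_factory):
        em = matrix_factory(np.tile([[3.0], [0.0], [1.0], [2.0]], (1, 4)))
        scores = jasmine_score(em, {"s": ["g0", "g2"]})
        assert np.allclose(scores["s"], 0.0)

    def test_monotone_transform_invariance(self, matrix_factory):
        rng = np.random.default_rng(8)
        x = rng.integers(0, 6, size=(15, 5)).astype(float)
        sets = {"s": ["g3", "g8"]}
        s1 = jasmine_score(matrix_factory(x), sets)
        s2 = jasmine_score(matrix_factory(np.sqrt(x) * 10), sets)
        assert np.allclose(s1["s"], s2["s"])


class TestPseudobulk:
    def test_additivity(self, matrix_factory):
        em = matrix_factory(
            np.array([[1.0, 3.0], [2.0, 4.0]]),
            obs_meta=pd.DataFrame({"grp": ["a", "a"]}, index=["c0", "c1"]),
        )
        pb = pseudobulk(em, "grp")
        assert pb.dense()[:, 0].tolist() == [4.0, 6.0]

    def test_identity_when_each_cell_own_group(self, matrix_factory):
        x = np.arange(12, dtype=float).reshape(3, 4)
        em = matrix_factory(
            x, obs_meta=pd.DataFrame({"grp": [f"c{j}" for j in range(4)]},
                                     index=[f"c{j}" for j in range(4)])
        )
        pb = pseudobulk(em, "grp")
        assert np.array_equal(pb.dense(), x)

    def test_three_patients_two_regions_give_six_columns(self, matrix_factory):
        rng = np.random.default_rng(0)
        n = 60
        labels = [f"p{i % 3}_{'HFC' if j < 1 else 'LFC'}" for i in range(30) for j in range(2)]
        em = matrix_factory(
            rng.integers(0, 5, size=(10, n)).astype(float),
            obs_meta=pd.DataFrame({"sample": labels}, index=[f"c{j}" for j in range(n)]),
        )
        assert pseudobulk(em, "sample").n_obs == 6

    def test_unlabeled_observation_rejected(self, matrix_factory):
        em = matrix_factory(
            np.ones((2, 2)),
            obs_meta=pd.DataFrame({"grp": ["a", None]}, index=["c0", "c1"]),
        )
        with pytest.raises(ValueError, match="unlabeled"):
            pseudobulk(em, "grp")


class TestZnorm:
    def test_arithmetic_example(self):
        df = pd.DataFrame({"s": [1.0, 2.0, 3.0]})
        assert znorm(df)["s"].tolist() == pytest.approx([-1.0, 0.0, 1.0])

    def test_constant_scores_map_to_zero(self):
        df = pd.DataFrame({"s": [2.0, 2.0, 2.0]})
        assert znorm(df)["s"].tolist() == [0.0, 0.0, 0.0]

    @pytest.mark.parametrize("seed", range(5))
    def test_output_mean_zero_unit_sd(self, seed):
        rng = np.random.default_rng(seed)
        df = pd.DataFrame({"s": rng.normal(3, 2, size=50)})
        z = znorm(df)["s"]
        assert z.mean() == pytest.approx(0.0, abs=1e-12)
        assert z.std(ddof=1) == pytest.approx(1.0)

    def test_single_observation_rejected(self):
        with pytest.raises(ValueError):
            znorm(pd.DataFrame({"s": [1.0]}))


class TestAmparScore:
    def test_ampar_top_ranked_column_is_maximal(self, matrix_factory):
        genes = ["Gria1", "Gria2", "Gria3", "Gria4"] + [f"g{i}" for i in range(8)]
        x = np.ones((12, 3))
        x[:4, 0] = 50.0  # AMPAR genes dominate column 0
        x[4:, 1] = 50.0
        em = matrix_factory(x, genes=genes)
        scores = ampar_score(em)
        assert scores["AMPAR"].idxmax() == "c0"
        assert scores.attrs["set_size"] == 4

    def test_equal_columns_equal_scores(self, matrix_factory):
        genes = ["Gria1", "Gria2", "Gria3", "Gria4"] + [f"g{i}" for i in range(4)]
        x = np.tile(np.arange(8, dtype=float).reshape(-1, 1) + 1, (1, 3))
        scores = ampar_score(matrix_factory(x, genes=genes))
        assert scores["AMPAR"].nunique() == 1


@pytest.mark.parametrize("seed", range(10))
def test_all_methods_agree_on_dominating_observation(matrix_factory, seed):
    """One observation strictly dominates another on set genes and matches on
    the rest: every scoring method must rank it at least as high."""
    rng = np.random.default_rng(seed)
    n_genes = 30
    base = rng.integers(1, 8, size=n_genes).astype(float)
    x = np.column_stack([base.copy(), base.copy()])
    set_ix = rng.choice(n_genes, size=5, replace=False)
    x[set_ix, 0] += rng.integers(3, 10, size=5)
    sets = {"s": [f"g{i}" for i in set_ix]}
    em = matrix_factory(x)
    for scores in (
        module_score(em, sets, seed=0, normalize=False),
        auc_score(em, sets, top_fraction=0.5),
        ssgsea_score(em, sets),
        jasmine_score(em, sets),
    ):
        assert scores["s"].iloc[0] >= scores["s"].iloc[1]
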