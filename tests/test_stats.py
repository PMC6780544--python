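"""Univariate tests, PCA, and random-forest importance on ratio matrices."""

import numpy as np
import pandas as pd
import pytest

from iroapairs import (
    bh_qvalues,
    pca,
    random_forest_mda,
    top_importance,
    unpaired_t_test,
)

from conftest import GROUPS, SAMPLES, make_ratio_matrix


def matrix_from_log2(values, index=None):
    return make_ratio_matrix(2.0 ** np.asarray(values, dtype=float), index=index)


class TestTTest:
    def test_hand_computed_example(self):
        # log2 ratios {0, .1, -.1, 0} vs {1, 1.1, .9, 1}: pooled t = -17.32, df = 6
        vals = [[0.0, 0.1, -0.1, 0.0, 1.0, 1.1, 0.9, 1.0]]
        res = unpaired_t_test(matrix_from_log2(vals))
        assert res.frame["t"].iloc[0] == pytest.approx(-np.sqrt(300.0), abs=1e-6)
        assert res.frame["df"].iloc[0] == 6

    def test_identical_groups_degenerate(self):
        res = unpaired_t_test(matrix_from_log2([[0.3] * 8]))
        assert res.frame["t"].iloc[0] == 0.0
        assert res.frame["p"].iloc[0] == 1.0

    def test_degenerate_variance_with_shift(self):
        res = unpaired_t_test(matrix_from_log2([[1.0] * 4 + [0.0] * 4]))
        assert np.isinf(res.frame["t"].iloc[0]) and res.frame["t"].iloc[0] > 0
        assert res.frame["p"].iloc[0] == 0.0

    def test_sign_matches_mean_difference(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(0, 1, (100, 8))
        res = unpaired_t_test(matrix_from_log2(vals))
        diff = vals[:, :4].mean(axis=1) - vals[:, 4:].mean(axis=1)
        assert (np.sign(res.frame["t"]) == np.sign(diff)).all()

    def test_against_statsmodels_oracle(self):
        from statsmodels.stats.weightstats import ttest_ind as sm_ttest

        rng = np.random.default_rng(8)
        vals = rng.normal(0, 1, (20, 8))
        res = unpaired_t_test(matrix_from_log2(vals))
        for i in range(20):
            t, p, df = sm_ttest(vals[i, :4], vals[i, 4:], usevar="pooled")
            assert res.frame["t"].iloc[i] == pytest.approx(t, abs=1e-10)
            assert res.frame["p"].iloc[i] == pytest.approx(p, abs=1e-12)
            assert res.frame["df"].iloc[i] == df

    def test_welch_variant_differs_under_unequal_variance(self):
        rng = np.random.default_rng(9)
        vals = np.column_stack([rng.normal(0, 3, (30, 4)), rng.normal(0, 0.3, (30, 4))])
        student = unpaired_t_test(matrix_from_log2(vals))
        welch = unpaired_t_test(matrix_from_log2(vals), welch=True)
        assert not np.allclose(student.frame["df"], welch.frame["df"])

    def test_null_rejection_rate_at_alpha(self):
        """Type-I error of the pooled test at alpha = 0.001 on 10,000 null
        rows stays inside the 99% binomial band."""
        rng = np.random.default_rng(12)
        vals = rng.normal(0, 1, (10_000, 8))
        res = unpaired_t_test(matrix_from_log2(vals))
        k = int((res.frame["p"] < 0.001).sum())
        assert 2 <= k <= 18  # 99% binomial interval around 10

    def test_bh_qvalues_match_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(1)
        p = pd.Series(rng.uniform(0, 1, 200))
        q = bh_qvalues(p)
        _, q_sm, _, _ = multipletests(p.to_numpy(), method="fdr_bh")
        assert np.allclose(q, q_sm)


class TestPCA:
    def test_single_varying_metabolite_owns_all_variance(self):
        vals = np.ones((5, 8))
        vals[0] = [4, 4, 4, 4, 1, 1, 1, 1]
        res = pca(make_ratio_matrix(vals), scaling="autoscale")
        assert res.variance_fraction[0] == pytest.approx(1.0)

    def test_variance_fractions_non_increasing_and_bounded(self):
        rng = np.random.default_rng(6)
        res = pca(make_ratio_matrix(2.0 ** rng.normal(0, 1, (40, 8))))
        vf = res.variance_fraction
        assert (np.diff(vf) <= 1e-12).all()
        assert vf.sum() <= 1 + 1e-9

    def test_full_rank_reconstruction(self):
        rng = np.random.default_rng(7)
        vals = rng.normal(0, 1, (30, 8))
        matrix = make_ratio_matrix(2.0**vals)
        res = pca(matrix, scaling="center")
        recon = res.scores.to_numpy() @ res.loadings.to_numpy().T
        centered = vals.T - vals.T.mean(axis=0)
        assert np.allclose(recon, centered, atol=1e-8)

    def test_two_group_shift_separates_on_pc1(self):
        rng = np.random.default_rng(10)
        vals = rng.normal(0, 0.2, (60, 8))
        vals[:30, :4] += 1.0  # 30 metabolites shifted in the treatment group
        res = pca(make_ratio_matrix(2.0**vals))
        pc1 = res.scores["PC1"]
        assert np.sign(pc1.iloc[:4].mean()) != np.sign(pc1.iloc[4:].mean())

    def test_sign_convention_deterministic(self):
        rng = np.random.default_rng(13)
        matrix = make_ratio_matrix(2.0 ** rng.normal(0, 1, (25, 8)))
        a, b = pca(matrix), pca(matrix)
        assert a.scores.equals(b.scores)
        for col in a.loadings.columns:
            load = a.loadings[col].to_numpy()
            assert load[np.argmax(np.abs(load))] > 0

    def test_too_few_samples_rejected(self):
        vals = np.ones((4, 8))
        matrix = make_ratio_matrix(vals)
        matrix.ratios = matrix.ratios.iloc[:, :2]
        matrix.imputed_mask = matrix.imputed_mask.iloc[:, :2]
        with pytest.raises(ValueError):
            pca(matrix)


def marker_matrix(n_noise=4, seed=0, constant_noise=True):
    """One perfectly separating metabolite; the rest carry no usable signal."""
    rng = np.random.default_rng(seed)
    rows = [np.concatenate([np.full(4, 3.0), np.full(4, -3.0)])]
    for _ in range(n_noise):
        rows.append(np.zeros(8) if constant_noise else rng.normal(0, 1, 8))
    index = ["marker"] + [f"noise{i}" for i in range(n_noise)]
    return make_ratio_matrix(2.0 ** np.array(rows), index=index)


class TestRandomForest:
    def test_perfect_marker_maximal_mda_zero_oob(self):
        """With one separating metabolite (and no competing variation) every
        tree must split on it: OOB error 0 and the marker tops the MDA."""
        rf = random_forest_mda(marker_matrix(), n_trees=500, seed=42)
        assert rf.oob_error == 0.0
        assert rf.mda.idxmax() == "marker"
        assert rf.mda["marker"] > 0.2
        assert (rf.mda.drop("marker").abs() < 1e-12).all()  # constants can't split

    def test_pure_noise_mda_centers_on_zero(self):
        rng = np.random.default_rng(21)
        matrix = make_ratio_matrix(2.0 ** rng.normal(0, 1, (30, 8)))
        rf = random_forest_mda(matrix, n_trees=300, seed=2)
        assert abs(rf.mda.mean()) < 0.05

    def test_determinism_under_fixed_seed(self):
        m = marker_matrix(n_noise=6, constant_noise=False)
        a = random_forest_mda(m, n_trees=200, seed=7)
        b = random_forest_mda(m, n_trees=200, seed=7)
        assert a.oob_error == b.oob_error
        assert a.mda.equals(b.mda)
        assert a.proximity.equals(b.proximity)
        assert a.mds_coords.equals(b.mds_coords)

    def test_group_label_swap_symmetry(self):
        """Renaming the two classes consistently changes nothing the forest
        measures."""
        m1 = marker_matrix(n_noise=6, constant_noise=False)
        m2 = marker_matrix(n_noise=6, constant_noise=False)
        m2.groups = m1.groups.map({"treatment": "control", "control": "treatment"})
        a = random_forest_mda(m1, n_trees=200, seed=3)
        b = random_forest_mda(m2, n_trees=200, seed=3)
        assert a.oob_error == b.oob_error
        assert np.allclose(a.mda, b.mda)

    def test_proximity_properties(self):
        rf = random_forest_mda(marker_matrix(n_noise=6, constant_noise=False), n_trees=200, seed=5)
        prox = rf.proximity.to_numpy()
        assert np.allclose(prox, prox.T)
        assert np.allclose(np.diag(prox), 1.0)
        assert prox.min() >= 0.0 and prox.max() <= 1.0
        assert rf.mds_coords.shape == (8, 2)

    def test_too_few_trees_rejected(self):
        with pytest.raises(ValueError):
            random_forest_mda(marker_matrix(), n_trees=50, seed=0)


class TestTopImportance:
    def test_ranking_and_directions(self):
        rf = random_forest_mda(marker_matrix(n_noise=6, constant_noise=False), n_trees=200, seed=1)
        fc = pd.Series(1.0, index=rf.mda.index)
        top = top_importance(rf, 3, log2fc=fc)
        assert len(top) == 3
        assert top.index[0] == "marker"
        assert (top["direction"] == "increase").all()
        assert (top["mda"].diff().dropna() <= 0).all()

    def test_zero_k_empty(self):
        rf = random_forest_mda(marker_matrix(), n_trees=200, seed=1)
        assert len(top_importance(rf, 0)) == 0

    def test_k_beyond_rows_rejected(self):
        rf = random_forest_mda(marker_matrix(), n_trees=200, seed=1)
        with pytest.raises(ValueError):
            top_importance(rf, 99)
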