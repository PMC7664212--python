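"""Transform gating, ANOVA, PCA/OPLS-DA latent models and the selection rule."""

import numpy as np
import pandas as pd
import pytest

from cilffa.stats_models import (one_way_anova, oplsda, pca, select_significant,
                                 transform_gate)


class TestTransformGate:
    def test_normal_data_keeps_identity(self):
        rng = np.random.default_rng(0)
        hits = 0
        n_sim = 200
        for _ in range(n_sim):
            groups = [rng.normal(10, 1, 12) for _ in range(4)]
            if transform_gate(groups).transform == "none":
                hits += 1
        assert hits / n_sim > 0.9

    def test_lognormal_data_selects_log10(self):
        rng = np.random.default_rng(1)
        hits = 0
        n_sim = 200
        for _ in range(n_sim):
            groups = [np.exp(rng.normal(0, 1.0, 20)) for _ in range(4)]
            if transform_gate(groups).transform == "log10":
                hits += 1
        assert hits / n_sim >= 0.9

    def test_negative_values_error_for_nonidentity(self):
        rng = np.random.default_rng(2)
        # strongly skewed groups containing a negative value: the identity gate
        # fails and sqrt/log10 cannot be applied
        groups = [np.concatenate([rng.exponential(1.0, 30) ** 2, [-0.5]])
                  for _ in range(3)]
        with pytest.raises(ValueError, match="non-positive"):
            transform_gate(groups)

    def test_shift_policy(self):
        rng = np.random.default_rng(2)
        groups = [np.concatenate([rng.exponential(1.0, 30) ** 2, [-0.5]])
                  for _ in range(3)]
        res = transform_gate(groups, shift=True)
        assert res.transform in ("none", "sqrt", "log10")

    def test_forced_fallback_is_flagged(self):
        rng = np.random.default_rng(3)
        # heavy bimodal mixture: no candidate transform normalizes it
        groups = [np.concatenate([rng.normal(1, 0.01, 10), rng.normal(100, 0.01, 10)])
                  for _ in range(3)]
        res = transform_gate(groups)
        assert res.transform == "log10" and res.forced


class TestOneWayAnova:
    def test_identical_groups(self):
        res = one_way_anova([np.array([1., 2., 3.]), np.array([1., 2., 3.])])
        assert res.f == 0.0 and res.p == 1.0

    def test_hand_computed_f(self):
        res = one_way_anova([np.array([1., 2.]), np.array([3., 4.])])
        assert res.f == pytest.approx(8.0)
        assert res.p == pytest.approx(0.10557, abs=1e-4)
        assert (res.df_between, res.df_within) == (1, 2)

    def test_agrees_with_scipy(self):
        from scipy.stats import f_oneway
        rng = np.random.default_rng(4)
        groups = [rng.normal(i * 0.3, 1, 10) for i in range(4)]
        res = one_way_anova(groups)
        ref = f_oneway(*groups)
        assert res.f == pytest.approx(ref.statistic)
        assert res.p == pytest.approx(ref.pvalue)

    def test_degenerate_zero_within_variance(self):
        res = one_way_anova([np.array([1., 1.]), np.array([2., 2.])])
        assert res.degenerate and res.p < 1e-100 and np.isinf(res.f)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            one_way_anova([np.array([1., 2.])])


class TestPCA:
    def test_collinear_rows_fully_explained(self):
        t = np.linspace(0, 1, 10)
        X = np.outer(t, [1.0, -2.0, 0.5])
        model = pca(X, n_components=1, scale=False)
        assert model.r2x[0] == pytest.approx(1.0)

    def test_row_permutation_leaves_r2x(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(30, 8))
        m1 = pca(X, 3)
        m2 = pca(X[rng.permutation(30)], 3)
        np.testing.assert_allclose(m1.r2x, m2.r2x, atol=1e-12)

    def test_full_rank_reconstruction_exact(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(12, 5))
        m = pca(X, n_components=5, scale=False)
        Xc = X - X.mean(axis=0)
        np.testing.assert_allclose(m.scores @ m.loadings.T, Xc, atol=1e-9)

    def test_excess_components_truncated(self):
        rng = np.random.default_rng(7)
        m = pca(rng.normal(size=(4, 10)), n_components=8)
        assert m.truncated and len(m.r2x) == 3

    def test_planted_group_separates_in_scores(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(40, 20))
        X[:10, :5] += 4.0  # one group shifted along a 5-variable direction
        m = pca(X, 2)
        d = m.scores[:10, :2].mean(axis=0) - m.scores[10:, :2].mean(axis=0)
        spread = m.scores[:, :2].std(axis=0)
        assert np.linalg.norm(d / spread) > 2.0

    def test_missing_values_rejected(self):
        X = np.ones((5, 3))
        X[0, 0] = np.nan
        with pytest.raises(ValueError, match="missing"):
            pca(X)


class TestOplsda:
    def _shifted(self, rng, n_per=20, p=10, shift=3.0):
        X = rng.normal(size=(2 * n_per, p))
        X[n_per:, :3] += shift
        y = np.array(["a"] * n_per + ["b"] * n_per)
        return X, y

    def test_informative_variable_ranks_above_noise(self):
        rng = np.random.default_rng(9)
        n = 40
        y = np.array(["a"] * 20 + ["b"] * 20)
        x1 = (y == "b").astype(float) * 2 + rng.normal(0, 0.3, n)
        x2 = rng.normal(0, 1, n)
        m = oplsda(np.column_stack([x1, x2]), y, n_orthogonal=0)
        assert m.vip[0] > 1 > m.vip[1]

    def test_vip_normalization_identity(self):
        rng = np.random.default_rng(10)
        X = rng.normal(size=(25, 17))
        y = np.array(["a", "b", "c", "d", "a"] * 5)
        m = oplsda(X, y, n_orthogonal=2)
        assert (m.vip ** 2).sum() == pytest.approx(X.shape[1], abs=1e-9)

    def test_separated_classes_give_high_q2(self):
        rng = np.random.default_rng(11)
        X, y = self._shifted(rng, shift=3.0)
        m = oplsda(X, y)
        assert m.q2 > 0.5 and m.r2y > 0.5

    def test_single_class_rejected(self):
        rng = np.random.default_rng(12)
        with pytest.raises(ValueError, match="classes"):
            oplsda(rng.normal(size=(10, 3)), np.array(["a"] * 10))

    def test_variable_reordering_flips_scores_at_most_in_sign(self):
        rng = np.random.default_rng(13)
        X, y = self._shifted(rng)
        perm = rng.permutation(X.shape[1])
        t1 = oplsda(X, y, n_orthogonal=1).scores[:, 0]
        t2 = oplsda(X[:, perm], y, n_orthogonal=1).scores[:, 0]
        agree = min(np.abs(t1 - t2).max(), np.abs(t1 + t2).max())
        assert agree < 1e-9

    def test_r2x_gains_are_fractions(self):
        rng = np.random.default_rng(14)
        X, y = self._shifted(rng)
        m = oplsda(X, y, n_orthogonal=3)
        assert np.all(m.r2x >= 0) and m.r2x_cum <= 1.0 + 1e-12

    def test_predictive_scores_match_sklearn_pls(self):
        # with no orthogonal filtering and binary y the single predictive
        # component must align with scikit-learn's PLS scores (independent
        # NIPALS implementation)
        from sklearn.cross_decomposition import PLSRegression

        rng = np.random.default_rng(15)
        X, y = self._shifted(rng)
        m = oplsda(X, y, n_orthogonal=0)
        ref = PLSRegression(n_components=1, scale=True).fit(X, (y == "b").astype(float))
        r = np.corrcoef(m.scores[:, 0], ref.x_scores_[:, 0])[0, 1]
        assert abs(r) > 0.999


class TestSelectSignificant:
    def _series(self, d):
        return pd.Series(d)

    def test_joint_rule(self):
        p = self._series({"f1": 0.01, "f2": 0.2, "f3": 0.01})
        vip = self._series({"f1": 1.2, "f2": 1.2, "f3": 0.8})
        assert select_significant(p, vip) == ["f1"]

    def test_mismatched_sets_rejected(self):
        with pytest.raises(ValueError, match="different"):
            select_significant(self._series({"a": 0.01}), self._series({"b": 1.5}))

    def test_fdr_flag_only_shrinks_selection(self):
        rng = np.random.default_rng(16)
        ids = [f"f{i}" for i in range(100)]
        p = pd.Series(rng.uniform(0, 0.2, 100), index=ids)
        vip = pd.Series(rng.uniform(0.5, 2.0, 100), index=ids)
        assert set(select_significant(p, vip, fdr=True)) <= set(select_significant(p, vip))
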