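"""Distance mathematics: noise covariance, whitening, crossnobis, comparison."""

import numpy as np
import pytest
from scipy.stats import rankdata

import spatemp_rsa as sr
from spatemp_rsa import crossnobis
from spatemp_rsa.types import RDM, FoldPatterns


def rand_rdm(n, seed):
    return sr.synth.random_geometry_rdm(n, seed=seed)


class TestEstimateNoiseCov:
    def test_scaled_orthonormal_residuals_give_identity(self):
        t, v = 50, 5
        q, _ = np.linalg.qr(np.random.default_rng(0).standard_normal((t, v)))
        r = q * np.sqrt(t)
        cov, _ = crossnobis.estimate_noise_cov(r, shrinkage=0.0)
        assert np.allclose(cov, np.eye(v), atol=1e-12)

    def test_hand_computed_two_feature_case(self):
        # T = 3 residual matrix; covariance is R'R / T by hand
        r = np.array([[1.0, 2.0], [0.0, -1.0], [2.0, 1.0]])
        cov, lam = crossnobis.estimate_noise_cov(r, shrinkage=0.0)
        expected = np.array([[5.0, 4.0], [4.0, 6.0]]) / 3.0
        assert lam == 0.0
        assert np.allclose(cov, expected, atol=1e-12)

    def test_full_shrinkage_is_diagonal(self):
        r = np.random.default_rng(1).standard_normal((30, 4))
        cov, _ = crossnobis.estimate_noise_cov(r, shrinkage=1.0)
        off = cov - np.diag(np.diag(cov))
        assert np.abs(off).max() == 0.0

    def test_auto_shrinkage_in_unit_interval(self):
        r = np.random.default_rng(2).standard_normal((20, 8))
        _, lam = crossnobis.estimate_noise_cov(r, shrinkage="auto")
        assert 0.0 <= lam <= 1.0

    def test_nan_residuals_rejected(self):
        r = np.ones((5, 2))
        r[0, 0] = np.nan
        with pytest.raises(ValueError, match="finite"):
            crossnobis.estimate_noise_cov(r, shrinkage=0.0)


class TestWhitenPatterns:
    def test_identity_covariance_is_noop(self):
        p = np.random.default_rng(3).standard_normal((4, 6))
        assert np.allclose(crossnobis.whiten_patterns(p, np.eye(6)), p)

    def test_diagonal_covariance_divides_columns(self):
        p = np.random.default_rng(4).standard_normal((3, 2))
        out = crossnobis.whiten_patterns(p, np.diag([4.0, 9.0]))
        assert np.allclose(out, p / np.array([2.0, 3.0]), atol=1e-12)

    def test_round_trip_through_covariance_sqrt(self):
        rng = np.random.default_rng(5)
        a = rng.standard_normal((6, 6))
        cov = a @ a.T + 0.5 * np.eye(6)
        p = rng.standard_normal((4, 6))
        w, v = np.linalg.eigh(cov)
        sqrt_cov = v @ np.diag(np.sqrt(w)) @ v.T
        unwhitened = p @ sqrt_cov
        assert np.allclose(crossnobis.whiten_patterns(unwhitened, cov), p, atol=1e-8)

    def test_whitened_residual_covariance_near_identity(self):
        # with T >> V the whitening makes the residual covariance ~ identity
        rng = np.random.default_rng(6)
        a = rng.standard_normal((5, 5))
        chol = a @ a.T + np.eye(5)
        r = rng.standard_normal((10_000, 5)) @ np.linalg.cholesky(chol).T
        cov, _ = crossnobis.estimate_noise_cov(r, shrinkage=0.0)
        white = crossnobis.whiten_patterns(r, cov)
        emp = white.T @ white / white.shape[0]
        assert np.linalg.norm(emp - np.eye(5)) < 0.05

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError, match="incompatible"):
            crossnobis.whiten_patterns(np.zeros((2, 3)), np.eye(4))


class TestCrossnobisRdm:
    def test_noiseless_equal_folds_match_direct_distance(self):
        rng = np.random.default_rng(7)
        p = rng.standard_normal((5, 7))
        fp = FoldPatterns([p.copy() for _ in range(4)], [f"c{i}" for i in range(5)])
        rdm = crossnobis.crossnobis_rdm(fp)
        direct = ((p[:, None] - p[None]) ** 2).sum(-1) / 7.0
        assert np.abs(rdm.values - direct).max() < 1e-12

    def test_identical_conditions_give_zero(self):
        rng = np.random.default_rng(8)
        folds = []
        for _ in range(3):
            f = rng.standard_normal((3, 5))
            f[1] = f[0]  # conditions 0 and 1 identical within every fold
            folds.append(f)
        rdm = crossnobis.crossnobis_rdm(FoldPatterns(folds, ["a", "b", "c"]))
        assert rdm.values[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_unbiased_under_null(self):
        """Mean distance straddles zero for pure-noise patterns (sign test)."""
        from scipy.stats import binomtest

        rng = np.random.default_rng(9)
        signs = []
        for _ in range(400):
            folds = [rng.standard_normal((4, 6)) for _ in range(3)]
            rdm = crossnobis.crossnobis_rdm(FoldPatterns(folds, list("abcd")))
            signs.append(rdm.condensed().mean() > 0)
        p = binomtest(sum(signs), len(signs), 0.5).pvalue
        assert p > 0.01

    def test_single_fold_rejected(self):
        fp = FoldPatterns([np.zeros((2, 3))], ["a", "b"])
        with pytest.raises(ValueError, match="2 folds"):
            crossnobis.crossnobis_rdm(fp)

    def test_pairs_scheme_equals_loo_for_two_folds(self):
        rng = np.random.default_rng(10)
        folds = [rng.standard_normal((4, 6)) for _ in range(2)]
        fp = FoldPatterns(folds, list("abcd"))
        a = crossnobis.crossnobis_rdm(fp, scheme="loo")
        b = crossnobis.crossnobis_rdm(fp, scheme="pairs")
        assert np.allclose(a.values, b.values, atol=1e-12)

    def test_feature_normalization_toggle(self):
        rng = np.random.default_rng(11)
        folds = [rng.standard_normal((3, 8)) for _ in range(2)]
        fp = FoldPatterns(folds, list("abc"))
        a = crossnobis.crossnobis_rdm(fp, normalize_by_features=True)
        b = crossnobis.crossnobis_rdm(fp, normalize_by_features=False)
        assert np.allclose(b.values, a.values * 8.0, atol=1e-12)


class TestSpearmanRdm:
    def test_self_correlation_is_one(self):
        m = rand_rdm(6, 1)
        rho, n = crossnobis.spearman_rdm(m, m)
        assert rho == pytest.approx(1.0)
        assert n == 15

    def test_rank_reversal_gives_minus_one(self):
        m = rand_rdm(6, 2)
        flipped = RDM(m.values.max() - m.values, m.labels)
        rho, _ = crossnobis.spearman_rdm(flipped, m)
        assert rho == pytest.approx(-1.0)

    def test_matches_brute_force_rank_then_pearson(self):
        d, m = rand_rdm(4, 3), rand_rdm(4, 4)
        rho, _ = crossnobis.spearman_rdm(d, m)
        rx, ry = rankdata(d.condensed()), rankdata(m.condensed())
        expected = np.sum((rx - rx.mean()) * (ry - ry.mean())) / np.sqrt(
            np.sum((rx - rx.mean()) ** 2) * np.sum((ry - ry.mean()) ** 2)
        )
        assert rho == pytest.approx(expected, abs=1e-12)

    def test_invariant_under_monotone_transforms(self):
        d, m = rand_rdm(7, 5), rand_rdm(7, 6)
        rho0, _ = crossnobis.spearman_rdm(d, m)
        d2 = RDM(np.sqrt(d.values), d.labels)
        m2 = RDM(np.log1p(m.values) * 3.0, m.labels)
        rho1, _ = crossnobis.spearman_rdm(d2, m2)
        assert rho1 == pytest.approx(rho0, abs=1e-12)

    def test_constant_model_rejected(self):
        d = rand_rdm(4, 7)
        flat = RDM(np.ones((4, 4)) - np.eye(4), d.labels)
        flat.values[:] = 0  # zero everywhere -> constant condensed vector
        with pytest.raises(ValueError, match="constant"):
            crossnobis.spearman_rdm(d, RDM(np.zeros((4, 4)), d.labels))


class TestPartialSpearmanRdm:
    def test_matches_independent_partial_correlation(self):
        import pandas as pd
        import pingouin as pg

        d, m, c = rand_rdm(6, 1), rand_rdm(6, 2), rand_rdm(6, 3)
        rho, _ = crossnobis.partial_spearman_rdm(d, m, c)
        df = pd.DataFrame(
            {"x": d.condensed(), "y": m.condensed(), "z": c.condensed()}
        )
        expected = pg.partial_corr(df, x="x", y="y", covar="z", method="spearman")
        assert rho == pytest.approx(expected["r"].iloc[0], abs=1e-10)

    def test_orthogonal_control_equals_plain_spearman(self):
        # build data/model/control RDMs directly from rank permutations,
        # with the control exactly rank-orthogonal to both of the others
        # (15 pairs: the orthogonality sum is an integer, so exact zero
        # correlation between distinct-rank permutations is attainable)
        n, n_pairs = 6, 15
        rng = np.random.default_rng(0)
        rc = rng.permutation(n_pairs).astype(float) + 1

        def orthogonal_perm(local_rng):
            for _ in range(50_000):
                p = local_rng.permutation(n_pairs).astype(float) + 1
                if abs(np.corrcoef(p, rc)[0, 1]) < 1e-12:
                    return p
            raise AssertionError("no orthogonal permutation found")

        rd = orthogonal_perm(np.random.default_rng(1))
        rm = orthogonal_perm(np.random.default_rng(2))

        def to_rdm(vec):
            vals = np.zeros((n, n))
            i, j = np.tril_indices(n, -1)
            vals[i, j] = vec
            vals += vals.T
            return RDM(vals, [f"c{k}" for k in range(n)])

        d, m, control = to_rdm(rd), to_rdm(rm), to_rdm(rc)
        plain, _ = crossnobis.spearman_rdm(d, m)
        partial, _ = crossnobis.partial_spearman_rdm(d, m, control)
        assert partial == pytest.approx(plain, abs=1e-10)

    def test_data_generated_from_control_has_near_zero_partial(self):
        rhos = []
        for seed in range(100):
            c = rand_rdm(8, seed + 500)
            m = rand_rdm(8, seed + 900)
            rho, _ = crossnobis.partial_spearman_rdm(c, m, c)  # data == control
            rhos.append(rho)
        assert np.abs(np.mean(rhos)) < 0.05

    def test_model_equal_control_rejected(self):
        d, m = rand_rdm(4, 6), rand_rdm(4, 7)
        with pytest.raises(ValueError, match="identical"):
            crossnobis.partial_spearman_rdm(d, m, m)


class TestNoiseCeiling:
    def test_identical_subjects_give_one(self):
        m = rand_rdm(6, 8)
        assert crossnobis.noise_ceiling_upper([m, m, m]) == pytest.approx(1.0)

    def test_rank_opposite_subjects_give_finite_value(self):
        m = rand_rdm(3, 9)
        flipped = RDM(m.values.max() - m.values, m.labels)
        val = crossnobis.noise_ceiling_upper([m, flipped])
        assert np.isfinite(val)

    def test_upper_bound_exceeds_lower_bound(self):
        rng = np.random.default_rng(10)
        base = rand_rdm(8, 11)
        subs = []
        for _ in range(6):
            noise = rng.standard_normal(base.values.shape)
            noise = 0.3 * (noise + noise.T) * (1 - np.eye(8))
            subs.append(RDM(np.abs(base.values + noise), base.labels))
        assert crossnobis.noise_ceiling_upper(subs) >= crossnobis.noise_ceiling_lower(subs)

    def test_label_mismatch_rejected(self):
        a = rand_rdm(4, 12)
        b = RDM(a.values, ["w", "x", "y", "z"])
        with pytest.raises(ValueError, match="labels"):
            crossnobis.noise_ceiling_upper([a, b])
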