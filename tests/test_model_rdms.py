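"""Model-RDM construction: onsets, averaging, correlation RDMs, MNN, display."""

import numpy as np
import pytest

import spatemp_rsa as sr
from spatemp_rsa import model_rdms
from spatemp_rsa.types import RDM, ChannelEpochs


def make_epochs(data, fs=100.0, labels=None, t0=0.0):
    data = np.asarray(data, dtype=float)
    if labels is None:
        labels = [f"c{i}" for i in range(data.shape[0])]
    return ChannelEpochs(data, fs, t0, labels)


class TestDetectOnset:
    fs = 1000.0

    def test_zero_signal_gives_none(self):
        assert model_rdms.detect_onset(np.zeros(1000), self.fs) is None

    def test_constant_signal_gives_none(self):
        assert model_rdms.detect_onset(np.ones(1000), self.fs) is None

    def test_step_onset_near_true_sample(self):
        sig = np.zeros(1000)
        sig[400:650] = 1.0
        onset = model_rdms.detect_onset(sig, self.fs)
        # Hilbert edge ringing spreads the detected edge by a few ms
        assert onset is not None and abs(onset - 400) <= 15

    def test_burst_duration_threshold(self):
        t = np.arange(1000) / self.fs
        short = np.zeros(1000)
        short[400:500] = np.sin(2 * np.pi * 50 * t[:100])  # 100 ms < 200 ms
        assert model_rdms.detect_onset(short, self.fs) is None
        long = np.zeros(1000)
        long[400:700] = np.sin(2 * np.pi * 50 * t[:300])  # 300 ms >= 200 ms
        onset = model_rdms.detect_onset(long, self.fs)
        assert onset is not None and abs(onset - 400) <= 5

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError, match="sampling rate"):
            model_rdms.detect_onset(np.zeros(1000), 0.0)
        with pytest.raises(ValueError, match="shorter"):
            model_rdms.detect_onset(np.zeros(50), self.fs)


class TestEarliestOnset:
    def test_minimum_over_channels(self):
        fs = 1000.0
        t = np.arange(1000) / fs
        burst = np.sin(2 * np.pi * 40 * t[:300])
        data = np.zeros((1, 3, 1000))
        for ch, start in enumerate((100, 80, 120)):
            data[0, ch, start : start + 300] = burst
        ep = make_epochs(data, fs=fs, labels=["m"])
        onset = model_rdms.earliest_onset(ep, 0)
        assert onset == pytest.approx(80.0, abs=5.0)

    def test_single_channel_equals_channel_onset(self):
        fs = 1000.0
        t = np.arange(1000) / fs
        data = np.zeros((1, 1, 1000))
        data[0, 0, 300:600] = np.sin(2 * np.pi * 40 * t[:300])
        ep = make_epochs(data, fs=fs, labels=["m"])
        idx = model_rdms.detect_onset(data[0, 0], fs, smoothing_ms=0.0)
        assert model_rdms.earliest_onset(ep, 0) == pytest.approx(1000.0 * idx / fs)

    def test_no_onset_flags_trial(self):
        ep = make_epochs(np.zeros((1, 3, 1000)), fs=1000.0, labels=["m"])
        assert model_rdms.earliest_onset(ep, 0) is None


class TestAverageByCondition:
    def test_identity_for_single_trials(self):
        rng = np.random.default_rng(0)
        data = rng.standard_normal((3, 2, 10))
        ep = make_epochs(data, labels=["a", "b", "c"])
        avgs, conds = model_rdms.average_by_condition(ep)
        assert conds == ["a", "b", "c"]
        assert np.array_equal(avgs, data)

    def test_mean_of_two_trials(self):
        data = np.stack([np.zeros((2, 5)), np.full((2, 5), 2.0)])
        ep = make_epochs(data, labels=["a", "a"])
        avgs, _ = model_rdms.average_by_condition(ep)
        assert np.allclose(avgs[0], 1.0)


class TestChannelCorrelationRdm:
    def test_identical_timecourses_have_zero_dissimilarity(self):
        rng = np.random.default_rng(1)
        tc = rng.standard_normal((2, 30))
        avgs = np.stack([tc, tc])
        rdm = model_rdms.channel_correlation_rdm(avgs, ["a", "b"])
        assert rdm.values[0, 1] == pytest.approx(0.0, abs=1e-9)

    def test_single_channel_equals_one_minus_pearson(self):
        rng = np.random.default_rng(2)
        x, y = rng.standard_normal((2, 50))
        avgs = np.stack([x[None, :], y[None, :]])
        rdm = model_rdms.channel_correlation_rdm(avgs, ["a", "b"])
        expected = 1.0 - np.corrcoef(x, y)[0, 1]
        assert rdm.values[0, 1] == pytest.approx(expected, abs=1e-12)

    def test_matches_brute_force_oracle(self):
        """3 conditions x 2 channels against an independent direct computation."""
        rng = np.random.default_rng(3)
        avgs = rng.standard_normal((3, 2, 40))
        rdm = model_rdms.channel_correlation_rdm(avgs, ["a", "b", "c"])
        for i in range(3):
            for j in range(3):
                if i == j:
                    continue
                zs = []
                for ch in range(2):
                    r = np.corrcoef(avgs[i, ch], avgs[j, ch])[0, 1]
                    zs.append(np.arctanh(r))
                expected = 1.0 - np.tanh(np.mean(zs))
                assert rdm.values[i, j] == pytest.approx(expected, abs=1e-12)

    def test_invariant_to_per_channel_affine_rescaling(self):
        rng = np.random.default_rng(4)
        avgs = rng.standard_normal((4, 3, 25))
        scaled = avgs * np.array([2.0, 0.5, 7.0])[None, :, None] + np.array(
            [1.0, -3.0, 10.0]
        )[None, :, None]
        a = model_rdms.channel_correlation_rdm(avgs, list("abcd"))
        b = model_rdms.channel_correlation_rdm(scaled, list("abcd"))
        assert np.allclose(a.values, b.values, atol=1e-10)

    def test_constant_channel_dropped_with_warning(self, caplog):
        rng = np.random.default_rng(5)
        avgs = rng.standard_normal((2, 2, 30))
        avgs[0, 1, :] = 3.0  # constant channel for condition 0
        with caplog.at_level("WARNING"):
            rdm = model_rdms.channel_correlation_rdm(avgs, ["a", "b"])
        expected = 1.0 - np.corrcoef(avgs[0, 0], avgs[1, 0])[0, 1]
        assert rdm.values[0, 1] == pytest.approx(expected, abs=1e-12)
        assert "constant channel" in caplog.text


class TestMnnTrials:
    def _epochs_with_cov(self, cov, n_trials=2000, seed=0):
        rng = np.random.default_rng(seed)
        n_ch = cov.shape[0]
        chol = np.linalg.cholesky(cov)
        noise = rng.standard_normal((n_trials, 20, n_ch)) @ chol.T
        data = noise.transpose(0, 2, 1)
        labels = ["a", "b"] * (n_trials // 2)
        return make_epochs(data, labels=labels)

    def test_identity_error_covariance_is_noop(self):
        rng = np.random.default_rng(6)
        # exactly identity pooled covariance via symmetric orthogonalization
        data = rng.standard_normal((40, 3, 30))
        ep = make_epochs(data, labels=["a", "b"] * 20)
        cov = model_rdms.error_covariance(ep)
        w, v = np.linalg.eigh(cov)
        fix = v @ np.diag(1.0 / np.sqrt(w)) @ v.T
        ep2 = ChannelEpochs(
            np.einsum("tcs,cd->tds", ep.data, fix), ep.fs, ep.t0_ms, ep.labels
        )
        out = model_rdms.mnn_trials(ep2, shrinkage=0.0)
        assert np.allclose(out.data, ep2.data, atol=1e-10)

    def test_invariant_to_channel_scaling(self):
        # base data with exactly identity error covariance, so the scaled
        # covariance is exactly diagonal and the inverse square root
        # undoes the scaling without a residual rotation
        rng = np.random.default_rng(7)
        data = rng.standard_normal((40, 3, 30))
        ep0 = make_epochs(data, labels=["a", "b"] * 20)
        cov = model_rdms.error_covariance(ep0)
        w, v = np.linalg.eigh(cov)
        fix = v @ np.diag(1.0 / np.sqrt(w)) @ v.T
        base = ChannelEpochs(
            np.einsum("tcs,cd->tds", ep0.data, fix), ep0.fs, ep0.t0_ms, ep0.labels
        )
        out1 = model_rdms.mnn_trials(base, shrinkage=0.0)
        scaled = ChannelEpochs(
            base.data * np.array([10.0, 1.0, 1.0])[None, :, None],
            base.fs, base.t0_ms, base.labels,
        )
        out2 = model_rdms.mnn_trials(scaled, shrinkage=0.0)
        rel = np.abs(out1.data - out2.data).max() / np.abs(out1.data).max()
        assert rel < 1e-6

    def test_pooled_error_covariance_becomes_identity(self):
        cov = np.array([[2.0, 0.8, 0.0], [0.8, 1.0, -0.3], [0.0, -0.3, 0.5]])
        ep = self._epochs_with_cov(cov, seed=8)
        out = model_rdms.mnn_trials(ep, shrinkage=0.0)
        pooled = model_rdms.error_covariance(out)
        assert np.allclose(pooled, np.eye(3), atol=1e-6)

    def test_singular_covariance_rejected(self):
        data = np.zeros((4, 2, 10))
        data[:, 0] = np.random.default_rng(9).standard_normal((4, 10))
        data[:, 1] = data[:, 0]  # perfectly correlated channels
        ep = make_epochs(data, labels=["a", "a", "b", "b"])
        with pytest.raises(ValueError, match="shrinkage"):
            model_rdms.mnn_trials(ep, shrinkage=0.0)


class TestEthologicalRdm:
    def test_binary_by_category(self, movements26):
        rdm = model_rdms.ethological_rdm(movements26)
        cats = [movements26.categories[lab] for lab in movements26.labels]
        for i in range(26):
            for j in range(26):
                expected = 0.0 if cats[i] == cats[j] else 1.0
                if i == j:
                    expected = 0.0
                assert rdm.values[i, j] == expected
        assert rdm.kind == "model_categorical"

    def test_category_blocks_after_reordering(self, movements26):
        rdm = model_rdms.ethological_rdm(movements26)
        cats = np.array([movements26.categories[lab] for lab in movements26.labels])
        order = np.argsort(cats, kind="stable")
        v = rdm.values[np.ix_(order, order)]
        sorted_cats = cats[order]
        for c in np.unique(sorted_cats):
            block = v[np.ix_(sorted_cats == c, sorted_cats == c)]
            assert block.max() == 0.0

    def test_unknown_category_rejected(self):
        mv = sr.MovementSet(["x", "y"], {"x": "precision-prehensile", "y": "weird"})
        with pytest.raises(ValueError, match="unknown categories"):
            model_rdms.ethological_rdm(mv)


class TestClusterOrder:
    def test_well_separated_pairs_are_adjacent(self):
        v = np.array(
            [[0, 0.1, 5, 5], [0.1, 0, 5, 5], [5, 5, 0, 0.1], [5, 5, 0.1, 0]],
            dtype=float,
        )
        order = model_rdms.cluster_order(RDM(v, list("abcd")))
        pos = {k: i for i, k in enumerate(order)}
        assert abs(pos[0] - pos[1]) == 1
        assert abs(pos[2] - pos[3]) == 1

    def test_all_equal_rdm_gives_identity_under_tie_rule(self):
        v = np.ones((5, 5))
        np.fill_diagonal(v, 0)
        order = model_rdms.cluster_order(RDM(v, list("abcde")))
        assert np.array_equal(order, np.arange(5))

    def test_output_is_permutation(self, target26):
        order = model_rdms.cluster_order(target26)
        assert np.array_equal(np.sort(order), np.arange(26))


class TestMdsEmbed:
    def test_exact_3d_geometry_gives_near_zero_stress(self):
        rng = np.random.default_rng(10)
        pts = rng.standard_normal((8, 3))
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        coords, stress = model_rdms.mds_embed(
            RDM(d, [f"c{i}" for i in range(8)]), n_dims=3, seed=0
        )
        assert coords.shape == (8, 3)
        assert stress <= 1e-4

    def test_default_is_three_dimensions(self):
        import inspect

        sig = inspect.signature(model_rdms.mds_embed)
        assert sig.parameters["n_dims"].default == 3

    def test_all_zero_rdm_collapses_to_a_point(self):
        coords, stress = model_rdms.mds_embed(
            RDM(np.zeros((4, 4)), list("abcd")), n_dims=2
        )
        assert np.allclose(coords, coords[0])
        assert stress == 0.0

    def test_too_many_dimensions_rejected(self):
        with pytest.raises(ValueError, match="n_dims"):
            model_rdms.mds_embed(RDM(np.zeros((3, 3)), list("abc")), n_dims=3)


class TestSessionConsistency:
    def test_independent_sessions_agree_at_default_noise(
        self, movements26, target26, reorder
    ):
        """Split-session reliability of the kinematic model at default noise."""
        rdms = []
        for seed in (21, 22):
            spec = sr.PlantSpec(target26, noise_sd=1.0, seed=seed)
            ep = sr.synth.gen_glove_session(movements26, spec)
            avgs, conds = model_rdms.average_by_condition(ep)
            kin = model_rdms.channel_correlation_rdm(avgs, conds)
            rdms.append(reorder(RDM(kin.values, kin.labels), movements26.labels))
        rho, _ = sr.crossnobis.spearman_rdm(rdms[0], rdms[1])
        assert rho > 0.9
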