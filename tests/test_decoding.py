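"""Feature construction, shrinkage covariance, Mahalanobis tuning and
cross-validated decoding tests."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from prioshift.containers import EpochSet
from prioshift.decoding import (
    TUNING_OFFSETS_DEG,
    MahalanobisOrientationDecoder,
    build_features,
    crossval_decode,
    decoding_score,
    mahalanobis_tuning,
    shrinkage_covariance,
    _make_folds,
)
from prioshift.montage import CHANNELS_61, DECODING_CHANNELS
from prioshift.synth import ORIENTATION_GRID, SignalSpec, TaskConfig, simulate_dataset


def _noise_epochs(n_trials=8, seed=0):
    rng = np.random.default_rng(seed)
    n_t = 813
    times = -0.75 + np.arange(n_t) / 250.0
    return EpochSet(rng.standard_normal((n_trials, 61, n_t)), times, 250.0, CHANNELS_61)


class TestFeatures:
    def test_default_build_yields_629_features(self):
        fm = build_features(_noise_epochs(), t=1.1)
        assert fm.X.shape[1] == 629
        assert fm.X.shape[1] == 37 * len(DECODING_CHANNELS)
        assert len(fm.time_offsets) == 37

    def test_window_spacing_is_12ms_backward(self):
        fm = build_features(_noise_epochs(), t=1.1)
        d = np.diff(fm.time_offsets)
        assert np.allclose(d, 0.012)
        assert fm.time_offsets[-1] == pytest.approx(0.0, abs=1e-9)
        assert fm.time_offsets[0] == pytest.approx(-0.432, abs=1e-9)

    def test_constant_channel_demeans_to_zero(self):
        ep = _noise_epochs()
        ep.data[:, list(ep.channels).index("P7"), :] = 7.0  # first decoding sensor
        fm = build_features(ep, t=1.1)
        assert np.allclose(fm.X[:, :37], 0.0)

    def test_matches_direct_computation_on_toy_sensors(self):
        ep = _noise_epochs(n_trials=3, seed=1)
        sensors = ("P3", "Oz", "POz")
        fm = build_features(ep, t=1.1, sensors=sensors)
        i_t = ep.time_index(1.1)
        idx = i_t - 3 * np.arange(37)[::-1]
        for si, ch in enumerate(sensors):
            ci = list(ep.channels).index(ch)
            raw = ep.data[:, ci, idx]
            expect = raw - raw.mean(axis=1, keepdims=True)
            assert np.allclose(fm.X[:, si * 37:(si + 1) * 37], expect)

    def test_window_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            build_features(_noise_epochs(), t=-0.5)


class TestShrinkageCovariance:
    def test_identity_data_converges_to_identity(self):
        rng = np.random.default_rng(2)
        C, s = shrinkage_covariance(rng.standard_normal((20000, 5)))
        assert np.allclose(C, np.eye(5), atol=0.05)

    def test_invertible_when_features_exceed_rows(self):
        rng = np.random.default_rng(3)
        C, s = shrinkage_covariance(rng.standard_normal((10, 50)))
        assert np.linalg.cond(C) < 1e6
        assert np.allclose(C, C.T)
        assert np.all(np.linalg.eigvalsh(C) > 0)

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError):
            shrinkage_covariance(np.zeros((1, 4)))


class TestTuningAndScore:
    def test_identity_covariance_reduces_to_euclidean(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((64, 6))
        y = np.tile(ORIENTATION_GRID, 4)
        dec = MahalanobisOrientationDecoder().fit(X, y)
        dec.covariance_ = np.eye(6)
        from scipy.linalg import cho_factor

        dec._cho = cho_factor(dec.covariance_)
        d = dec.distances(X[:3])
        expect = np.linalg.norm(X[:3, None, :] - dec.class_means_[None], axis=2)
        assert np.allclose(d, expect)

    def test_class_mean_attains_maximal_similarity(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((64, 8))
        y = np.tile(ORIENTATION_GRID, 4)
        dec = MahalanobisOrientationDecoder().fit(X, y)
        for k in (0, 5, 11):
            curve = dec.tuning_curves(dec.class_means_[k][None], [ORIENTATION_GRID[k]])[0]
            assert curve.argmax() == 7               # center bin, offset 0

    def test_mahalanobis_tuning_matches_solve_oracle(self):
        rng = np.random.default_rng(6)
        X = rng.standard_normal((48, 5))
        y = np.tile(ORIENTATION_GRID, 3)
        cov = np.cov(rng.standard_normal((40, 5)), rowvar=False) + 0.5 * np.eye(5)
        x_test = rng.standard_normal(5)
        curve = mahalanobis_tuning(X, y, (x_test, ORIENTATION_GRID[4]), cov)
        means = np.stack([X[np.isclose(y, o)].mean(0) for o in ORIENTATION_GRID])
        inv = np.linalg.inv(cov)
        d = np.array([np.sqrt((x_test - m) @ inv @ (x_test - m)) for m in means])
        centered = -d[(4 + np.arange(16) - 7) % 16]
        assert np.allclose(curve, centered, atol=1e-10)

    def test_flat_curve_scores_zero(self):
        assert decoding_score(np.full(16, 3.3)) == pytest.approx(0.0, abs=1e-12)

    def test_cosine_curve_scores_sum_of_squares(self):
        c = np.cos(2 * np.deg2rad(TUNING_OFFSETS_DEG))
        brute = sum(np.cos(2 * np.deg2rad(th)) ** 2 for th in TUNING_OFFSETS_DEG)
        assert decoding_score(c) == pytest.approx(brute)
        assert decoding_score(-c) == pytest.approx(-brute)

    @given(st.floats(-100, 100), st.integers(0, 2**16 - 1))
    def test_score_offset_invariant_and_sign_equivariant(self, offset, bits):
        rng = np.random.default_rng(bits)
        curve = rng.standard_normal(16) * 3
        s = decoding_score(curve)
        assert decoding_score(curve + offset) == pytest.approx(s, abs=1e-8)
        assert decoding_score(-curve) == pytest.approx(-s, abs=1e-10)


class TestOracleEquivalence:
    def test_distances_match_bruteforce_on_random_small_instances(self):
        """Mahalanobis path vs explicit-inverse quadratic forms, many instances."""
        rng = np.random.default_rng(7)
        from scipy.spatial.distance import mahalanobis as scipy_mahal

        for _ in range(300):
            p = int(rng.integers(2, 11))
            X = rng.standard_normal((32, p))
            y = np.tile(ORIENTATION_GRID, 2)
            dec = MahalanobisOrientationDecoder().fit(X, y)
            inv = np.linalg.inv(dec.covariance_)
            x = rng.standard_normal(p)
            d = dec.distances(x[None])[0]
            expect = np.array([scipy_mahal(x, m, inv) for m in dec.class_means_])
            assert np.allclose(d, expect, atol=1e-8)


class TestFolds:
    def test_128_blocks_give_12_tens_and_one_eight(self):
        folds = _make_folds(np.repeat(np.arange(128), 16))
        sizes = [len(f) for f in folds]
        assert len(folds) == 13
        assert sizes == [10] * 12 + [8]

    def test_minimum_block_count_enforced(self):
        with pytest.raises(ValueError, match="13"):
            _make_folds(np.arange(5))

    def test_folds_are_contiguous_and_disjoint(self):
        folds = _make_folds(np.arange(16))
        allb = np.concatenate(folds)
        assert sorted(allb) == list(range(16))
        assert np.all(np.diff(allb) == 1)


class TestCrossvalDecode:
    def test_shuffled_labels_score_near_zero(self, planted_dataset):
        trials, epochs = planted_dataset
        rng = np.random.default_rng(8)
        sh = trials.copy()
        sh["theta_cued"] = rng.permutation(sh["theta_cued"].to_numpy())
        res = crossval_decode(epochs, sh, target="cued", timepoints=[1.1])
        s = res["score"]
        assert abs(s.mean()) < 2 * s.std() / np.sqrt(len(s))

    def test_planted_tuning_recovered_and_monotone_in_snr(self):
        means = []
        for snr in (0.0, 0.5, 1.0):
            per = []
            for seed in (30, 31):
                tr, ep = simulate_dataset(TaskConfig(n_blocks=16),
                                          SignalSpec(evoked_snr=snr, snr_jitter_sd=0.0),
                                          seed=seed)
                res = crossval_decode(ep, tr, target="cued", timepoints=[1.1])
                per.append(res["score"].mean())
            means.append(np.mean(per))
        assert abs(means[0]) < 1.0                 # no signal
        assert means[1] > 2.0 and means[2] > means[1]

    def test_cross_decoding_requires_shared_weights(self):
        """Training on cued and testing on uncued orientations only transfers
        when the uncued item is encoded in the cued item's representational
        format (shared channel weights); with an independent format the cross
        score collapses to the (slightly negative) finite-sample floor."""
        shared, indep = [], []
        for seed in (40, 41, 42):
            tr, ep = simulate_dataset(TaskConfig(n_blocks=16),
                                      SignalSpec(uncued_shares_weights=True), seed=seed)
            shared.append(crossval_decode(ep, tr, "cross", timepoints=[1.1])["score"].mean())
            tr2, ep2 = simulate_dataset(TaskConfig(n_blocks=16),
                                        SignalSpec(uncued_shares_weights=False), seed=seed)
            indep.append(crossval_decode(ep2, tr2, "cross", timepoints=[1.1])["score"].mean())
        assert np.mean(shared) > 1.0
        assert np.mean(indep) < 1.0
        assert np.mean(shared) - np.mean(indep) > 2.0

    def test_no_leakage_on_iid_label_noise(self):
        """With signal-free epochs and iid orientation labels the mean score
        is statistically zero (no information leaks through the CV chain)."""
        rng = np.random.default_rng(9)
        means = []
        for s in range(6):
            tr, ep = simulate_dataset(
                TaskConfig(n_blocks=16),
                SignalSpec(evoked_snr=0.0, theta_amp=0.0, beta_amp=0.0), seed=700 + s)
            tr = tr.copy()
            tr["theta_cued"] = rng.choice(ORIENTATION_GRID, len(tr))
            means.append(crossval_decode(ep, tr, "cued", timepoints=[1.1])["score"].mean())
        m = np.asarray(means)
        assert abs(m.mean()) < 2.5 * m.std(ddof=1) / np.sqrt(len(m))

    def test_tidy_output_schema(self, planted_dataset):
        trials, epochs = planted_dataset
        res = crossval_decode(epochs, trials, target=["cued", "cross"], timepoints=[1.0, 1.1])
        assert set(res.columns) == {"trial", "timepoint", "target", "score", "fold"}
        assert set(res["target"]) == {"cued", "cross"}
        assert len(res) == 2 * 2 * len(trials)
        assert np.isfinite(res["score"]).all()
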