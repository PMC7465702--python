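import numpy as np
import pytest
from scipy import linalg

from smrfes import features as feat
from smrfes.features import (
    DegenerateEpochError,
    SubBandSet,
    band_power,
    csp_features,
    csp_fit,
    erds,
    erds_map,
    fusion_weights_from_accuracies,
    sbcsp_fuse,
    subband_decompose,
    total_power,
)
from smrfes.synthetic import SimulationParams, generate_session
from tests.test_preprocess import make_epoch


class TestSubBandSet:
    def test_default_bands(self):
        bands = SubBandSet()
        assert bands.bands[0] == (1.0, 5.0)
        assert bands.bands[-1] == (25.0, 29.0)
        assert len(bands.bands) == 7

    def test_non_contiguous_rejected(self):
        with pytest.raises(ValueError):
            SubBandSet(bands=((1.0, 5.0),) * 7)


class TestSubbandDecompose:
    def test_pure_tone_lands_in_its_band(self):
        t = np.arange(3072) / 256.0
        epoch = make_epoch(np.sin(2 * np.pi * 10 * t))
        outs = subband_decompose(epoch)
        energies = np.array([np.sum(o.signal**2) for o in outs])
        assert energies[2] / energies.sum() >= 0.9  # band (9, 13)

    def test_zero_input_zero_outputs(self):
        epoch = make_epoch(np.zeros((2, 3072)))
        for out in subband_decompose(epoch):
            assert np.allclose(out.signal, 0.0)

    def test_band_sum_reconstructs_wideband(self, rng):
        # Reconstruction oracle: identical tap counts make the seven
        # band filters sum to the full 1-29 Hz design exactly.
        from smrfes.features import zero_phase_fir
        from smrfes.preprocess import bandpass_taps

        epoch = make_epoch(rng.standard_normal((2, 3072)))
        outs = subband_decompose(epoch, numtaps=769)
        summed = np.sum([o.signal for o in outs], axis=0)
        full = zero_phase_fir(epoch.signal, bandpass_taps(256.0, (1.0, 29.0), 769))
        err = np.linalg.norm(summed - full) / np.linalg.norm(full)
        assert err <= 0.1

    def test_band_above_nyquist_rejected(self):
        epoch = make_epoch(np.zeros((1, 512)), fs=40.0)
        with pytest.raises(ValueError):
            subband_decompose(epoch)


class TestBandPower:
    def test_consumes_640_points(self, rng):
        seg = rng.standard_normal((3, 640))
        out = band_power(seg, fs=256.0)
        assert out.shape == (3, 7)
        with pytest.raises(ValueError):
            band_power(seg[:, :639], fs=256.0)

    def test_parseval_on_white_noise(self, rng):
        sigma = 2.5
        seg = rng.standard_normal((1, 640)) * sigma
        total = total_power(seg, fs=256.0)[0]
        assert abs(total - seg.var()) / seg.var() < 0.15

    def test_zero_signal_zero_power(self):
        assert np.allclose(band_power(np.zeros((2, 640)), fs=256.0), 0.0)


class TestErds:
    def test_identity(self):
        assert erds(10.0, 10.0) == 0.0

    def test_half_power_is_minus_fifty(self):
        assert erds(10.0, 5.0) == -50.0

    def test_double_power_is_plus_hundred(self):
        assert erds(5.0, 10.0) == 100.0

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            erds(0.0, 1.0)


def orthogonal_trial(var1: float, var2: float, n: int = 1024) -> np.ndarray:
    """Two-channel trial with exactly diagonal covariance (var1, var2)."""
    t = np.arange(n)
    x1 = np.sqrt(2 * var1) * np.sin(2 * np.pi * 8 * t / n)
    x2 = np.sqrt(2 * var2) * np.cos(2 * np.pi * 8 * t / n)
    return np.vstack([x1, x2])


class TestCspFit:
    def test_identical_classes_give_half_eigenvalues(self, rng):
        trials = [rng.standard_normal((3, 512)) for _ in range(4)]
        model = csp_fit(trials, trials, selected_pairs=1)
        assert np.allclose(model.eigenvalues, 0.5, atol=1e-6)

    def test_diagonal_toy_matches_eigendecomposition_oracle(self):
        c1 = [orthogonal_trial(0.8, 0.2) for _ in range(3)]
        c2 = [orthogonal_trial(0.2, 0.8) for _ in range(3)]
        model = csp_fit(c1, c2)
        assert np.allclose(sorted(model.eigenvalues), [0.2, 0.8], atol=1e-6)
        # Independent oracle: generalized eigenvalues of (C1, C1 + C2).
        cov1 = np.diag([0.8, 0.2])
        cov2 = np.diag([0.2, 0.8])
        oracle = np.sort(linalg.eigh(cov1, cov1 + cov2)[0])
        assert np.allclose(np.sort(model.eigenvalues), oracle, atol=1e-6)
        # Filters align with the coordinate axes up to sign/scale.
        for row in model.projection:
            assert min(abs(row[0]), abs(row[1])) < 1e-6 * max(abs(row))

    def test_trace_normalization(self, rng):
        c1 = [rng.standard_normal((4, 512)) for _ in range(5)]
        c2 = [rng.standard_normal((4, 512)) * 2.0 for _ in range(5)]
        model = csp_fit(c1, c2)
        assert np.isclose(np.trace(model.cov_class1), 1.0, atol=1e-9)
        assert np.isclose(np.trace(model.cov_class2), 1.0, atol=1e-9)

    def test_eigenvalue_pairing_sums_to_one(self, rng):
        # For each filter, class-1 and class-2 eigenvalues sum to 1.
        c1 = [rng.standard_normal((4, 512)) for _ in range(6)]
        c2 = [np.diag([2.0, 1.0, 0.5, 0.25]) @ rng.standard_normal((4, 512))
              for _ in range(6)]
        model = csp_fit(c1, c2)
        w = model.projection
        lam2 = np.diag(w @ model.cov_class2 @ w.T) / np.diag(
            w @ (model.cov_class1 + model.cov_class2) @ w.T)
        assert np.allclose(model.eigenvalues + lam2, 1.0, atol=1e-6)

    def test_too_few_trials_rejected(self, rng):
        with pytest.raises(ValueError):
            csp_fit([rng.standard_normal((2, 64))],
                    [rng.standard_normal((2, 64))] * 3)


class TestCspFeatures:
    def toy_model(self):
        c1 = [orthogonal_trial(0.8, 0.2) for _ in range(3)]
        c2 = [orthogonal_trial(0.2, 0.8) for _ in range(3)]
        return csp_fit(c1, c2)

    def test_class1_draws_favor_first_filter(self, rng):
        model = self.toy_model()
        wins = 0
        for _ in range(100):
            trial = np.diag([np.sqrt(0.8), np.sqrt(0.2)]) @ rng.standard_normal((2, 256))
            f = csp_features(model, trial)
            wins += f[0] > f[-1]
        assert wins >= 90

    def test_zero_epoch_rejected(self):
        model = self.toy_model()
        with pytest.raises(DegenerateEpochError):
            csp_features(model, np.zeros((2, 256)))

    def test_scaling_shifts_log_features(self, rng):
        model = self.toy_model()
        trial = rng.standard_normal((2, 256))
        c = 3.0
        assert np.allclose(csp_features(model, c * trial),
                           csp_features(model, trial) + 2 * np.log(c))

    def test_channel_mismatch_rejected(self, rng):
        model = self.toy_model()
        with pytest.raises(ValueError):
            csp_features(model, rng.standard_normal((3, 256)))


class TestFusion:
    def test_one_hot_weight_selects_band(self):
        scores = np.array([0.1, -0.4, 2.0, 0.3, 0.0, -1.0, 0.5])
        weights = np.zeros(7)
        weights[2] = 1.0
        assert sbcsp_fuse(scores, weights) == 2.0

    def test_equal_weights_tie(self):
        scores = np.array([1.0, 1.0, 1.0, 1.0, 1.0, 1.0, -6.0])
        fused = sbcsp_fuse(scores, np.full(7, 1 / 7))
        assert abs(fused) < 1e-12

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            sbcsp_fuse(np.ones(7), np.ones(6) / 6)

    def test_negative_weights_rejected(self):
        w = np.full(7, 1 / 7)
        w[0], w[1] = -0.1, 2 / 7 + 0.1 - 1 / 7
        with pytest.raises(ValueError):
            sbcsp_fuse(np.ones(7), w)

    def test_informative_band_gets_largest_weight(self, rng):
        # CV oracle: per-band accuracies near chance except band 4.
        accs = np.full(7, 0.5)
        accs[4] = 0.9
        weights = fusion_weights_from_accuracies(accs)
        assert np.argmax(weights) == 4
        assert np.isclose(weights.sum(), 1.0)

    def test_fusion_dominance(self, rng):
        for _ in range(20):
            scores = rng.normal(0, 1, 7)
            scores[3] = 10.0 * np.sign(rng.standard_normal() + 1e-9)
            weights = rng.uniform(0.5, 1.0, 7)
            weights /= weights.sum()
            dominated = abs(weights[3] * scores[3]) > np.sum(
                np.abs(np.delete(weights * scores, 3)))
            if dominated:
                fused = sbcsp_fuse(scores, weights)
                assert np.sign(fused) == np.sign(scores[3])


def test_erd_recovery_on_synthetic_sessions():
    """ERD/ERS recovery: injected attenuation at C3 yields a clearly
    negative mu-band map entry on session averages."""
    params = SimulationParams(blink_rate=0.0, fes_artifact_amplitude=0.0,
                              erd_depth={"SOG": {"C3": 0.5}, "FCO": {"C3": 0.5}})
    c3 = list(params.channel_labels).index("C3")
    negatives = 0
    n_sessions = 5
    for s in range(n_sessions):
        session = generate_session(20, params, seed=100 + s)
        ref = np.mean([erds_map(ep).reference_power[c3, 2] for ep in session])
        act = np.mean([erds_map(ep).activity_power[c3, 2] for ep in session])
        value = erds(ref, act)
        if value < 0:
            negatives += 1
        assert -80.0 <= value <= -10.0
    assert negatives == n_sessions
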