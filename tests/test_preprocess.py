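import numpy as np
import pytest
from dataclasses import replace
from scipy import stats

from smrfes.montage import DEFAULT_NEIGHBORS
from smrfes.preprocess import (
    EmptySessionError,
    FilterSpec,
    FilterSpecError,
    OfflineOnlyError,
    bandpass_filter,
    ica_clean,
    notch_filter,
    pca_fit_project,
    reject_trials,
    surface_laplacian,
    trial_entropy,
)
from smrfes.synthetic import PERIOD_LAYOUT, TrialEpoch


def make_epoch(signal: np.ndarray, fs: float = 256.0,
               trial_id: str = "t0") -> TrialEpoch:
    return TrialEpoch(signal=np.atleast_2d(signal), sampling_rate=fs,
                      mi_class="SOG", feedback_class="KEEP",
                      period_bounds=PERIOD_LAYOUT, trial_id=trial_id, seed=0,
                      channel_labels=tuple(
                          f"ch{i}" for i in range(np.atleast_2d(signal).shape[0])))


def steady_rms(x: np.ndarray, margin: int = 256) -> float:
    return float(np.sqrt(np.mean(x[..., margin:-margin] ** 2)))


@pytest.fixture
def t_vec():
    return np.arange(3072) / 256.0


class TestNotch:
    def test_60hz_attenuated(self, t_vec):
        epoch = make_epoch(np.sin(2 * np.pi * 60 * t_vec))
        out = notch_filter(epoch)
        assert steady_rms(out.signal) <= 0.1 * steady_rms(epoch.signal)

    def test_10hz_preserved(self, t_vec):
        epoch = make_epoch(np.sin(2 * np.pi * 10 * t_vec))
        out = notch_filter(epoch)
        assert abs(steady_rms(out.signal) / steady_rms(epoch.signal) - 1) < 0.1

    def test_zero_in_zero_out(self):
        epoch = make_epoch(np.zeros((3, 3072)))
        assert np.allclose(notch_filter(epoch).signal, 0.0)

    def test_notch_above_nyquist_rejected(self, t_vec):
        epoch = make_epoch(np.sin(t_vec))
        with pytest.raises(FilterSpecError):
            notch_filter(epoch, FilterSpec(notch_freq=200.0))


class TestBandpass:
    def test_dc_removed(self):
        epoch = make_epoch(np.full(3072, 5.0))
        out = bandpass_filter(epoch)
        assert steady_rms(out.signal) < 0.05 * 5.0

    def test_45hz_attenuated(self, t_vec):
        epoch = make_epoch(np.sin(2 * np.pi * 45 * t_vec))
        out = bandpass_filter(epoch)
        assert steady_rms(out.signal) <= 0.1 * steady_rms(epoch.signal)

    def test_10hz_preserved(self, t_vec):
        epoch = make_epoch(np.sin(2 * np.pi * 10 * t_vec))
        out = bandpass_filter(epoch)
        assert abs(steady_rms(out.signal) / steady_rms(epoch.signal) - 1) < 0.1

    def test_linearity(self, rng):
        x = make_epoch(rng.standard_normal((2, 3072)))
        y = make_epoch(rng.standard_normal((2, 3072)))
        combo = make_epoch(2.0 * x.signal - 3.0 * y.signal)
        lhs = bandpass_filter(combo).signal
        rhs = 2.0 * bandpass_filter(x).signal - 3.0 * bandpass_filter(y).signal
        assert np.allclose(lhs, rhs, rtol=1e-8, atol=1e-8)


class TestRejectTrials:
    def make_session(self, rng, n=21, scale=10.0):
        return [make_epoch(rng.standard_normal((4, 3072)) * scale, trial_id=f"t{i}")
                for i in range(n)]

    def test_amplitude_spike_rejected(self, rng):
        session = self.make_session(rng, scale=10.0)
        spiked = session[3].signal.copy()
        spiked[0, 100] = 200.0
        session[3] = replace(session[3], signal=spiked)
        report = reject_trials(session)
        assert ("t3", "amplitude") in report.rejected
        assert "t3" not in report.kept_ids

    def test_identical_clean_trials_kept(self):
        sig = np.sin(np.arange(3072) / 10.0)[None, :] * 20.0
        session = [make_epoch(sig, trial_id=f"t{i}") for i in range(5)]
        report = reject_trials(session)
        assert report.rejected == []
        assert len(report.kept_ids) == 5

    def test_heavy_tailed_trial_rejected_for_kurtosis(self, rng):
        # z-score oracle: the heavy-tailed trial's kurtosis z must exceed 3
        # across the session for the named reason to be recorded.
        session = self.make_session(rng, n=21, scale=5.0)
        # Sparse ±4-SD spikes: large fourth moment, near-normal histogram.
        heavy = rng.standard_normal((4, 3072)) * 5.0
        for ch in range(4):
            pos = rng.choice(3072, 60, replace=False)
            heavy[ch, pos] = rng.choice([-1.0, 1.0], 60) * 20.0
        session[7] = replace(session[7], signal=heavy)
        kurts = np.array([np.mean(stats.kurtosis(ep.signal, axis=1))
                          for ep in session])
        z = (kurts - kurts.mean()) / kurts.std(ddof=1)
        assert z[7] > 3  # oracle precondition
        report = reject_trials(session)
        assert ("t7", "kurtosis") in report.rejected

    def test_empty_session_rejected(self):
        with pytest.raises(EmptySessionError):
            reject_trials([])

    def test_permutation_equivariance(self, rng):
        session = self.make_session(rng, n=12, scale=10.0)
        spiked = session[2].signal.copy()
        spiked[0, 0] = 400.0
        session[2] = replace(session[2], signal=spiked)
        report = reject_trials(session)
        shuffled = session[::-1]
        report_shuffled = reject_trials(shuffled)
        assert set(report.kept_ids) == set(report_shuffled.kept_ids)
        assert set(report.rejected) == set(report_shuffled.rejected)


class TestPCA:
    def test_rank_one_data(self, rng):
        base = rng.standard_normal(3072)
        epoch = make_epoch(np.tile(base, (6, 1)))
        model, reduced = pca_fit_project([epoch], threshold=0.95)
        assert model.retained_count == 1
        assert reduced[0].signal.shape[0] == 1

    def test_matches_eigendecomposition_oracle(self, rng):
        # Construct channels with known covariance spectrum (9, 1, ~0).
        n = 20000
        latents = np.vstack([rng.standard_normal(n) * 3.0,
                             rng.standard_normal(n) * 1.0])
        mix = np.vstack([np.eye(2), np.zeros((2, 2))])  # 4 channels, rank 2
        epoch = make_epoch(mix @ latents)
        model, _ = pca_fit_project([epoch], threshold=0.85)
        # Brute-force oracle on the sample covariance.
        cov = np.cov(epoch.signal)
        eig = np.sort(np.linalg.eigvalsh(cov))[::-1]
        cum = np.cumsum(eig) / eig.sum()
        expected = int(np.searchsorted(cum, 0.85 - 1e-12) + 1)
        assert model.retained_count == expected == 1

    def test_threshold_one_keeps_all(self, rng):
        epoch = make_epoch(rng.standard_normal((5, 4096)))
        model, _ = pca_fit_project([epoch], threshold=1.0)
        assert model.retained_count == 5

    def test_bad_threshold_rejected(self, rng):
        epoch = make_epoch(rng.standard_normal((3, 128)))
        with pytest.raises(ValueError):
            pca_fit_project([epoch], threshold=1.5)

    def test_retained_variance_preserved(self, rng):
        epoch = make_epoch(rng.standard_normal((6, 8192)) * [[1], [2], [3], [4], [5], [6]])
        model, reduced = pca_fit_project([epoch], threshold=0.9)
        data = reduced[0].signal
        var = np.sum(data.var(axis=1, ddof=1))
        retained = model.eigenvalues[: model.retained_count].sum()
        assert np.isclose(var, retained, rtol=1e-6)


class TestICA:
    def test_online_mode_refused(self, rng):
        epoch = make_epoch(rng.standard_normal((3, 1024)))
        with pytest.raises(OfflineOnlyError):
            ica_clean([epoch], template=np.zeros(1024), online=True)

    def test_no_flag_means_passthrough(self, rng):
        epoch = make_epoch(rng.standard_normal((4, 4096)))
        template = np.sin(np.arange(4096))  # uncorrelated with noise
        cleaned, model = ica_clean([epoch], template=template, seed=0)
        assert not model.component_flags.any()
        assert np.allclose(cleaned[0].signal, epoch.signal, atol=1e-6)

    def test_blink_component_removed(self, rng):
        n = 4096
        template = np.zeros(n)
        for onset in range(200, n - 200, 700):
            template[onset: onset + 100] = np.hanning(100)
        sources = rng.standard_normal((3, n))
        mixing = rng.standard_normal((4, 3))
        blink_topo = np.array([3.0, 2.5, 0.1, 0.0])
        data = mixing @ sources + blink_topo[:, None] * template[None, :] * 5.0
        epoch = make_epoch(data)
        cleaned, model = ica_clean([epoch], template=template, seed=0)
        assert model.component_flags.any()
        corr = np.corrcoef(cleaned[0].signal[0], template)[0, 1]
        assert abs(corr) < 0.2

    def test_mixing_unmixing_consistency(self, rng):
        epoch = make_epoch(rng.standard_normal((4, 4096)))
        _, model = ica_clean([epoch], template=np.sin(np.arange(4096)), seed=0)
        ident = model.unmixing @ model.mixing
        assert np.allclose(ident, np.eye(ident.shape[0]), atol=1e-6)


class TestSurfaceLaplacian:
    def test_uniform_signal_nulled(self):
        sig = np.tile(np.sin(np.arange(512) / 7.0), (4, 1))
        epoch = TrialEpoch(signal=sig, sampling_rate=256.0, mi_class="SOG",
                           feedback_class="KEEP", period_bounds=PERIOD_LAYOUT,
                           trial_id="t", seed=0,
                           channel_labels=("a", "b", "c", "d"))
        neighbors = {"a": ("b", "c"), "b": ("a", "c"), "c": ("a", "b"),
                     "d": ("a", "b", "c")}
        out = surface_laplacian(epoch, neighbors)
        assert np.allclose(out.signal, 0.0, atol=1e-12)

    def test_focal_source_sharpened(self, rng):
        labels = ("C3", "C5", "C1", "FC3", "CP3")
        sig = np.zeros((5, 512))
        sig[0] = np.sin(np.arange(512) / 5.0)
        epoch = TrialEpoch(signal=sig, sampling_rate=256.0, mi_class="SOG",
                           feedback_class="KEEP", period_bounds=PERIOD_LAYOUT,
                           trial_id="t", seed=0, channel_labels=labels)
        neighbors = {"C3": ("C5", "C1", "FC3", "CP3"),
                     "C5": ("C3",), "C1": ("C3",), "FC3": ("C3",),
                     "CP3": ("C3",)}
        out = surface_laplacian(epoch, neighbors)
        assert np.max(np.abs(out.signal[0])) > 0.5 * np.max(np.abs(sig[0]))
        # Neighbors acquire the sign-flipped focal signal.
        assert np.allclose(out.signal[1], -sig[0])

    def test_direct_arithmetic_oracle(self, rng):
        labels = ("C3", "C5", "C1", "FC3", "CP3")
        sig = rng.standard_normal((5, 512))
        epoch = TrialEpoch(signal=sig, sampling_rate=256.0, mi_class="SOG",
                           feedback_class="KEEP", period_bounds=PERIOD_LAYOUT,
                           trial_id="t", seed=0, channel_labels=labels)
        neighbors = {"C3": ("C5", "C1", "FC3", "CP3")}
        out = surface_laplacian(epoch, neighbors)
        expected = sig[0] - sig[1:].mean(axis=0)
        assert np.allclose(out.signal[0], expected)
        # Channels without neighbor sets pass through unchanged.
        assert np.array_equal(out.signal[1], sig[1])

    def test_default_montage_covers_all_channels(self):
        from smrfes.montage import CHANNELS_32

        for ch in CHANNELS_32:
            assert DEFAULT_NEIGHBORS[ch], ch
            for nb in DEFAULT_NEIGHBORS[ch]:
                assert nb in CHANNELS_32


def test_entropy_increases_with_spread(rng):
    narrow = np.zeros(1000)
    narrow[::2] = 1.0
    wide = rng.standard_normal(1000)
    assert trial_entropy(wide) > trial_entropy(narrow)
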