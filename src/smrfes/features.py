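"""Sub-band decomposition, ERD/ERS band power, and sub-band CSP features.

The 1-29 Hz range is split into seven contiguous 4-Hz bands.  Band power
uses a Hamming-windowed periodogram on 2.5-s (640-sample at 256 Hz)
segments.  ERD/ERS is the relative band-power change of an activity
segment versus a reference segment.  Per band, a common-spatial-pattern
projection is fitted from trace-normalized class covariances; the
retained filters yield log-variance features whose per-band classifier
scores are fused by a weighted sum.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal as sps

from smrfes.preprocess import bandpass_taps
from smrfes.synthetic import TrialEpoch

SUB_BANDS: tuple[tuple[float, float], ...] = (
    (1.0, 5.0), (5.0, 9.0), (9.0, 13.0), (13.0, 17.0),
    (17.0, 21.0), (21.0, 25.0), (25.0, 29.0),
)

N_BANDS = len(SUB_BANDS)
DEFAULT_SEGMENT_SAMPLES = 640  # 2.5 s at 256 Hz


class DegenerateEpochError(ValueError):
    """Raised when an epoch has zero variance under projection."""


@dataclass(frozen=True)
class SubBandSet:
    bands: tuple[tuple[float, float], ...] = SUB_BANDS

    def __post_init__(self) -> None:
        if len(self.bands) != 7:
            raise ValueError("expected exactly 7 sub-bands")
        for (lo, hi), (lo2, _) in zip(self.bands, self.bands[1:]):
            if hi != lo2:
                raise ValueError("sub-bands must be contiguous")
            if hi - lo != 4.0:
                raise ValueError("sub-bands must be 4 Hz wide")


@dataclass(frozen=True)
class ERDSMap:
    """Percent band-power change per (channel, band); negative = ERD."""

    values: np.ndarray  # (n_channels, n_bands)
    reference_power: np.ndarray
    activity_power: np.ndarray


@dataclass(frozen=True)
class BandCSP:
    """CSP decomposition for one sub-band."""

    cov_class1: np.ndarray  # trace-normalized, trial-averaged
    cov_class2: np.ndarray
    eigenvalues: np.ndarray  # class-1 generalized eigenvalues, descending
    projection: np.ndarray  # full W, rows = spatial filters
    selected: np.ndarray  # row indices of retained filters


@dataclass(frozen=True)
class CSPModel:
    bands: tuple[tuple[float, float], ...]
    per_band: tuple[BandCSP, ...]
    selected_pairs: int
    n_channels: int


def zero_phase_fir(data: np.ndarray, taps: np.ndarray) -> np.ndarray:
    """Single-pass zero-phase FIR: centered linear convolution.

    Odd-length linear-phase taps make centering exact; the operation is
    linear in the taps, so contiguous band designs sum telescopically.
    """
    if len(taps) % 2 == 0:
        raise ValueError("taps length must be odd for exact centering")
    return sps.fftconvolve(np.atleast_2d(data), taps[None, :], mode="same",
                           axes=1)


def subband_decompose(epoch: TrialEpoch,
                      bands: SubBandSet | None = None,
                      numtaps: int | None = None) -> list[TrialEpoch]:
    """Split an epoch into the seven 4-Hz band-limited epochs.

    Filters are unscaled Hamming FIR sharing one tap count, applied as a
    centered single pass, so the sum of the outputs equals the full
    1-29 Hz band-passed input exactly (the designs telescope).
    """
    bands = bands or SubBandSet()
    fs = epoch.sampling_rate
    if fs <= 2 * max(hi for _, hi in bands.bands):
        raise ValueError("sampling rate too low for the highest band edge")
    if numtaps is None:
        numtaps = min(769, epoch.signal.shape[1] // 3 * 2 + 1)
        if numtaps % 2 == 0:
            numtaps += 1
    out = []
    for band in bands.bands:
        taps = bandpass_taps(fs, band, numtaps)
        out.append(replace(epoch, signal=zero_phase_fir(epoch.signal, taps)))
    return out


def band_power(segment: np.ndarray, fs: float,
               bands: SubBandSet | None = None,
               n_points: int = DEFAULT_SEGMENT_SAMPLES) -> np.ndarray:
    """Hamming-windowed periodogram power per (channel, band), µV².

    Consumes exactly ``n_points`` samples from the start of ``segment``.
    """
    bands = bands or SubBandSet()
    segment = np.atleast_2d(segment)
    if segment.shape[1] < n_points:
        raise ValueError(
            f"segment has {segment.shape[1]} samples; {n_points} required"
        )
    data = segment[:, :n_points]
    freqs, psd = sps.periodogram(data, fs=fs, window="hamming", axis=1,
                                 detrend=False, scaling="density")
    df = freqs[1] - freqs[0]
    out = np.empty((data.shape[0], len(bands.bands)))
    for j, (lo, hi) in enumerate(bands.bands):
        mask = (freqs >= lo) & (freqs < hi)
        out[:, j] = psd[:, mask].sum(axis=1) * df
    return out


def total_power(segment: np.ndarray, fs: float,
                n_points: int = DEFAULT_SEGMENT_SAMPLES) -> np.ndarray:
    """Window-corrected total periodogram power (Parseval check helper)."""
    segment = np.atleast_2d(segment)
    if segment.shape[1] < n_points:
        raise ValueError("segment shorter than n_points")
    data = segment[:, :n_points]
    freqs, psd = sps.periodogram(data, fs=fs, window="hamming", axis=1,
                                 detrend=False, scaling="density")
    return psd.sum(axis=1) * (freqs[1] - freqs[0])


def erds(reference_power: np.ndarray | float,
         activity_power: np.ndarray | float) -> np.ndarray | float:
    """Relative band-power change (A - R) / R x 100 (percent)."""
    R = np.asarray(reference_power, dtype=float)
    A = np.asarray(activity_power, dtype=float)
    if np.any(R <= 0):
        raise ValueError("reference power must be strictly positive")
    out = (A - R) / R * 100.0
    return float(out) if out.ndim == 0 else out


def erds_map(epoch: TrialEpoch, bands: SubBandSet | None = None,
             reference_period: str = "reference",
             activity_period: str = "mi") -> ERDSMap:
    """ERD/ERS map of one trial: activity vs reference band power."""
    bands = bands or SubBandSet()
    R = band_power(epoch.period_signal(reference_period), epoch.sampling_rate,
                   bands)
    A = band_power(epoch.period_signal(activity_period), epoch.sampling_rate,
                   bands)
    return ERDSMap(values=erds(R, A), reference_power=R, activity_power=A)


def _normalized_cov(trial: np.ndarray) -> np.ndarray:
    c = trial @ trial.T
    tr = np.trace(c)
    if tr <= 0:
        raise DegenerateEpochError("trial has zero total variance")
    return c / tr


def _csp_single_band(trials_c1: list[np.ndarray], trials_c2: list[np.ndarray],
                     selected_pairs: int) -> BandCSP:
    c1 = np.mean([_normalized_cov(x) for x in trials_c1], axis=0)
    c2 = np.mean([_normalized_cov(x) for x in trials_c2], axis=0)
    cc = c1 + c2
    # Whitening from the composite covariance's eigendecomposition,
    # regularized if rank-deficient.
    evals, evecs = np.linalg.eigh(cc)
    if evals.min() < 1e-10 * evals.max():
        cc = cc + 1e-8 * np.trace(cc) * np.eye(cc.shape[0])
        evals, evecs = np.linalg.eigh(cc)
    whitener = np.diag(evals**-0.5) @ evecs.T
    s1 = whitener @ c1 @ whitener.T
    lam, b = np.linalg.eigh(s1)
    order = np.argsort(lam)[::-1]  # descending class-1 eigenvalue
    lam, b = lam[order], b[:, order]
    w = b.T @ whitener
    n = w.shape[0]
    selected = np.array(
        sorted(set(range(selected_pairs)) | set(range(n - selected_pairs, n)))
    )
    return BandCSP(cov_class1=c1, cov_class2=c2, eigenvalues=lam,
                   projection=w, selected=selected)


def csp_fit(trials_class1: list[np.ndarray], trials_class2: list[np.ndarray],
            selected_pairs: int = 1) -> BandCSP:
    """Fit a CSP projection from raw (channels x samples) trials.

    Class covariances are trace-normalized per trial, then averaged.
    Filters are ordered by descending class-1 generalized eigenvalue;
    the first and last ``selected_pairs`` filters are retained.
    """
    if len(trials_class1) < 2 or len(trials_class2) < 2:
        raise ValueError("need at least 2 trials per class")
    if trials_class1[0].shape[0] < 2:
        raise ValueError("need at least 2 channels")
    return _csp_single_band(trials_class1, trials_class2, selected_pairs)


def csp_features(model: BandCSP, epoch: np.ndarray) -> np.ndarray:
    """Log-variance of the retained CSP-projected signals."""
    w_sel = model.projection[model.selected]
    if epoch.shape[0] != w_sel.shape[1]:
        raise ValueError("channel count mismatch with fitted model")
    projected = w_sel @ epoch
    variances = projected.var(axis=1)
    if np.any(variances <= 0):
        raise DegenerateEpochError("zero variance under CSP projection")
    return np.log(variances)


def sbcsp_fit(band_trials_c1: list[list[np.ndarray]],
              band_trials_c2: list[list[np.ndarray]],
              selected_pairs: int = 1) -> CSPModel:
    """Fit one CSP model per sub-band (inputs indexed [band][trial])."""
    per_band = tuple(
        _csp_single_band(c1, c2, selected_pairs)
        for c1, c2 in zip(band_trials_c1, band_trials_c2)
    )
    return CSPModel(bands=SUB_BANDS, per_band=per_band,
                    selected_pairs=selected_pairs,
                    n_channels=band_trials_c1[0][0].shape[0])


def sbcsp_features(model: CSPModel, band_epochs: list[np.ndarray]) -> np.ndarray:
    """Concatenated per-band CSP log-variance features (length 2*pairs*7)."""
    return np.concatenate([
        csp_features(bm, ep) for bm, ep in zip(model.per_band, band_epochs)
    ])


def sbcsp_fuse(band_scores: np.ndarray, weights: np.ndarray) -> float:
    """Weighted sum of per-band classifier scores; sign decides the class.

    An exact zero fuses to the first class by convention (handled by
    downstream sign mapping, which treats 0 as non-negative).
    """
    band_scores = np.asarray(band_scores, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if band_scores.shape != weights.shape:
        raise ValueError("scores and weights must have matching length")
    if np.any(weights < 0) or not np.isclose(weights.sum(), 1.0):
        raise ValueError("weights must be nonnegative and sum to 1")
    return float(np.dot(weights, band_scores))


def fusion_weights_from_accuracies(accuracies: np.ndarray,
                                   temperature: float = 10.0) -> np.ndarray:
    """Softmax of per-band cross-validated accuracies."""
    a = np.asarray(accuracies, dtype=float) * temperature
    e = np.exp(a - a.max())
    return e / e.sum()
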