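"""Preprocessing chain: notch, trial rejection, band-pass, PCA, ICA, Laplacian.

All filters are zero-phase (forward-backward) so that period boundaries
keep their latencies.  Trial rejection mirrors automatic artifact
screening: an absolute amplitude ceiling plus z-scored entropy and
kurtosis statistics across the session.  ICA cleaning is an offline-only
operation; the surface Laplacian is the discrete small-Laplacian
(channel minus neighbor mean).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal as sps
from scipy import stats

from smrfes.synthetic import TrialEpoch


class FilterSpecError(ValueError):
    """Invalid filter configuration (edges vs Nyquist)."""


class EmptySessionError(ValueError):
    """Raised when an operation receives no trials."""


class OfflineOnlyError(RuntimeError):
    """Raised when an offline-only step is requested in online mode."""


@dataclass(frozen=True)
class FilterSpec:
    notch_freq: float = 60.0
    bandpass: tuple[float, float] = (1.0, 29.0)
    filter_family: str = "FIR"  # for the band-pass; notch is always IIR
    notch_q: float = 30.0
    order: int | None = None  # taps; default 3 * fs / low_edge

    def validate(self, fs: float) -> None:
        low, high = self.bandpass
        if not 0 < low < high < fs / 2:
            raise FilterSpecError(
                f"band edges {self.bandpass} must satisfy 0 < low < high < Nyquist"
            )
        if self.notch_freq >= fs / 2:
            raise FilterSpecError("notch frequency must be below Nyquist")


@dataclass(frozen=True)
class RejectionReport:
    kept_ids: list[str]
    rejected: list[tuple[str, str]]  # (trial_id, reason)
    thresholds: tuple[float, float]  # (amplitude µV, z)

    @property
    def rejected_ids(self) -> list[str]:
        return [tid for tid, _ in self.rejected]


@dataclass(frozen=True)
class PCAModel:
    component_basis: np.ndarray  # (n_channels, n_components), orthonormal columns
    explained_variance_ratio: np.ndarray
    retained_count: int
    threshold: float
    eigenvalues: np.ndarray


@dataclass(frozen=True)
class ICAModel:
    unmixing: np.ndarray
    mixing: np.ndarray
    component_flags: np.ndarray  # True = artifact
    criterion_scores: np.ndarray


def _filter_epoch(epoch: TrialEpoch, b: np.ndarray, a: np.ndarray) -> TrialEpoch:
    padlen = min(3 * (max(len(b), len(a)) - 1), epoch.signal.shape[1] - 1)
    filtered = sps.filtfilt(b, a, epoch.signal, axis=1, padlen=padlen)
    return replace(epoch, signal=filtered)


def notch_filter(epoch: TrialEpoch, spec: FilterSpec | None = None) -> TrialEpoch:
    """Zero-phase IIR notch (Q-factor spec.notch_q) at spec.notch_freq."""
    spec = spec or FilterSpec()
    spec.validate(epoch.sampling_rate)
    b, a = sps.iirnotch(spec.notch_freq, spec.notch_q, fs=epoch.sampling_rate)
    return _filter_epoch(epoch, b, a)


def bandpass_taps(fs: float, band: tuple[float, float],
                  numtaps: int | None = None) -> np.ndarray:
    """Hamming-windowed FIR band-pass taps (unscaled, odd length)."""
    if numtaps is None:
        numtaps = int(round(3 * fs / band[0]))
    if numtaps % 2 == 0:
        numtaps += 1
    return sps.firwin(numtaps, band, pass_zero=False, window="hamming",
                      fs=fs, scale=False)


def bandpass_filter(epoch: TrialEpoch, spec: FilterSpec | None = None) -> TrialEpoch:
    """Zero-phase FIR band-pass over spec.bandpass."""
    spec = spec or FilterSpec()
    spec.validate(epoch.sampling_rate)
    b = bandpass_taps(epoch.sampling_rate, spec.bandpass, spec.order)
    return _filter_epoch(epoch, b, np.ones(1))


def trial_entropy(x: np.ndarray, bins: int = 20) -> float:
    """Shannon entropy (nats) of the pooled amplitude histogram."""
    hist, _ = np.histogram(x.ravel(), bins=bins)
    p = hist / hist.sum()
    p = p[p > 0]
    return float(-np.sum(p * np.log(p)))


def reject_trials(session: list[TrialEpoch], amplitude_limit: float = 150.0,
                  z_limit: float = 3.0) -> RejectionReport:
    """Screen trials on amplitude, entropy and kurtosis statistics.

    Amplitude is an absolute per-sample ceiling; entropy and kurtosis
    are z-scored across the session and rejected beyond ``z_limit``
    standard deviations.  Reasons are recorded with priority
    amplitude > entropy > kurtosis.
    """
    if not session:
        raise EmptySessionError("cannot screen an empty session")
    ent = np.array([trial_entropy(ep.signal) for ep in session])
    kur = np.array([float(np.mean(stats.kurtosis(ep.signal, axis=1)))
                    for ep in session])

    def zscores(v: np.ndarray) -> np.ndarray:
        sd = v.std(ddof=1) if len(v) > 1 else 0.0
        return np.zeros_like(v) if sd == 0 else (v - v.mean()) / sd

    ent_z, kur_z = zscores(ent), zscores(kur)
    kept, rejected = [], []
    for i, ep in enumerate(session):
        if np.max(np.abs(ep.signal)) > amplitude_limit:
            rejected.append((ep.trial_id, "amplitude"))
        elif abs(ent_z[i]) > z_limit:
            rejected.append((ep.trial_id, "entropy"))
        elif abs(kur_z[i]) > z_limit:
            rejected.append((ep.trial_id, "kurtosis"))
        else:
            kept.append(ep.trial_id)
    return RejectionReport(kept_ids=kept, rejected=rejected,
                           thresholds=(amplitude_limit, z_limit))


def pca_fit_project(epochs: list[TrialEpoch],
                    threshold: float = 0.95) -> tuple[PCAModel, list[TrialEpoch]]:
    """Channel-space PCA over concatenated epochs; keep components up to
    the smallest count whose cumulative explained variance meets
    ``threshold``."""
    if not 0 < threshold <= 1:
        raise ValueError("threshold must lie in (0, 1]")
    if not epochs:
        raise EmptySessionError("no epochs to fit")
    data = np.concatenate([ep.signal for ep in epochs], axis=1)
    if data.shape[0] < 2 or data.shape[1] < 2:
        raise ValueError("need at least 2 channels and 2 samples")
    centered = data - data.mean(axis=1, keepdims=True)
    cov = centered @ centered.T / (centered.shape[1] - 1)
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    eigvals = np.clip(eigvals, 0, None)
    ratio = eigvals / eigvals.sum() if eigvals.sum() > 0 else eigvals
    cumulative = np.cumsum(ratio)
    retained = int(np.searchsorted(cumulative, threshold - 1e-12) + 1)
    retained = min(retained, len(eigvals))
    basis = eigvecs[:, :retained]
    model = PCAModel(component_basis=basis, explained_variance_ratio=ratio,
                     retained_count=retained, threshold=threshold,
                     eigenvalues=eigvals)
    reduced = [replace(ep, signal=basis.T @ ep.signal,
                       channel_labels=tuple(f"PC{i + 1}" for i in range(retained)))
               for ep in epochs]
    return model, reduced


def ica_clean(epochs: list[TrialEpoch], template: np.ndarray,
              corr_threshold: float = 0.7, online: bool = False,
              seed: int = 0) -> tuple[list[TrialEpoch], ICAModel]:
    """Remove independent components correlated with an artifact template.

    Offline only: the online pipeline skips ICA.  Components whose time
    course has absolute Pearson correlation with ``template`` above
    ``corr_threshold`` are zeroed before reconstruction.
    """
    if online:
        raise OfflineOnlyError("ICA cleaning is an offline-only operation")
    if not epochs:
        raise EmptySessionError("no epochs to clean")
    from sklearn.decomposition import FastICA

    data = np.concatenate([ep.signal for ep in epochs], axis=1)
    n_comp = data.shape[0]
    if n_comp < 2:
        model = ICAModel(unmixing=np.eye(n_comp), mixing=np.eye(n_comp),
                         component_flags=np.zeros(n_comp, bool),
                         criterion_scores=np.zeros(n_comp))
        return list(epochs), model

    ica = FastICA(n_components=n_comp, whiten="unit-variance",
                  random_state=seed, max_iter=1000, tol=1e-6)
    sources = ica.fit_transform(data.T).T  # (components, samples)
    tiled = np.tile(template, int(np.ceil(data.shape[1] / template.size)))
    tiled = tiled[: data.shape[1]]
    scores = np.array([
        abs(float(np.corrcoef(src, tiled)[0, 1])) if src.std() > 0 else 0.0
        for src in sources
    ])
    flags = scores > corr_threshold
    mixing = ica.mixing_
    unmixing = np.linalg.pinv(mixing)
    cleaned_epochs = []
    offset = 0
    mean = ica.mean_[:, None]
    for ep in epochs:
        n = ep.signal.shape[1]
        src = sources[:, offset: offset + n].copy()
        src[flags] = 0.0
        cleaned = mixing @ src + mean
        cleaned_epochs.append(replace(ep, signal=cleaned))
        offset += n
    model = ICAModel(unmixing=unmixing, mixing=mixing,
                     component_flags=flags, criterion_scores=scores)
    return cleaned_epochs, model


def surface_laplacian(epoch: TrialEpoch, neighbors: dict[str, tuple[str, ...]],
                      segment: tuple[float, float] | None = None) -> TrialEpoch:
    """Discrete small-Laplacian: each channel minus the mean of its neighbors.

    When ``segment`` (seconds) is given, only that span is re-referenced;
    channels without recorded neighbors pass through unchanged.
    """
    labels = epoch.channel_labels
    index = {lab: i for i, lab in enumerate(labels)}
    sig = epoch.signal
    if segment is None:
        sl = slice(0, sig.shape[1])
    else:
        fs = epoch.sampling_rate
        sl = slice(int(round(segment[0] * fs)), int(round(segment[1] * fs)))
    out = sig.copy()
    for lab, i in index.items():
        nbrs = [index[n] for n in neighbors.get(lab, ()) if n in index]
        if not nbrs:
            continue
        out[i, sl] = sig[i, sl] - sig[nbrs, sl].mean(axis=0)
    return replace(epoch, signal=out)
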