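"""Reproducible synthetic EEG sessions with motor-imagery structure.

Trials follow a 12-s layout: rest (2.5 s), reference (2.5 s), motor
imagery (3 s), stimulation ramp-up (1 s), and feedback (3 s).  Two
imagery classes are modeled — slow one-time grasping (SOG, modulated at
1/3 Hz) and fast cyclic opening (FCO, at 1 Hz).  The signal model is
1/f-shaped background noise plus band-limited mu/beta oscillators over
sensorimotor channels; imagery attenuates the oscillator envelope
(multiplicative ERD) with amplitude modulation at the class rhythm.
Ocular artifacts and a stimulation pulse train contaminate frontal
channels and the feedback period respectively.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from smrfes.montage import CHANNELS_32, channel_index

MI_CLASSES = ("SOG", "FCO")
FEEDBACK_CLASSES = ("KEEP", "STOP")

#: (name, start_s, stop_s) of the five half-open trial periods.
PERIOD_LAYOUT: tuple[tuple[str, float, float], ...] = (
    ("rest", 0.0, 2.5),
    ("reference", 2.5, 5.0),
    ("mi", 5.0, 8.0),
    ("fes_init", 8.0, 9.0),
    ("feedback", 9.0, 12.0),
)

TRIAL_DURATION_S = 12.0


class UnknownClassError(ValueError):
    """Raised for a class label outside the known enums."""


class InvalidParamsError(ValueError):
    """Raised when simulation parameters violate their invariants."""


def _default_erd_depth() -> dict[str, dict[str, float]]:
    # Distinct spatial ERD profiles make the two classes separable for
    # variance-based spatial filters: SOG is centro-parietal dominant,
    # FCO fronto-central dominant.
    return {
        "SOG": {"C3": 0.60, "CP3": 0.50, "CP5": 0.30, "FC3": 0.15, "C5": 0.15},
        "FCO": {"C3": 0.25, "CP3": 0.15, "CP5": 0.10, "FC3": 0.55, "C5": 0.45},
    }


def _default_rhythm_weights() -> dict[str, float]:
    return {
        "C3": 1.0, "CP3": 0.8, "FC3": 0.7, "C5": 0.7, "CP5": 0.5,
        "FC1": 0.4, "Cz": 0.3, "CPz": 0.3, "C4": 0.25, "CP4": 0.2, "FC2": 0.2,
    }


@dataclass(frozen=True)
class SimulationParams:
    """Knobs of the synthetic EEG generator (amplitudes in microvolts)."""

    sampling_rate: float = 256.0
    n_channels: int = 32
    channel_labels: tuple[str, ...] = CHANNELS_32
    background_exponent: float = 1.0
    mu_band: tuple[float, float] = (8.0, 12.0)
    beta_band: tuple[float, float] = (18.0, 26.0)
    rhythm_amplitude: float = 8.0
    rhythm_weights: dict[str, float] = field(default_factory=_default_rhythm_weights)
    erd_depth: dict[str, dict[str, float]] = field(default_factory=_default_erd_depth)
    modulation_rate: dict[str, float] = field(
        default_factory=lambda: {"SOG": 1.0 / 3.0, "FCO": 1.0}
    )
    blink_rate: float = 10.0  # events / minute
    blink_amplitude: float = 60.0
    fes_artifact_amplitude: float = 80.0  # default 10x rhythm amplitude
    fes_pulse_rate: float = 25.0
    noise_sd: float = 3.0

    def validate(self) -> None:
        if self.sampling_rate <= 0:
            raise InvalidParamsError("sampling_rate must be positive")
        if len(self.channel_labels) != self.n_channels:
            raise InvalidParamsError("channel_labels length must equal n_channels")
        if len(set(self.channel_labels)) != self.n_channels:
            raise InvalidParamsError("channel_labels contains duplicates")
        for band in (self.mu_band, self.beta_band):
            if not (1.0 <= band[0] < band[1] <= 29.0):
                raise InvalidParamsError(f"band {band} must lie inside 1-29 Hz")
        for cls, depths in self.erd_depth.items():
            if cls not in MI_CLASSES:
                raise UnknownClassError(f"unknown MI class {cls!r}")
            for ch, d in depths.items():
                if not 0.0 <= d <= 1.0:
                    raise InvalidParamsError(
                        f"erd_depth[{cls}][{ch}]={d} outside [0, 1]"
                    )


@dataclass(frozen=True)
class TrialEpoch:
    """One annotated 12-s multichannel trial (channels x samples, µV)."""

    signal: np.ndarray
    sampling_rate: float
    mi_class: str
    feedback_class: str
    period_bounds: tuple[tuple[str, float, float], ...]
    trial_id: str
    seed: int
    channel_labels: tuple[str, ...] = CHANNELS_32

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    def period_slice(self, name: str) -> slice:
        """Sample slice of a named period."""
        for pname, start, stop in self.period_bounds:
            if pname == name:
                return slice(
                    int(round(start * self.sampling_rate)),
                    int(round(stop * self.sampling_rate)),
                )
        raise KeyError(f"unknown period {name!r}")

    def period_signal(self, name: str) -> np.ndarray:
        return self.signal[:, self.period_slice(name)]


@dataclass(frozen=True)
class VirtualSubject:
    """Probabilistic stand-in for a decoding pipeline (plumbing for FSM tests)."""

    p_smr_detect: float = 0.8
    p_act_correct: float = 0.75
    p_fes_correct: float = 0.7
    drift_magnitude: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_smr_detect", "p_act_correct", "p_fes_correct"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise InvalidParamsError(f"{name}={p} outside [0, 1]")


def _pink_noise(rng: np.random.Generator, n_channels: int, n_samples: int,
                fs: float, exponent: float, sd: float) -> np.ndarray:
    """1/f^exponent-shaped Gaussian noise, scaled to RMS `sd` per channel."""
    white = rng.standard_normal((n_channels, n_samples))
    spec = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    shape = np.ones_like(freqs)
    nz = freqs > 0
    shape[nz] = freqs[nz] ** (-exponent / 2.0)
    shape[0] = 0.0  # no DC
    out = np.fft.irfft(spec * shape, n=n_samples, axis=1)
    rms = np.sqrt(np.mean(out**2, axis=1, keepdims=True))
    rms[rms == 0] = 1.0
    return out / rms * sd


def _narrowband(rng: np.random.Generator, n_samples: int, fs: float,
                band: tuple[float, float]) -> np.ndarray:
    """Unit-RMS band-limited Gaussian oscillation (FFT brick-wall)."""
    white = rng.standard_normal(n_samples)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    mask = (freqs >= band[0]) & (freqs <= band[1])
    spec[~mask] = 0.0
    out = np.fft.irfft(spec, n=n_samples)
    rms = np.sqrt(np.mean(out**2))
    return out / (rms if rms > 0 else 1.0)


def _blink_template(fs: float) -> np.ndarray:
    """Stereotyped biphasic ocular deflection, ~400 ms, unit peak."""
    t = np.arange(int(0.4 * fs)) / fs
    tpl = np.sin(2 * np.pi * t / 0.4) * np.exp(-t / 0.15)
    return tpl / np.max(np.abs(tpl))


def simulate_trial(mi_class: str, feedback_class: str,
                   params: SimulationParams | None = None,
                   seed: int = 0) -> TrialEpoch:
    """Generate one 12-s trial; bit-identical for identical (inputs, seed)."""
    params = params or SimulationParams()
    params.validate()
    if mi_class not in MI_CLASSES:
        raise UnknownClassError(f"unknown MI class {mi_class!r}")
    if feedback_class not in FEEDBACK_CLASSES:
        raise UnknownClassError(f"unknown feedback class {feedback_class!r}")

    fs = params.sampling_rate
    n_samples = int(round(TRIAL_DURATION_S * fs))
    n_ch = params.n_channels
    rng = np.random.default_rng(seed)
    idx = channel_index(params.channel_labels)
    t = np.arange(n_samples) / fs

    signal = _pink_noise(rng, n_ch, n_samples, fs,
                         params.background_exponent, params.noise_sd)

    # MI-period ERD envelope: attenuation oscillating at the class rhythm.
    mi_start, mi_stop = 5.0, 8.0
    in_mi = (t >= mi_start) & (t < mi_stop)
    f_mod = params.modulation_rate[mi_class]
    modulation = 0.5 * (1.0 - np.cos(2 * np.pi * f_mod * (t - mi_start)))
    depths = params.erd_depth.get(mi_class, {})

    for band in (params.mu_band, params.beta_band):
        carrier = _narrowband(rng, n_samples, fs, band)
        for ch, weight in params.rhythm_weights.items():
            if ch not in idx:
                continue
            depth = depths.get(ch, 0.0)
            envelope = np.ones(n_samples)
            envelope[in_mi] = 1.0 - depth * modulation[in_mi]
            signal[idx[ch]] += params.rhythm_amplitude * weight * carrier * envelope

    # Ocular artifacts: Poisson blink times on frontal channels.
    tpl = _blink_template(fs)
    n_blinks = rng.poisson(params.blink_rate * TRIAL_DURATION_S / 60.0)
    onsets = np.sort(rng.uniform(0, TRIAL_DURATION_S - 0.5, size=n_blinks))
    frontal_weights = {"AFz": 1.0, "Fz": 0.8, "F3": 0.6, "F4": 0.6,
                       "F7": 0.4, "F8": 0.4}
    for onset in onsets:
        s0 = int(onset * fs)
        seg = slice(s0, s0 + tpl.size)
        for ch, w in frontal_weights.items():
            if ch in idx:
                signal[idx[ch], seg] += params.blink_amplitude * w * tpl[: signal.shape[1] - s0]

    # Electrical stimulation artifact during feedback when FES stays on.
    if feedback_class == "KEEP" and params.fes_artifact_amplitude > 0:
        fb = (t >= 9.0) & (t < 12.0)
        phase = np.floor((t - 9.0) * params.fes_pulse_rate)
        pulse = ((t - 9.0) * params.fes_pulse_rate - phase) < 0.15
        train = np.where(fb & pulse, 1.0, 0.0) - np.where(fb, 0.15, 0.0)
        artifact_weights = rng.uniform(0.3, 1.0, size=n_ch)
        signal += params.fes_artifact_amplitude * artifact_weights[:, None] * train[None, :]

    return TrialEpoch(
        signal=signal,
        sampling_rate=fs,
        mi_class=mi_class,
        feedback_class=feedback_class,
        period_bounds=PERIOD_LAYOUT,
        trial_id=f"trial-{seed}",
        seed=seed,
        channel_labels=tuple(params.channel_labels),
    )


def generate_session(n_trials: int, params: SimulationParams | None = None,
                     seed: int = 0) -> list[TrialEpoch]:
    """Balanced, seed-shuffled session of `n_trials` epochs.

    Class counts are exactly n_trials/2 each; feedback labels are
    balanced within each MI class; trial ids are unique.
    """
    if n_trials % 2 != 0:
        raise ValueError("n_trials must be even for balanced classes")
    params = params or SimulationParams()
    params.validate()
    rng = np.random.default_rng(seed)
    classes = np.array(["SOG"] * (n_trials // 2) + ["FCO"] * (n_trials // 2))
    rng.shuffle(classes)
    feedback: list[str] = []
    counters = {"SOG": 0, "FCO": 0}
    for cls in classes:
        feedback.append(FEEDBACK_CLASSES[counters[cls] % 2])
        counters[cls] += 1
    child_seeds = rng.integers(0, 2**31 - 1, size=n_trials)
    epochs = []
    for i, (cls, fb, s) in enumerate(zip(classes, feedback, child_seeds)):
        epoch = simulate_trial(cls, fb, params, seed=int(s))
        epochs.append(replace(epoch, trial_id=f"trial-{i:03d}"))
    return epochs


_ROLE_PROB_ATTR = {"SMR": "p_smr_detect", "ACT": "p_act_correct",
                   "FES": "p_fes_correct"}

#: Binary label pairs per decision role: (positive, negative).
ROLE_LABELS = {"SMR": ("SMR", "NOSMR"), "ACT": ("SOG", "FCO"),
               "FES": ("KEEP", "STOP")}


def decision_feature(subject: VirtualSubject, role: str, truth: str,
                     rng: np.random.Generator,
                     drift_offset: float = 0.0) -> float:
    """Scalar decision feature whose sign encodes the role's binary label.

    Calibrated so that a zero-bias threshold reproduces the subject's
    per-role correctness probability; `drift_offset` shifts the feature
    to emulate session non-stationarity.
    """
    if role not in _ROLE_PROB_ATTR:
        raise ValueError(f"unknown role {role!r}")
    pos, neg = ROLE_LABELS[role]
    if truth not in (pos, neg):
        raise UnknownClassError(f"truth {truth!r} invalid for role {role}")
    p = getattr(subject, _ROLE_PROB_ATTR[role])
    sign = 1.0 if truth == pos else -1.0
    if p in (0.0, 1.0):
        # Degenerate probabilities: noise-free feature for exactness.
        m = 4.0 if p == 1.0 else -4.0
        return sign * m + drift_offset
    m = stats.norm.ppf(p)
    return sign * m + drift_offset + float(rng.standard_normal())


def sample_decision(subject: VirtualSubject, role: str, truth: str,
                    rng: np.random.Generator,
                    drift_offset: float = 0.0) -> str:
    """Predicted label: equals `truth` with the role's probability."""
    x = decision_feature(subject, role, truth, rng, drift_offset)
    pos, neg = ROLE_LABELS[role]
    predicted = pos if x > 0 else neg
    return predicted
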