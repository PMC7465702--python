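"""Session I/O and pipeline glue: EDF+ bundles, configs, model JSON,
trial-log JSONL, offline training, and the model-backed online source."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from smrfes import features as feat
from smrfes import fsm, metrics, preprocess
from smrfes.classify import (
    EnsembleModel,
    KernelClassifier,
    LinearClassifier,
    ensemble_fit,
)
from smrfes.edfplus import EdfAnnotation, EdfFile, read_edf, write_edf
from smrfes.montage import CHANNELS_32, DEFAULT_NEIGHBORS
from smrfes.synthetic import SimulationParams, TrialEpoch, generate_session

SEGMENT_SECONDS = 2.5
ROLE_SEGMENTS = {"SMR": ("mi", "reference"), "ACT": ("mi", "mi"),
                 "FES": ("feedback", "feedback")}


class SessionFormatError(ValueError):
    """Malformed session file; message locates the first error."""


@dataclass
class SessionBundle:
    epochs: list[TrialEpoch]
    channel_labels: tuple[str, ...] = CHANNELS_32
    neighbors: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(DEFAULT_NEIGHBORS))
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for ep in self.epochs:
            if tuple(ep.channel_labels) != tuple(self.channel_labels):
                raise SessionFormatError(
                    f"epoch {ep.trial_id} channel ordering differs from bundle"
                )


def write_session(bundle: SessionBundle, path) -> None:
    """Write a bundle as EDF+C with trial/period/class annotations."""
    if not bundle.epochs:
        raise SessionFormatError("bundle holds no epochs")
    fs = bundle.epochs[0].sampling_rate
    signal = np.concatenate([ep.signal for ep in bundle.epochs], axis=1)
    annotations = []
    trial_len = bundle.epochs[0].signal.shape[1] / fs
    for i, ep in enumerate(bundle.epochs):
        t0 = i * trial_len
        annotations.append(EdfAnnotation(
            onset=t0, duration=trial_len,
            text=(f"trial {ep.trial_id} mi={ep.mi_class} "
                  f"fb={ep.feedback_class} seed={ep.seed}")))
        for name, start, stop in ep.period_bounds:
            annotations.append(EdfAnnotation(
                onset=t0 + start, duration=stop - start,
                text=f"period {name}"))
    seed = bundle.metadata.get("seed", "")
    edf = EdfFile(signals=signal, sampling_rate=fs,
                  labels=list(bundle.channel_labels),
                  annotations=annotations,
                  recording_id=f"Startdate 01-JAN-2000 smrfes seed={seed}")
    write_edf(path, edf)


def read_session(path) -> SessionBundle:
    """Read an EDF+ session written by :func:`write_session`."""
    try:
        edf = read_edf(path)
    except Exception as exc:
        raise SessionFormatError(str(exc)) from exc
    fs = edf.sampling_rate
    trial_anns = [a for a in edf.annotations if a.text.startswith("trial ")]
    if not trial_anns:
        raise SessionFormatError("no trial annotations found in file")
    period_anns = [a for a in edf.annotations if a.text.startswith("period ")]
    epochs = []
    for ann in sorted(trial_anns, key=lambda a: a.onset):
        tokens = dict(
            tok.split("=") for tok in ann.text.split()[2:] if "=" in tok)
        trial_id = ann.text.split()[1]
        s0 = int(round(ann.onset * fs))
        s1 = int(round((ann.onset + (ann.duration or 12.0)) * fs))
        bounds = []
        for p in period_anns:
            if ann.onset - 1e-6 <= p.onset < ann.onset + (ann.duration or 12.0):
                name = p.text.split()[1]
                start = p.onset - ann.onset
                bounds.append((name, round(start, 6),
                               round(start + (p.duration or 0.0), 6)))
        if not bounds:
            raise SessionFormatError(
                f"trial {trial_id}: no period annotations at onset {ann.onset}")
        epochs.append(TrialEpoch(
            signal=edf.signals[:, s0:s1], sampling_rate=fs,
            mi_class=tokens.get("mi", "SOG"),
            feedback_class=tokens.get("fb", "KEEP"),
            period_bounds=tuple(bounds), trial_id=trial_id,
            seed=int(tokens.get("seed", 0)),
            channel_labels=tuple(edf.labels)))
    labels = tuple(edf.labels)
    neighbors = {ch: DEFAULT_NEIGHBORS.get(ch, ()) for ch in labels}
    return SessionBundle(epochs=epochs, channel_labels=labels,
                         neighbors=neighbors, metadata={"path": str(path)})


# --- configuration -------------------------------------------------------

def load_params(path) -> SimulationParams:
    """SimulationParams from a YAML or JSON mapping (missing keys default)."""
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    if "channel_labels" in data:
        data["channel_labels"] = tuple(data["channel_labels"])
    for key in ("mu_band", "beta_band"):
        if key in data:
            data[key] = tuple(data[key])
    params = SimulationParams(**data)
    params.validate()
    return params


def rejection_report_to_csv(report: preprocess.RejectionReport, path) -> None:
    lines = ["trial_id,status,reason,amplitude_limit,z_limit"]
    amp, z = report.thresholds
    for tid in report.kept_ids:
        lines.append(f"{tid},kept,,{amp},{z}")
    for tid, reason in report.rejected:
        lines.append(f"{tid},rejected,{reason},{amp},{z}")
    Path(path).write_text("\n".join(lines) + "\n")


# --- offline training ----------------------------------------------------

def _segment(epoch: TrialEpoch, period: str, fs: float) -> np.ndarray:
    n = int(round(SEGMENT_SECONDS * fs))
    return epoch.period_signal(period)[:, :n]


def _band_segments(segment: np.ndarray, fs: float) -> list[np.ndarray]:
    n = segment.shape[1]
    numtaps = min(193, n if n % 2 else n - 1)
    if numtaps % 2 == 0:
        numtaps -= 1
    return [feat.zero_phase_fir(segment, preprocess.bandpass_taps(fs, band, numtaps))
            for band in feat.SUB_BANDS]


@dataclass
class RoleModel:
    csp: feat.CSPModel
    ensemble: EnsembleModel


def train_models(bundle: SessionBundle, seed: int = 0,
                 selected_pairs: int = 1,
                 preprocessed: bool = False) -> dict[str, RoleModel]:
    """Fit per-role sub-band CSP + ensemble models from a session.

    Roles: SMR (imagery vs reference detection), ACT (class vs class
    during imagery), FES (keep vs stop during feedback).
    """
    epochs = bundle.epochs
    if not preprocessed:
        spec = preprocess.FilterSpec()
        epochs = [preprocess.bandpass_filter(preprocess.notch_filter(ep, spec),
                                             spec) for ep in epochs]
    fs = epochs[0].sampling_rate
    models: dict[str, RoleModel] = {}

    def fit_role(pos_segs, neg_segs, class_labels):
        pos_banded = [_band_segments(s, fs) for s in pos_segs]
        neg_banded = [_band_segments(s, fs) for s in neg_segs]
        bands_pos = [[trial[b] for trial in pos_banded] for b in range(feat.N_BANDS)]
        bands_neg = [[trial[b] for trial in neg_banded] for b in range(feat.N_BANDS)]
        csp = feat.sbcsp_fit(bands_pos, bands_neg, selected_pairs)
        X = np.vstack([feat.sbcsp_features(csp, trial)
                       for trial in pos_banded + neg_banded])
        y = np.array([class_labels[0]] * len(pos_banded)
                     + [class_labels[1]] * len(neg_banded))
        ens = ensemble_fit(X, y, seed=seed, class_labels=class_labels)
        return RoleModel(csp=csp, ensemble=ens)

    # SMR: imagery segments (both classes) vs reference segments.
    mi_segs = [_segment(ep, "mi", fs) for ep in epochs]
    ref_segs = [_segment(ep, "reference", fs) for ep in epochs]
    models["SMR"] = fit_role(mi_segs, ref_segs, ("SMR", "NOSMR"))

    # ACT: SOG vs FCO imagery segments.
    sog = [_segment(ep, "mi", fs) for ep in epochs if ep.mi_class == "SOG"]
    fco = [_segment(ep, "mi", fs) for ep in epochs if ep.mi_class == "FCO"]
    models["ACT"] = fit_role(sog, fco, ("SOG", "FCO"))

    # FES: keep vs stop feedback segments.
    keep = [_segment(ep, "feedback", fs) for ep in epochs
            if ep.feedback_class == "KEEP"]
    stop = [_segment(ep, "feedback", fs) for ep in epochs
            if ep.feedback_class == "STOP"]
    models["FES"] = fit_role(keep, stop, ("KEEP", "STOP"))
    return models


# --- model (de)serialization --------------------------------------------

def _csp_to_dict(model: feat.CSPModel) -> dict:
    return {
        "bands": [list(b) for b in model.bands],
        "selected_pairs": model.selected_pairs,
        "n_channels": model.n_channels,
        "per_band": [
            {
                "cov_class1": bm.cov_class1.tolist(),
                "cov_class2": bm.cov_class2.tolist(),
                "eigenvalues": bm.eigenvalues.tolist(),
                "projection": bm.projection.tolist(),
                "selected": bm.selected.tolist(),
            }
            for bm in model.per_band
        ],
    }


def _csp_from_dict(d: dict) -> feat.CSPModel:
    per_band = tuple(
        feat.BandCSP(
            cov_class1=np.array(b["cov_class1"]),
            cov_class2=np.array(b["cov_class2"]),
            eigenvalues=np.array(b["eigenvalues"]),
            projection=np.array(b["projection"]),
            selected=np.array(b["selected"], dtype=int),
        )
        for b in d["per_band"]
    )
    return feat.CSPModel(bands=tuple(tuple(b) for b in d["bands"]),
                         per_band=per_band,
                         selected_pairs=d["selected_pairs"],
                         n_channels=d["n_channels"])


def _ensemble_to_dict(model: EnsembleModel) -> dict:
    return {
        "class_labels": list(model.class_labels),
        "voting_weights": list(model.voting_weights),
        "lda": {"weights": model.lda.weights.tolist(), "bias": model.lda.bias},
        "svm": {
            "support": model.svm.support.tolist(),
            "dual_coef": model.svm.dual_coef.tolist(),
            "bias": model.svm.bias,
            "gamma": model.svm.gamma,
        },
    }


def _ensemble_from_dict(d: dict) -> EnsembleModel:
    labels = tuple(d["class_labels"])
    lda = LinearClassifier(weights=np.array(d["lda"]["weights"]),
                           bias=d["lda"]["bias"], class_labels=labels)
    svm = KernelClassifier(support=np.array(d["svm"]["support"]),
                           dual_coef=np.array(d["svm"]["dual_coef"]),
                           bias=d["svm"]["bias"], class_labels=labels,
                           gamma=d["svm"]["gamma"])
    return EnsembleModel(lda=lda, svm=svm,
                         voting_weights=tuple(d["voting_weights"]),
                         class_labels=labels)


def save_models(models: dict[str, RoleModel], path, seed: int = 0) -> None:
    payload = {"seed": seed, "roles": {
        role: {"csp": _csp_to_dict(rm.csp),
               "ensemble": _ensemble_to_dict(rm.ensemble)}
        for role, rm in models.items()
    }}
    Path(path).write_text(json.dumps(payload))


def load_models(path) -> dict[str, RoleModel]:
    payload = json.loads(Path(path).read_text())
    return {role: RoleModel(csp=_csp_from_dict(d["csp"]),
                            ensemble=_ensemble_from_dict(d["ensemble"]))
            for role, d in payload["roles"].items()}


# --- online decoding source ---------------------------------------------

class ModelBackedSource:
    """Decision source that decodes synthesized EEG windows with trained
    models.

    Each decision synthesizes a fresh 2.5-s window whose class matches
    the supplied truth label, extracts sub-band CSP features, and scores
    the role's ensemble.  The LDA member is exposed via ``classifiers``
    so pooled-mean adaptation can recenter its bias online.
    """

    def __init__(self, models: dict[str, RoleModel],
                 params: SimulationParams | None = None,
                 rng: np.random.Generator | None = None):
        self.models = models
        self.params = params or SimulationParams()
        self.rng = rng or np.random.default_rng(0)
        self.classifiers = {role: rm.ensemble.lda for role, rm in models.items()}

    def _window(self, role: str, truth: str) -> np.ndarray:
        from smrfes.synthetic import simulate_trial

        seed = int(self.rng.integers(0, 2**31 - 1))
        if role == "SMR":
            mi = ["SOG", "FCO"][int(self.rng.integers(2))]
            period = "mi" if truth == "SMR" else "reference"
            trial = simulate_trial(mi, "STOP", self.params, seed)
        elif role == "ACT":
            period = "mi"
            trial = simulate_trial(truth, "STOP", self.params, seed)
        else:  # FES
            period = "feedback"
            mi = ["SOG", "FCO"][int(self.rng.integers(2))]
            trial = simulate_trial(mi, truth, self.params, seed)
        fs = trial.sampling_rate
        spec = preprocess.FilterSpec()
        filtered = preprocess.bandpass_filter(
            preprocess.notch_filter(trial, spec), spec)
        return _segment(filtered, period, fs)

    def decide(self, role: str, truth: str) -> tuple[str, np.ndarray]:
        rm = self.models[role]
        seg = self._window(role, truth)
        banded = _band_segments(seg, self.params.sampling_rate)
        x = feat.sbcsp_features(rm.csp, banded)
        ens = rm.ensemble
        ens.lda = self.classifiers[role]
        predicted = str(ens.predict(x))
        return predicted, x

    def advance_trial(self) -> None:  # no feature drift in the generator
        pass


# --- trial logs and reports ---------------------------------------------

def write_trial_logs(logs: list[fsm.TrialLog], path) -> None:
    """One JSON object per decision event (JSON-lines)."""
    lines = []
    for log in logs:
        for ev in log.events:
            lines.append(json.dumps({
                "trial_id": log.trial_id, "adapted": log.adapted,
                "time": ev.time, "role": ev.role, "step": ev.step,
                "predicted": ev.predicted, "truth": ev.truth,
                "outcome": ev.outcome,
            }))
        for so in log.step_outcomes:
            lines.append(json.dumps({
                "trial_id": log.trial_id, "adapted": log.adapted,
                "step_outcome": so.step, "triggered_by": so.triggered_by,
                "latency": so.latency, "hold_successes": so.hold_successes,
            }))
    Path(path).write_text("\n".join(lines) + "\n")


def read_trial_logs(path) -> list[fsm.TrialLog]:
    logs: dict[str, fsm.TrialLog] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        d = json.loads(line)
        log = logs.setdefault(
            d["trial_id"], fsm.TrialLog(trial_id=d["trial_id"],
                                        adapted=d.get("adapted", False)))
        if "step_outcome" in d:
            log.step_outcomes.append(fsm.StepOutcome(
                step=d["step_outcome"], triggered_by=d["triggered_by"],
                latency=d["latency"], hold_successes=d["hold_successes"]))
        else:
            log.events.append(fsm.DecisionEvent(
                time=d["time"], role=d["role"], predicted=d["predicted"],
                truth=d["truth"], outcome=d["outcome"], step=d.get("step", "")))
    return list(logs.values())


def run_pipeline(outdir, seed: int = 0, n_trials: int = 12,
                 n_online_trials: int = 6,
                 params: SimulationParams | None = None) -> dict:
    """Deterministic end-to-end run: simulate, preprocess, train,
    run-online, report.  Returns the metrics bundle and writes all
    artifacts under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    params = params or SimulationParams()
    epochs = generate_session(n_trials, params, seed)
    bundle = SessionBundle(epochs=epochs,
                           channel_labels=tuple(params.channel_labels),
                           metadata={"seed": seed})
    write_session(bundle, outdir / "session.edf")
    report = preprocess.reject_trials(epochs)
    rejection_report_to_csv(report, outdir / "rejection.csv")
    kept = [ep for ep in epochs if ep.trial_id in set(report.kept_ids)]
    if len({ep.mi_class for ep in kept}) < 2:
        kept = epochs  # degenerate rejection: train on everything
    models = train_models(replace_bundle_epochs(bundle, kept), seed=seed)
    save_models(models, outdir / "models.json", seed=seed)
    source = ModelBackedSource(models, params, np.random.default_rng(seed + 1))
    config = fsm.FSMConfig(n_trials=n_online_trials)
    logs = fsm.run_session(source, config, seed=seed + 2,
                           start_after=n_online_trials // 2)
    write_trial_logs(logs, outdir / "trial_logs.jsonl")
    bundle_metrics = metrics.session_metrics(logs, config)
    payload = {"seed": seed, "n_trials": n_trials,
               "n_online_trials": n_online_trials, "metrics": bundle_metrics}
    (outdir / "metrics.json").write_text(json.dumps(payload, sort_keys=True,
                                                    indent=2))
    return payload


def replace_bundle_epochs(bundle: SessionBundle,
                          epochs: list[TrialEpoch]) -> SessionBundle:
    return SessionBundle(epochs=epochs, channel_labels=bundle.channel_labels,
                         neighbors=bundle.neighbors, metadata=bundle.metadata)
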