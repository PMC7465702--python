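"""Semi-asynchronous fixed-sequence control loop.

One trial walks a fixed step sequence: OPEN (BCI-triggered stimulation),
STOP_FES (BCI-stopped stimulation), a break, a non-BCI move, GRAB
(BCI-triggered), a non-BCI ball move, and HOLD (repeated keep
decisions).  Decisions run at a 1-s cadence; detection gates a
role switch from SMR to ACT within the same window, and a 6-s maximum
analysis time auto-triggers any step so every trial terminates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from smrfes.adaptive import (
    DEFAULT_ETA,
    DEFAULT_START_AFTER,
    PMeanState,
    adaptation_schedule,
    pmean_init,
    pmean_update,
)
from smrfes.classify import LinearClassifier
from smrfes.synthetic import ROLE_LABELS, VirtualSubject, decision_feature

#: step name -> (kind, role truth/target)
STEP_SPECS: dict[str, tuple[str, str | None]] = {
    "OPEN": ("trigger", "FCO"),
    "STOP_FES": ("stop", "STOP"),
    "BREAK": ("pause", None),
    "MOVE": ("pause", None),
    "GRAB": ("trigger", "SOG"),
    "MOVE_BALL": ("pause", None),
    "HOLD": ("hold", "KEEP"),
}

DEFAULT_SEQUENCE = ("OPEN", "STOP_FES", "BREAK", "MOVE", "GRAB",
                    "MOVE_BALL", "HOLD")

BCI_STEP_KINDS = ("trigger", "stop", "hold")


class RoleMismatchError(ValueError):
    """Decision role inconsistent with the machine's current role."""


@dataclass(frozen=True)
class FSMConfig:
    max_analysis_time: float = 6.0
    fes_duration: float = 5.0
    break_duration: float = 10.0
    decision_interval: float = 1.0
    move_window: float = 5.0
    n_trials: int = 20
    sequence: tuple[str, ...] = DEFAULT_SEQUENCE
    hold_required: int | None = None  # default: max windows (6)

    def __post_init__(self) -> None:
        for d in (self.max_analysis_time, self.fes_duration,
                  self.break_duration, self.decision_interval,
                  self.move_window):
            if d <= 0:
                raise ValueError("all durations must be positive")
        ratio = self.max_analysis_time / self.decision_interval
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValueError(
                "max_analysis_time must be a multiple of decision_interval"
            )
        unknown = set(self.sequence) - set(STEP_SPECS)
        if unknown:
            raise ValueError(f"unknown steps in sequence: {sorted(unknown)}")

    @property
    def max_windows(self) -> int:
        return int(round(self.max_analysis_time / self.decision_interval))

    @property
    def hold_windows(self) -> int:
        return self.hold_required if self.hold_required is not None else self.max_windows


@dataclass(frozen=True)
class DecisionEvent:
    time: float
    role: str  # SMR | ACT | FES
    predicted: str
    truth: str
    outcome: str  # correct | error | delay
    step: str = ""  # owning sequence step, when known


@dataclass(frozen=True)
class StepOutcome:
    step: str
    triggered_by: str  # bci | timeout | none (non-BCI steps)
    latency: float
    hold_successes: int = 0


@dataclass
class TrialLog:
    trial_id: str
    events: list[DecisionEvent] = field(default_factory=list)
    step_outcomes: list[StepOutcome] = field(default_factory=list)
    adapted: bool = False


@dataclass
class TrialState:
    """Mutable per-trial machine state (one BCI step at a time)."""

    config: FSMConfig
    step: str
    role: str  # current decision role
    window: int = 0  # windows consumed in this step
    fes_on: bool = False
    finished: bool = False
    triggered_by: str = ""
    latency: float = 0.0
    hold_successes: int = 0
    events: list[DecisionEvent] = field(default_factory=list)

    @property
    def kind(self) -> str:
        return STEP_SPECS[self.step][0]

    @property
    def target(self) -> str | None:
        return STEP_SPECS[self.step][1]


def start_step(step: str, config: FSMConfig) -> TrialState:
    kind = STEP_SPECS[step][0]
    role = {"trigger": "SMR", "stop": "FES", "hold": "FES"}.get(kind, "")
    return TrialState(config=config, step=step, role=role)


def fsm_step(state: TrialState, decision: DecisionEvent,
             config: FSMConfig | None = None) -> TrialState:
    """Advance the machine by one decision; mutates and returns ``state``."""
    config = config or state.config
    if state.finished or state.kind == "pause":
        raise RoleMismatchError(f"step {state.step} accepts no decisions")
    if decision.role != state.role:
        raise RoleMismatchError(
            f"decision role {decision.role} != machine role {state.role}"
        )
    state.events.append(decision)
    interval = config.decision_interval

    def advance_window() -> None:
        state.window += 1
        if state.kind == "hold":
            if state.window >= config.hold_windows:
                state.finished = True
                state.triggered_by = "timeout"
                state.latency = config.max_analysis_time
                state.fes_on = False  # auto-stop for safety
        elif state.window >= config.max_windows:
            state.finished = True
            state.triggered_by = "timeout"
            state.latency = config.max_analysis_time
            state.fes_on = state.kind == "trigger"

    if state.kind == "trigger":
        if state.role == "SMR":
            if decision.predicted == "SMR":
                state.role = "ACT"  # same window, same signal, new role
            else:
                advance_window()
        else:  # ACT
            if decision.predicted == state.target:
                state.finished = True
                state.triggered_by = "bci"
                state.latency = state.window * interval
                state.fes_on = True
            else:
                state.role = "SMR"
                advance_window()
    elif state.kind == "stop":
        if decision.predicted == "STOP":
            state.finished = True
            state.triggered_by = "bci"
            state.latency = state.window * interval
            state.fes_on = False
        else:
            advance_window()
    else:  # hold
        if decision.predicted == "KEEP":
            state.hold_successes += 1
        advance_window()
    return state


class VirtualSubjectSource:
    """Decision source backed by a probabilistic virtual subject.

    Each role has a one-dimensional feature model and a unit-weight
    linear classifier whose bias pooled-mean adaptation may recenter.
    Feature drift accumulates once per trial.
    """

    def __init__(self, subject: VirtualSubject, rng: np.random.Generator):
        self.subject = subject
        self.rng = rng
        self.drift_offset = 0.0
        self.classifiers: dict[str, LinearClassifier] = {
            role: LinearClassifier(weights=np.ones(1), bias=0.0,
                                   class_labels=labels)
            for role, labels in ROLE_LABELS.items()
        }

    def decide(self, role: str, truth: str) -> tuple[str, np.ndarray]:
        x = np.array([decision_feature(self.subject, role, truth, self.rng,
                                       self.drift_offset)])
        predicted = str(self.classifiers[role].predict(x))
        return predicted, x

    def advance_trial(self) -> None:
        self.drift_offset += self.subject.drift_magnitude


def run_trial(source, config: FSMConfig | None = None,
              trial_id: str = "trial-000",
              adapt_states: dict[str, PMeanState] | None = None,
              start_time: float = 0.0) -> TrialLog:
    """Execute one full step sequence and return its time-ordered log.

    ``adapt_states`` maps role -> PMeanState; when given (and the source
    exposes per-role classifiers), every decision window applies one
    unsupervised bias update.  The mapping is updated in place.
    """
    config = config or FSMConfig()
    log = TrialLog(trial_id=trial_id, adapted=adapt_states is not None)
    t = start_time
    for step in config.sequence:
        kind = STEP_SPECS[step][0]
        if kind == "pause":
            duration = (config.break_duration if step == "BREAK"
                        else config.move_window)
            log.step_outcomes.append(
                StepOutcome(step=step, triggered_by="none", latency=duration))
            t += duration
            continue
        state = start_step(step, config)
        while not state.finished:
            role = state.role
            truth = "SMR" if role == "SMR" else state.target
            predicted, feature = source.decide(role, truth)
            if predicted == truth:
                outcome = "correct"
            elif role == "SMR":
                outcome = "delay"
            else:
                outcome = "error"
            event = DecisionEvent(time=t + state.window * config.decision_interval,
                                  role=role, predicted=predicted, truth=truth,
                                  outcome=outcome, step=step)
            fsm_step(state, event, config)
            if adapt_states is not None and hasattr(source, "classifiers"):
                new_state, adapted_clf = pmean_update(
                    adapt_states[role], feature, source.classifiers[role])
                adapt_states[role] = new_state
                source.classifiers[role] = adapted_clf
        log.events.extend(state.events)
        log.step_outcomes.append(
            StepOutcome(step=step, triggered_by=state.triggered_by,
                        latency=state.latency,
                        hold_successes=state.hold_successes))
        t += state.latency + (config.fes_duration if kind == "trigger" else 0.0)
    return log


def run_session(subject_or_source, config: FSMConfig | None = None,
                seed: int = 0, adapt: bool = True,
                eta: float = DEFAULT_ETA,
                start_after: int = DEFAULT_START_AFTER) -> list[TrialLog]:
    """Run ``config.n_trials`` trials; adaptation starts after the warm-up.

    Trials at 1-based positions <= ``start_after`` use static models;
    later trials apply one pooled-mean update per decision window.
    """
    config = config or FSMConfig()
    if config.n_trials < 1:
        raise ValueError("n_trials must be at least 1")
    rng = np.random.default_rng(seed)
    if isinstance(subject_or_source, VirtualSubject):
        source = VirtualSubjectSource(subject_or_source, rng)
    else:
        source = subject_or_source
    adapt_states: dict[str, PMeanState] | None = None
    logs = []
    for i in range(1, config.n_trials + 1):
        active = adapt and adaptation_schedule(i, start_after)
        if active and adapt_states is None:
            dims = {role: np.shape(clf.weights)[0]
                    for role, clf in getattr(source, "classifiers", {}).items()}
            adapt_states = {role: pmean_init(dim, eta=eta)
                            for role, dim in dims.items()} or None
        log = run_trial(source, config, trial_id=f"trial-{i:03d}",
                        adapt_states=adapt_states if active else None)
        log.adapted = active
        logs.append(log)
        if hasattr(source, "advance_trial"):
            source.advance_trial()
    return logs
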