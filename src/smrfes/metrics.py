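"""Task metrics: completion rate, semi-asynchronous accuracy, information
transfer rate, sequential expected accuracy, t-ratio arithmetic, and
summary-table aggregation."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from smrfes.fsm import STEP_SPECS, FSMConfig, TrialLog

#: Step -> stimulation condition for accuracy pooling.
CONDITION_OF_STEP = {"OPEN": "No-FES", "GRAB": "No-FES",
                     "STOP_FES": "Yes-FES", "HOLD": "Yes-FES"}


def completion_rate(log: TrialLog, step: str,
                    config: FSMConfig | None = None) -> float:
    """Percent completion of one step of a trial.

    Trigger/stop steps map delay linearly: immediate success is 100 %,
    a timeout is 0 %.  The hold step scores the fraction of correct
    keep decisions out of the maximum window count.
    """
    config = config or FSMConfig()
    outcome = next((s for s in log.step_outcomes if s.step == step), None)
    if outcome is None or STEP_SPECS.get(step, ("pause",))[0] == "pause":
        raise KeyError(f"step {step!r} not a scored step of this log")
    if STEP_SPECS[step][0] == "hold":
        return outcome.hold_successes / config.hold_windows * 100.0
    if outcome.triggered_by == "timeout":
        return 0.0
    t_max = config.max_analysis_time
    return (t_max - outcome.latency) / t_max * 100.0


def semi_async_accuracy(logs: list[TrialLog],
                        include_delays: bool = False) -> dict[str, float | None]:
    """Accuracy (percent) per stimulation condition from decision events.

    Correct / (correct + error); detection misses during the SMR role
    count as delays and are excluded unless ``include_delays``.
    ``None`` marks a condition with an empty denominator.
    """
    if not logs:
        raise ValueError("no trial logs supplied")
    counts: dict[str, dict[str, int]] = {
        "No-FES": {"correct": 0, "error": 0, "delay": 0},
        "Yes-FES": {"correct": 0, "error": 0, "delay": 0},
    }
    for log in logs:
        # Map each event to its step via time ordering of step outcomes.
        step_events = _events_by_step(log)
        for step, events in step_events.items():
            condition = CONDITION_OF_STEP.get(step)
            if condition is None:
                continue
            for ev in events:
                counts[condition][ev.outcome] += 1
    out: dict[str, float | None] = {}
    for condition, c in counts.items():
        denom = c["correct"] + c["error"] + (c["delay"] if include_delays else 0)
        out[condition] = None if denom == 0 else c["correct"] / denom * 100.0
    return out


def _events_by_step(log: TrialLog) -> dict[str, list]:
    """Partition a log's events by owning BCI step, preserving order.

    Events produced by :func:`smrfes.fsm.run_trial` carry a step tag;
    untagged events (hand-built logs) are grouped by decision role.
    """
    out: dict[str, list] = {}
    role_to_step = {"SMR": "OPEN", "ACT": "OPEN", "FES": "STOP_FES"}
    for ev in log.events:
        step = ev.step or role_to_step.get(ev.role, "OPEN")
        out.setdefault(step, []).append(ev)
    return out


def itr(P: float, N: int = 2, decisions_per_min: float = 60.0) -> float:
    """Wolpaw information transfer rate in bits/minute."""
    if N < 2:
        raise ValueError("N must be at least 2")
    if not 0.0 <= P <= 1.0:
        raise ValueError("P must lie in [0, 1]")
    bits = np.log2(N)
    if P > 0:
        bits += P * np.log2(P)
    if P < 1:
        bits += (1 - P) * np.log2((1 - P) / (N - 1))
    return float(bits * decisions_per_min)


def sequential_expected_accuracy(
        stage_accuracies: list[float] | tuple[float, ...]
) -> tuple[float, float, float]:
    """(p_correct, p_idle, p_wrong) of a detect-then-classify cascade.

    p_correct multiplies all stage accuracies; p_idle is a first-stage
    miss; p_wrong is a first-stage hit followed by a downstream error.
    """
    if len(stage_accuracies) == 0:
        raise ValueError("at least one stage accuracy required")
    accs = [float(a) for a in stage_accuracies]
    for a in accs:
        if not 0.0 <= a <= 1.0:
            raise ValueError("stage accuracies must lie in [0, 1]")
    p_correct = float(np.prod(accs))
    p_idle = 1.0 - accs[0]
    p_wrong = accs[0] - p_correct
    return p_correct, p_idle, p_wrong


def t_from_summary(estimate: float, standard_error: float) -> float:
    """t-ratio from a summary pair: estimate / SE."""
    if standard_error <= 0:
        raise ValueError("standard error must be positive")
    return estimate / standard_error


def p_two_tailed(t: float, df: int) -> float:
    """Two-tailed p-value from the exact Student-t distribution."""
    return float(2.0 * stats.t.sf(abs(t), df))


@dataclass(frozen=True)
class SummaryTable:
    """Per-subject table with appended Average and SD rows."""

    table: pd.DataFrame

    @property
    def means(self) -> pd.Series:
        return self.table.loc["Average"]

    @property
    def sds(self) -> pd.Series:
        return self.table.loc["SD"]


def aggregate(values: pd.DataFrame | np.ndarray,
              columns: list[str] | None = None) -> SummaryTable:
    """Append column means and sample SDs to a per-subject table."""
    if isinstance(values, pd.DataFrame):
        df = values.copy()
    else:
        arr = np.atleast_2d(np.asarray(values, dtype=float))
        df = pd.DataFrame(arr, columns=columns)
    if df.shape[0] < 1:
        raise ValueError("at least one subject row required")
    if df.isna().any().any():
        raise ValueError("ragged table: missing entries")
    mean_row = df.mean(axis=0)
    sd_row = df.std(axis=0, ddof=1)  # NaN for a single row -> reported missing
    out = pd.concat([df, pd.DataFrame([mean_row, sd_row],
                                      index=["Average", "SD"])])
    return SummaryTable(table=out)


def session_metrics(logs: list[TrialLog],
                    config: FSMConfig | None = None) -> dict:
    """Bundle of completion rates, accuracies and ITR for one session,
    split by learning partition (before/after adaptation)."""
    config = config or FSMConfig()
    out: dict = {}
    for label, part in (("before", [l for l in logs if not l.adapted]),
                        ("after", [l for l in logs if l.adapted])):
        if not part:
            continue
        acc = semi_async_accuracy(part)
        rates = {}
        for step in ("OPEN", "STOP_FES", "GRAB", "HOLD"):
            vals = [completion_rate(log, step, config) for log in part
                    if any(s.step == step for s in log.step_outcomes)]
            rates[step] = float(np.mean(vals)) if vals else None
        n_dec = sum(len(l.events) for l in part)
        correct = sum(1 for l in part for e in l.events if e.outcome == "correct")
        errors = sum(1 for l in part for e in l.events if e.outcome == "error")
        denom = correct + errors
        p = correct / denom if denom else 0.5
        decisions_per_min = 60.0 / config.decision_interval
        out[label] = {
            "accuracy": acc,
            "completion_rate": rates,
            "itr_bits_per_min": itr(min(max(p, 0.0), 1.0), 2, decisions_per_min),
            "n_decisions": n_dec,
        }
    return out
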