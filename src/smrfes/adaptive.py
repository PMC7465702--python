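"""Pooled-mean (PMean) unsupervised bias adaptation.

The running feature mean is updated with an exponential coefficient and
the linear classifier's bias is recentered to the negated projection of
that mean.  Only the bias moves; the weight vector is untouched.
Adaptation starts after a warm-up block of trials.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from smrfes.classify import LinearClassifier

DEFAULT_ETA = 0.1
DEFAULT_START_AFTER = 10


@dataclass(frozen=True)
class PMeanState:
    """Running feature mean with its update coefficient and bias."""

    mu: np.ndarray
    eta: float = DEFAULT_ETA
    t: int = 0
    bias: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.eta <= 1.0:
            raise ValueError("eta must lie in [0, 1]")
        if self.t < 0:
            raise ValueError("t must be nonnegative")


def pmean_init(dim: int, eta: float = DEFAULT_ETA,
               bias: float = 0.0) -> PMeanState:
    return PMeanState(mu=np.zeros(dim), eta=eta, t=0, bias=bias)


def pmean_update(state: PMeanState, x: np.ndarray,
                 classifier: LinearClassifier
                 ) -> tuple[PMeanState, LinearClassifier]:
    """One unsupervised update: mu <- (1 - eta) mu + eta x; bias <- -w.mu."""
    x = np.atleast_1d(np.asarray(x, dtype=float))
    if x.shape != state.mu.shape:
        raise ValueError(
            f"feature dimension {x.shape} does not match state {state.mu.shape}"
        )
    if x.shape != np.shape(classifier.weights):
        raise ValueError("feature dimension does not match classifier weights")
    mu = (1.0 - state.eta) * state.mu + state.eta * x
    bias = -float(np.dot(classifier.weights, mu))
    new_state = PMeanState(mu=mu, eta=state.eta, t=state.t + 1, bias=bias)
    adapted = LinearClassifier(weights=classifier.weights, bias=bias,
                               class_labels=classifier.class_labels)
    return new_state, adapted


def adaptation_schedule(session_position: int,
                        start_after: int = DEFAULT_START_AFTER) -> bool:
    """True iff adaptation is active at this 1-based trial index."""
    if session_position < 1:
        raise ValueError("session_position is 1-based")
    return session_position > start_after
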