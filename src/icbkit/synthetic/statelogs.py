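"""Semi-Markov behavioural state-log generator.

Bout durations are exponential with a per-state mean; the next state
follows a row-stochastic transition matrix.  A transition back into the
same state extends the running bout (semi-Markov merging), so strictly
speaking ``bout_mean`` is the mean of a single exponential draw and the
realised bout mean matches it whenever the diagonal of the transition
matrix is zero.  The final bout of every window is truncated so the
events exactly tile the scoring span.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from ..states import SCORING_SPAN_S, StateEventLog


@dataclass
class StateLogParams:
    states: tuple[str, ...]
    bout_mean: dict[str, float] = field(default_factory=dict)
    transition_matrix: np.ndarray | None = None  # row-stochastic; default uniform off-diagonal
    window_length: float = SCORING_SPAN_S
    n_windows: int = 3
    seed: int = 0

    def validate(self) -> np.ndarray:
        if not self.states:
            raise ValueError("state list must not be empty")
        for s in self.states:
            m = self.bout_mean.get(s, None)
            if m is None or not math.isfinite(m) or m <= 0:
                raise ValueError(f"bout_mean must be positive for state {s!r}")
        k = len(self.states)
        if self.transition_matrix is None:
            if k == 1:
                T = np.ones((1, 1))
            else:
                T = np.full((k, k), 1.0 / (k - 1))
                np.fill_diagonal(T, 0.0)
        else:
            T = np.asarray(self.transition_matrix, dtype=float)
            if T.shape != (k, k):
                raise ValueError("transition matrix shape must match the state list")
            if np.any(T < 0) or np.any(np.abs(T.sum(axis=1) - 1.0) > 1e-9):
                raise ValueError("transition matrix rows must be stochastic")
        if self.window_length <= 0 or self.n_windows < 1:
            raise ValueError("window_length and n_windows must be positive")
        return T


def gen_state_log(params: StateLogParams) -> list[StateEventLog]:
    """One log per observation window; events tile the window."""
    T = params.validate()
    rng = np.random.default_rng(params.seed)
    k = len(params.states)
    logs = []
    for w in range(params.n_windows):
        events: list[tuple[str, float, float]] = []
        idx = int(rng.integers(k))
        t = 0.0
        while t < params.window_length - 1e-12:
            dur = rng.exponential(params.bout_mean[params.states[idx]])
            end = min(t + dur, params.window_length)
            if events and events[-1][0] == params.states[idx]:
                events[-1] = (events[-1][0], events[-1][1], end)
            else:
                events.append((params.states[idx], t, end))
            t = end
            idx = int(rng.choice(k, p=T[idx]))
        logs.append(
            StateEventLog(
                f"w{w}", events, params.window_length, meta={"seed": params.seed}
            )
        )
    return logs
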