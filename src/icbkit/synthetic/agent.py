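"""Delta-rule / softmax choice agent for the four-arm gambling maze.

Arm values update as Q <- Q + alpha * (r - Q) with the reward r in
pellet-equivalents (quinine encoded as a configurable negative value,
default -0.5); choices follow a softmax with inverse temperature beta.
With beta = 0 every arm is chosen with probability 1/4; with learning
enabled the advantageous-arm fraction rises above the 0.25 chance line
across blocks, qualitatively matching how untreated animals acquire
the task.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from ..rigt import (
    DeckOutcomes,
    RewardSchedule,
    TrialRecord,
    TRIALS_PER_SESSION,
    realize_outcome,
)

QUININE_VALUE = -0.5  # pellet-equivalents


@dataclass
class AgentParams:
    learning_rate: float = 0.2
    inverse_temperature: float = 3.0
    initial_values: dict[str, float] = field(default_factory=dict)
    n_trials: int = 120
    quinine_value: float = QUININE_VALUE
    seed: int = 0
    animal: str = "agent"

    def validate(self) -> None:
        if not 0.0 <= self.learning_rate <= 1.0:
            raise ValueError("learning_rate must lie in [0, 1]")
        if self.inverse_temperature < 0 or not math.isfinite(self.inverse_temperature):
            raise ValueError("inverse_temperature must be finite and >= 0")
        if self.n_trials < 1:
            raise ValueError("n_trials must be positive")


def _softmax(q: np.ndarray, beta: float) -> np.ndarray:
    z = beta * (q - q.max())
    e = np.exp(z)
    return e / e.sum()


def gen_choices(
    params: AgentParams,
    schedule: RewardSchedule | None = None,
    deck_mode: bool = False,
) -> list[TrialRecord]:
    """Simulate one animal's full trial sequence on the schedule."""
    params.validate()
    schedule = schedule or RewardSchedule.standard()
    arms = list(schedule.arms)
    if len(arms) < 2:
        raise ValueError("schedule must define at least two arms")
    rng = np.random.default_rng(params.seed)
    q = np.array([params.initial_values.get(a, 0.0) for a in arms], dtype=float)
    decks = DeckOutcomes(schedule, rng) if deck_mode else None
    records = []
    for i in range(params.n_trials):
        probs = _softmax(q, params.inverse_temperature)
        j = int(rng.choice(len(arms), p=probs))
        arm = arms[j]
        if decks is not None:
            pellets, quinine = decks.draw(arm)
        else:
            pellets, quinine = realize_outcome(schedule, arm, rng)
        reward = float(pellets) if pellets > 0 else (
            params.quinine_value if quinine else 0.0
        )
        q[j] += params.learning_rate * (reward - q[j])
        records.append(
            TrialRecord(
                animal=params.animal,
                session=i // TRIALS_PER_SESSION + 1,
                trial=i % TRIALS_PER_SESSION + 1,
                arm=arm,
                pellets=pellets,
                quinine=quinine,
            )
        )
    return records
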