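"""Rat Iowa Gambling Task: schedules, exclusions, and choice curves.

The maze offers four goal arms: one long-term advantageous arm (1
sugar pellet on 8 of 10 trials, a quinine pellet otherwise), one
disadvantageous arm (3 pellets on 1 of 10 trials, quinine otherwise),
and two empty arms controlling for unspecific exploration.  A complete
protocol is 120 trials over 10 daily sessions of 12 trials; data are
summarised per 12-trial block as the fraction of empty-arm and
advantageous-arm choices, against chance levels of 0.5 and 0.25.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

TRIALS_PER_SESSION = 12
N_SESSIONS = 10
TOTAL_TRIALS = TRIALS_PER_SESSION * N_SESSIONS

EXCLUSION_REASONS = (
    "none",
    "no_leave_start",
    "no_choice",
    "ate_quinine",
    "quinine_response",
)


@dataclass(frozen=True)
class ArmSchedule:
    role: str  # advantageous | disadvantageous | empty
    p_reward: float
    pellets_on_win: int
    quinine_otherwise: bool


@dataclass(frozen=True)
class RewardSchedule:
    arms: dict[str, ArmSchedule]

    @classmethod
    def standard(cls) -> "RewardSchedule":
        return cls(
            {
                "advantageous": ArmSchedule("advantageous", 0.8, 1, True),
                "disadvantageous": ArmSchedule("disadvantageous", 0.1, 3, True),
                "empty_1": ArmSchedule("empty", 0.0, 0, False),
                "empty_2": ArmSchedule("empty", 0.0, 0, False),
            }
        )

    def roles(self) -> dict[str, str]:
        return {name: arm.role for name, arm in self.arms.items()}


def expected_payoff(schedule: RewardSchedule, arm: str) -> float:
    """Pellets expected per 10 choices of one arm."""
    a = schedule.arms[arm]
    return 10.0 * a.p_reward * a.pellets_on_win


def chance_levels(schedule: RewardSchedule) -> tuple[float, float]:
    """(empty, advantageous) choice fractions under indifference: the
    share of arms carrying each role."""
    roles = list(schedule.roles().values())
    n = len(roles)
    return roles.count("empty") / n, roles.count("advantageous") / n


@dataclass
class TrialRecord:
    animal: str
    session: int  # 1-10
    trial: int  # 1-12 within session
    arm: str
    pellets: int = 0
    quinine: bool = False
    exclusion: str = "none"

    def __post_init__(self):
        if self.exclusion not in EXCLUSION_REASONS:
            raise ValueError(f"unknown exclusion flag {self.exclusion!r}")


def apply_exclusions(
    records: list[TrialRecord],
) -> tuple[list[TrialRecord], pd.DataFrame]:
    """Drop every animal with any flagged trial; return the retained
    records and an audit table of reason counts per animal."""
    flagged: dict[str, dict[str, int]] = {}
    for r in records:
        if r.exclusion != "none":
            flagged.setdefault(r.animal, {}).setdefault(r.exclusion, 0)
            flagged[r.animal][r.exclusion] += 1
    audit_rows = [
        {"animal": a, "reason": reason, "n_trials": n}
        for a, reasons in sorted(flagged.items())
        for reason, n in sorted(reasons.items())
    ]
    audit = pd.DataFrame(audit_rows, columns=["animal", "reason", "n_trials"])
    retained = [r for r in records if r.animal not in flagged]
    return retained, audit


def block_fractions(
    records: list[TrialRecord],
    schedule: RewardSchedule | None = None,
    block_size: int = TRIALS_PER_SESSION,
) -> pd.DataFrame:
    """Choice fractions per block of ``block_size`` trials for one
    animal's record (sorted by session, trial).  An incomplete final
    block is normalised by its actual trial count."""
    schedule = schedule or RewardSchedule.standard()
    roles = schedule.roles()
    recs = sorted(records, key=lambda r: (r.session, r.trial))
    rows = []
    for b in range(0, len(recs), block_size):
        chunk = recs[b : b + block_size]
        n = len(chunk)
        empty = sum(1 for r in chunk if roles[r.arm] == "empty")
        adv = sum(1 for r in chunk if roles[r.arm] == "advantageous")
        rows.append(
            {
                "block": b // block_size + 1,
                "n_trials": n,
                "empty_fraction": empty / n,
                "advantageous_fraction": adv / n,
            }
        )
    return pd.DataFrame(rows)


def group_curves(
    records_by_animal: dict[str, list[TrialRecord]],
    schedule: RewardSchedule | None = None,
) -> pd.DataFrame:
    """Per-block fractions for each animal, stacked long-form."""
    frames = []
    for animal, recs in records_by_animal.items():
        cur = block_fractions(recs, schedule)
        cur.insert(0, "animal", animal)
        frames.append(cur)
    return pd.concat(frames, ignore_index=True)


def final_performance(curve: pd.DataFrame) -> pd.Series:
    """Scores of the last session (block 10) as final performance."""
    return curve.loc[curve["block"] == curve["block"].max()].iloc[0]


def realize_outcome(
    schedule: RewardSchedule, arm: str, rng: np.random.Generator
) -> tuple[int, bool]:
    """Sample (pellets, quinine) for one choice; win probabilities are
    treated as i.i.d. Bernoulli per trial rather than a fixed per-10
    deck (see ``deck_mode`` for the quota variant)."""
    a = schedule.arms[arm]
    if a.role == "empty":
        return 0, False
    if rng.random() < a.p_reward:
        return a.pellets_on_win, False
    return 0, a.quinine_otherwise


class DeckOutcomes:
    """Quota variant: exactly p*10 wins per rolling deck of 10 trials,
    shuffled, matching the printed '8 of 10' wording literally."""

    def __init__(self, schedule: RewardSchedule, rng: np.random.Generator):
        self.schedule = schedule
        self.rng = rng
        self._decks: dict[str, list[bool]] = {}

    def draw(self, arm: str) -> tuple[int, bool]:
        a = self.schedule.arms[arm]
        if a.role == "empty":
            return 0, False
        deck = self._decks.get(arm)
        if not deck:
            wins = int(round(a.p_reward * 10))
            deck = [True] * wins + [False] * (10 - wins)
            self.rng.shuffle(deck)
            self._decks[arm] = deck
        win = self._decks[arm].pop()
        return (a.pellets_on_win, False) if win else (0, a.quinine_otherwise)
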