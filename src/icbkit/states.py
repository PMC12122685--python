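"""Behavioural-state bout analysis of event-recorder logs.

Each observation window is a 50 s scoring span in which an observer
annotated contiguous bouts of one behavioural state at a time, drawn
from a six-state repertoire (locomoting, rearing, grooming, head
bobbing, sniffing up, sniffing down).  Unclassifiable spans remain
unscored gaps.  Summaries: total time per state averaged across the
windows, mean bout duration for the four states expressed by every
experimental group, and the switch rate (state-to-state transitions
divided by the number of distinct common states present, averaged
across windows).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

STATE_REPERTOIRE = (
    "locomoting",
    "rearing",
    "grooming",
    "head bobbing",
    "sniffing up",
    "sniffing down",
)
# states scored repeatedly in every experimental group; bout-duration and
# switch-rate denominators are restricted to these
COMMON_STATES = ("locomoting", "rearing", "sniffing up", "sniffing down")
SCORING_SPAN_S = 50.0


class EventFormatError(ValueError):
    pass


@dataclass
class StateEventLog:
    window_id: str
    events: list[tuple[str, float, float]]  # (state, start_s, end_s)
    span: float = SCORING_SPAN_S
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.events = sorted(self.events, key=lambda e: e[1])

    @property
    def scored_time(self) -> float:
        return sum(e[2] - e[1] for e in self.events)


def parse_event_log(rows, span: float = SCORING_SPAN_S) -> list[StateEventLog]:
    """Build validated logs from (window_id, state, start_s, end_s) rows.

    Raises :class:`EventFormatError` naming the offending row numbers on
    overlap, reversed intervals, or unknown states.  Gaps between events
    are preserved as unscored time.
    """
    windows: dict[str, list[tuple[str, float, float, int]]] = {}
    for i, (wid, state, start, end) in enumerate(rows):
        start, end = float(start), float(end)
        if state not in STATE_REPERTOIRE:
            raise EventFormatError(f"row {i}: unknown state {state!r}")
        if end <= start:
            raise EventFormatError(f"row {i}: end <= start")
        if end > span + 1e-9 or start < -1e-9:
            raise EventFormatError(f"row {i}: interval outside the {span} s span")
        windows.setdefault(str(wid), []).append((state, start, end, i))
    logs = []
    for wid, evs in windows.items():
        evs.sort(key=lambda e: e[1])
        for (s1, a1, b1, r1), (s2, a2, b2, r2) in zip(evs, evs[1:]):
            if a2 < b1 - 1e-9:
                raise EventFormatError(f"rows {r1} and {r2}: overlapping events")
        logs.append(StateEventLog(wid, [(s, a, b) for s, a, b, _ in evs], span))
    return logs


def parse_keystroke_stream(
    onsets, span: float = SCORING_SPAN_S, window_id: str = "w0",
    gap_symbol: str = ".",
) -> StateEventLog:
    """Reconstruct intervals from an onset stream ``(time_s, state)``.

    Each keystroke opens a state that closes at the next keystroke (or
    the end of the span); the gap symbol closes the current state
    without opening a new one, leaving unscored time.
    """
    onsets = sorted(((float(t), s) for t, s in onsets), key=lambda e: e[0])
    events = []
    for (t, s), nxt in zip(onsets, list(onsets[1:]) + [(span, gap_symbol)]):
        if s == gap_symbol:
            continue
        if s not in STATE_REPERTOIRE:
            raise EventFormatError(f"unknown state symbol {s!r} at t={t}")
        if nxt[0] > t:
            events.append((s, t, min(nxt[0], span)))
    return StateEventLog(window_id, events, span)


def state_totals(logs: list[StateEventLog]) -> dict[str, float]:
    """Seconds per state, averaged across the observation windows."""
    if not logs:
        raise ValueError("no logs supplied")
    totals = {s: 0.0 for s in STATE_REPERTOIRE}
    for log in logs:
        for state, start, end in log.events:
            totals[state] += end - start
    return {s: v / len(logs) for s, v in totals.items()}


def bout_durations(
    logs: list[StateEventLog], states_common=COMMON_STATES
) -> dict[str, float | None]:
    """Mean bout duration per common state, pooling bouts across
    windows; a state with zero bouts is reported missing (None), never
    as a zero duration."""
    pools: dict[str, list[float]] = {s: [] for s in states_common}
    for log in logs:
        for state, start, end in log.events:
            if state in pools:
                pools[state].append(end - start)
    return {s: (float(np.mean(v)) if v else None) for s, v in pools.items()}


def switch_rate(
    logs: list[StateEventLog],
    states_common=COMMON_STATES,
    across_gaps: bool = True,
) -> float | None:
    """Mean over windows of (label switches) / (distinct common states
    present).

    A switch is a change of label between consecutive scored events;
    with ``across_gaps`` (default) an unscored gap does not reset the
    sequence.  Windows with no scored events, or none of the common
    states, are excluded from the average; None if nothing remains.
    """
    rates = []
    for log in logs:
        if not log.events:
            continue
        labels = [e[0] for e in log.events]
        if across_gaps:
            seq = labels
        else:
            seq = []
            prev_end = None
            for (s, a, b) in log.events:
                if prev_end is not None and a > prev_end + 1e-9:
                    seq.append(None)  # gap breaks the chain
                seq.append(s)
                prev_end = b
        switches = sum(
            1
            for u, v in zip(seq, seq[1:])
            if u is not None and v is not None and u != v
        )
        present = {s for s in labels if s in states_common}
        if not present:
            continue
        rates.append(switches / len(present))
    return float(np.mean(rates)) if rates else None


@dataclass
class StateSummary:
    total_time: dict[str, float]
    bout_duration: dict[str, float | None]
    switch_rate: float | None


def summarize_states(logs: list[StateEventLog]) -> StateSummary:
    return StateSummary(state_totals(logs), bout_durations(logs), switch_rate(logs))
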