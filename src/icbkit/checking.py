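"""Compulsive-checking analysis on the elevated open platform.

The 140 x 140 cm platform is subdivided into a square grid of 35 cm
zones whose outer ring extends 17.5 cm beyond the platform edge (25
zones in the standard configuration).  Stops are maximal intervals of
immobility longer than one second; the one or two zones accumulating
the most stopping time are the animal's home bases, and a "check" is a
visit (zone entry) to a home base.  Checking is quantified by the visit
frequency, the ratio of observed home-base visits to the per-zone visit
count expected under indifference, the mean dwell per home-base visit,
the mean return time between consecutive checks, and the mean number of
stops made in between checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .trajectory import Trajectory, speed

DEFAULT_IMMOBILITY_SPEED = 1.0  # cm/s; the duration criterion is >1 s
DEFAULT_MIN_STOP_S = 1.0
DEFAULT_DEBOUNCE_S = 1.0  # re-entries into the same zone within 1 s merge
DEFAULT_SECONDARY_THRESHOLD = 0.5  # HB2 needs >= 50% of HB1's stop time


class GeometryError(ValueError):
    pass


class AnalysisError(ValueError):
    pass


@dataclass(frozen=True)
class ZoneGrid:
    platform: float  # cm
    zone: float  # cm
    border: float  # cm beyond the platform edge
    n_side: int

    @property
    def n_zones(self) -> int:
        return self.n_side**2

    @property
    def extent(self) -> float:
        return self.platform + 2 * self.border

    def zone_of(self, x, y) -> np.ndarray:
        """Zone ids (row-major from the lower-left corner); points beyond
        the extended square are clamped to the nearest edge zone."""
        half = self.extent / 2
        col = np.clip(((np.asarray(x) + half) // self.zone).astype(int), 0, self.n_side - 1)
        row = np.clip(((np.asarray(y) + half) // self.zone).astype(int), 0, self.n_side - 1)
        return row * self.n_side + col

    def centre_of(self, zone_id: int) -> tuple[float, float]:
        half = self.extent / 2
        row, col = divmod(int(zone_id), self.n_side)
        return (
            -half + (col + 0.5) * self.zone,
            -half + (row + 0.5) * self.zone,
        )

    def adjacent(self, a: int, b: int) -> bool:
        """8-neighbour adjacency on the grid (a zone is not its own
        neighbour)."""
        ra, ca = divmod(int(a), self.n_side)
        rb, cb = divmod(int(b), self.n_side)
        return (a != b) and max(abs(ra - rb), abs(ca - cb)) <= 1


def build_zone_grid(
    platform: float = 140.0, zone: float = 35.0, border: float = 17.5
) -> ZoneGrid:
    extent = platform + 2 * border
    n = extent / zone
    if abs(n - round(n)) > 1e-6:
        raise GeometryError(
            f"(platform + 2*border) = {extent} is not divisible by zone = {zone}"
        )
    return ZoneGrid(platform, zone, border, int(round(n)))


@dataclass
class Stop:
    zone: int
    start: float  # s
    duration: float  # s


def detect_stops(
    traj: Trajectory,
    grid: ZoneGrid,
    immobility_speed: float = DEFAULT_IMMOBILITY_SPEED,
    min_duration: float = DEFAULT_MIN_STOP_S,
) -> list[Stop]:
    """Maximal intervals with smoothed speed below ``immobility_speed``
    lasting strictly longer than ``min_duration``; each stop is assigned
    to the zone of its time-weighted centroid."""
    v = speed(traj)
    still = v < immobility_speed
    stops: list[Stop] = []
    i, n = 0, still.size
    while i < n:
        if not still[i]:
            i += 1
            continue
        j = i
        while j < n and still[j]:
            j += 1
        dur = (j - i) * traj.dt
        if dur > min_duration:
            cx = float(traj.x[i:j].mean())
            cy = float(traj.y[i:j].mean())
            zone = int(grid.zone_of(cx, cy))
            stops.append(Stop(zone, float(traj.t[i]), dur))
        i = j
    return stops


@dataclass
class Visit:
    zone: int
    entry: float
    exit: float

    @property
    def dwell(self) -> float:
        return self.exit - self.entry


def zone_visits(
    traj: Trajectory, grid: ZoneGrid, debounce_s: float = DEFAULT_DEBOUNCE_S
) -> list[Visit]:
    """Visit sequence from the tracked point's zone membership.

    Consecutive visits always differ in zone; a return to the previous
    zone within ``debounce_s`` is merged into the earlier visit so that
    boundary jitter does not inflate visit counts.
    """
    zones = grid.zone_of(traj.x, traj.y)
    visits: list[Visit] = []
    i, n = 0, zones.size
    while i < n:
        j = i
        while j < n and zones[j] == zones[i]:
            j += 1
        entry = float(traj.t[i])
        exit_ = float(traj.t[j - 1]) + traj.dt
        if visits and visits[-1].zone == zones[i] and entry - visits[-1].exit <= debounce_s:
            visits[-1].exit = exit_
        else:
            visits.append(Visit(int(zones[i]), entry, exit_))
        i = j
    return visits


def identify_home_bases(
    stops: list[Stop],
    grid: ZoneGrid,
    secondary_threshold: float = DEFAULT_SECONDARY_THRESHOLD,
) -> list[int]:
    """One or two non-adjacent zones with the highest total stop time.

    The top zone is always a home base.  The best-ranked zone not
    adjacent to it is added when its total stop duration reaches
    ``secondary_threshold`` of the top zone's.  Ties break toward the
    lower zone index.
    """
    if not stops:
        raise AnalysisError(
            "no stops detected; animal cannot be scored for checking "
            "(exclude from this analysis)"
        )
    totals: dict[int, float] = {}
    for s in stops:
        totals[s.zone] = totals.get(s.zone, 0.0) + s.duration
    ranked = sorted(totals.items(), key=lambda kv: (-kv[1], kv[0]))
    hb1, dur1 = ranked[0]
    bases = [hb1]
    for zone, dur in ranked[1:]:
        if grid.adjacent(hb1, zone):
            continue
        if dur >= secondary_threshold * dur1:
            bases.append(zone)
        break
    return bases


@dataclass
class CheckingReport:
    home_bases: list[int]
    frequency: int
    ratio_obs_exp: float
    mean_visit_time: float | None
    mean_return_time: float | None  # None with <2 home-base visits
    stops_between_checks: float | None
    total_visits: int = 0
    window: tuple[float, float] = (0.0, 0.0)
    meta: dict = field(default_factory=dict)


def checking_metrics(
    visits: list[Visit],
    stops: list[Stop],
    home_bases: list[int],
    grid: ZoneGrid,
    window: tuple[float, float],
) -> CheckingReport:
    """The five checking parameters over ``window`` (seconds).

    ratio_obs_exp = (home-base visits / number of home bases) divided by
    (total zone visits / number of zones): the per-home-base visit count
    against the per-zone count expected were visits spread evenly, which
    normalises checking for overall locomotion.
    """
    t0, t1 = window
    vis = [v for v in visits if t0 <= v.entry < t1]
    sts = [s for s in stops if t0 <= s.start < t1]
    hb = set(home_bases)
    checks = [v for v in vis if v.zone in hb]
    frequency = len(checks)
    total = len(vis)
    if total == 0:
        ratio = 0.0
    else:
        ratio = (frequency / len(home_bases)) / (total / grid.n_zones)
    mean_visit = float(np.mean([v.dwell for v in checks])) if checks else None
    mean_return = None
    stops_between = None
    if frequency >= 2:
        returns, counts = [], []
        for a, b in zip(checks[:-1], checks[1:]):
            returns.append(b.entry - a.exit)
            counts.append(
                sum(1 for s in sts if a.exit < s.start < b.entry)
            )
        mean_return = float(np.mean(returns))
        stops_between = float(np.mean(counts))
    return CheckingReport(
        list(home_bases),
        frequency,
        ratio,
        mean_visit,
        mean_return,
        stops_between,
        total_visits=total,
        window=window,
    )


def select_window(
    treatment_class: str, recording_min: float = 45.0
) -> tuple[float, float]:
    """Scoring window in seconds: the full recording for baseline-like
    animals, the final 30 minutes for hyperlocomotive ones (the first
    15 min are discarded because D2-class agonists transiently suppress
    locomotion before the hyperactive phase)."""
    if treatment_class == "baseline_like":
        return (0.0, recording_min * 60.0)
    if treatment_class == "hyperlocomotive":
        return ((recording_min - 30.0) * 60.0, recording_min * 60.0)
    raise ValueError(f"unknown treatment class {treatment_class!r}")


def analyze_checking(
    traj: Trajectory,
    treatment_class: str = "baseline_like",
    grid: ZoneGrid | None = None,
    immobility_speed: float = DEFAULT_IMMOBILITY_SPEED,
    secondary_threshold: float = DEFAULT_SECONDARY_THRESHOLD,
) -> CheckingReport:
    """Full scoring pipeline for one animal: window selection, stop
    detection, home-base identification, and the five metrics."""
    grid = grid or build_zone_grid()
    window = select_window(treatment_class, recording_min=traj.duration / 60.0)
    sub = traj.slice_time(*window)
    stops = detect_stops(sub, grid, immobility_speed=immobility_speed)
    bases = identify_home_bases(stops, grid, secondary_threshold=secondary_threshold)
    visits = zone_visits(sub, grid)
    return checking_metrics(visits, stops, bases, grid, window)
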