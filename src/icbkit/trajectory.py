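"""Trajectory container and open-field / plus-maze motion metrics.

A trajectory is a uniformly sampled planar track of one animal
(timestamps in seconds, positions in centimetres, arena-centred).
Metrics follow the usual video-tracking definitions: distance as the
sum of Euclidean step lengths, mobility as time above a smoothed speed
threshold, maximal speed as the peak of a windowed mean speed, and zone
occupancy by point-in-region tests on the tracked point.

Distances are reported in metres and speeds in m/s to match how these
assays are conventionally plotted; positions stay in cm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .arenas import (
    ArenaSpec,
    EPM_OPEN,
    EPM_ZONES,
    epm_zone,
    open_field_zone,
)

DEFAULT_MOBILITY_THRESHOLD = 2.0  # cm/s
DEFAULT_SMOOTH_S = 0.5  # median smoothing of speed
DEFAULT_SPEED_WINDOW_S = 0.5  # window for maximal speed
DEFAULT_EPM_MIN_DWELL_S = 0.5  # dwell needed to count an arm entry


class InsufficientDataError(ValueError):
    pass


@dataclass
class Trajectory:
    t: np.ndarray  # s, strictly increasing, uniform step
    x: np.ndarray  # cm
    y: np.ndarray  # cm
    arena: ArenaSpec
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (self.t.size == self.x.size == self.y.size):
            raise ValueError("t, x, y must have equal length")
        if self.t.size >= 2:
            dt = np.diff(self.t)
            if np.any(dt <= 0):
                raise ValueError("timestamps must be strictly increasing")
            if np.ptp(dt) > 1e-6:
                raise ValueError("sampling must be uniform")
        for arr, name in ((self.t, "t"), (self.x, "x"), (self.y, "y")):
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"non-finite values in {name}")

    @property
    def dt(self) -> float:
        if self.t.size < 2:
            raise InsufficientDataError("need >=2 samples")
        return float(self.t[1] - self.t[0])

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0]) + self.dt

    def __len__(self) -> int:
        return self.t.size

    def slice_time(self, t0: float, t1: float) -> "Trajectory":
        keep = (self.t >= t0) & (self.t < t1)
        return Trajectory(self.t[keep], self.x[keep], self.y[keep], self.arena, self.meta)


def _median_smooth(v: np.ndarray, window: int) -> np.ndarray:
    if window <= 1 or v.size < 3:
        return v
    window = min(window | 1, v.size if v.size % 2 else v.size - 1)
    from scipy.ndimage import median_filter

    return median_filter(v, size=window, mode="nearest")


def speed(traj: Trajectory, smooth_s: float = DEFAULT_SMOOTH_S) -> np.ndarray:
    """Per-sample speed (cm/s) by central differences, median-smoothed."""
    if len(traj) < 2:
        raise InsufficientDataError("need >=2 samples for speed")
    vx = np.gradient(traj.x, traj.t)
    vy = np.gradient(traj.y, traj.t)
    v = np.hypot(vx, vy)
    return _median_smooth(v, int(round(smooth_s / traj.dt)))


def total_distance(traj: Trajectory, smooth_s: float = 0.0) -> float:
    """Path length in metres, optionally median-smoothing positions."""
    if len(traj) < 2:
        raise InsufficientDataError("need >=2 samples for distance")
    x, y = traj.x, traj.y
    if smooth_s > 0:
        w = int(round(smooth_s / traj.dt))
        x = _median_smooth(x, w)
        y = _median_smooth(y, w)
    return float(np.hypot(np.diff(x), np.diff(y)).sum()) / 100.0


def time_mobile(
    traj: Trajectory,
    speed_threshold: float = DEFAULT_MOBILITY_THRESHOLD,
    smooth_s: float = DEFAULT_SMOOTH_S,
) -> float:
    """Seconds with smoothed speed >= threshold (cm/s)."""
    if speed_threshold <= 0:
        raise ValueError("speed threshold must be positive")
    v = speed(traj, smooth_s)
    return float(np.count_nonzero(v >= speed_threshold)) * traj.dt


def max_speed(traj: Trajectory, window_s: float = DEFAULT_SPEED_WINDOW_S) -> float:
    """Maximum windowed-mean speed in m/s."""
    v = speed(traj, smooth_s=0.0)
    w = max(1, int(round(window_s / traj.dt)))
    if w > 1:
        kernel = np.ones(w) / w
        v = np.convolve(v, kernel, mode="valid")
    return float(v.max()) / 100.0


def zone_fractions(traj: Trajectory) -> dict[str, float]:
    """Open-field inner/outer time fractions (sum to 1).

    Samples beyond the walls (tracking overshoot) are clamped to the
    outer zone and counted in ``meta['n_clamped']``.
    """
    if traj.arena.kind != "open_field":
        raise ValueError("zone_fractions requires an open-field arena")
    inner = open_field_zone(traj.arena, traj.x, traj.y)
    outside = ~traj.arena.contains(traj.x, traj.y, tol=1e-9)
    inner = inner & ~outside
    f_in = float(np.count_nonzero(inner)) / len(traj)
    traj.meta["n_clamped"] = int(np.count_nonzero(outside))
    return {"inner": f_in, "outer": 1.0 - f_in}


@dataclass
class EPMResult:
    open_arm_entry_fraction: float | None  # None when no arm entry occurred
    entries: dict[str, int]
    total_entries: int
    total_distance_m: float


def epm_entries(
    traj: Trajectory, min_dwell_s: float = DEFAULT_EPM_MIN_DWELL_S
) -> EPMResult:
    """Arm entries on the plus maze.

    An entry is a transition from the centre into an arm with the
    tracked point remaining there for at least ``min_dwell_s``.  The
    open-arm entry fraction is flagged undefined (None) when no arm
    entry occurred; it is never silently reported as zero.
    """
    if traj.arena.kind != "epm":
        raise ValueError("epm_entries requires an EPM arena")
    labels = [epm_zone(traj.arena, xi, yi) for xi, yi in zip(traj.x, traj.y)]
    min_n = max(1, int(round(min_dwell_s / traj.dt)))
    entries = {z: 0 for z in EPM_ZONES if z != "centre"}
    i, n = 0, len(labels)
    current = labels[0]
    while i < n:
        j = i
        while j < n and labels[j] == labels[i]:
            j += 1
        run_label, run_len = labels[i], j - i
        if run_label != "centre" and run_label != current and run_len >= min_n:
            entries[run_label] += 1
            current = run_label
        elif run_label == "centre" and run_len >= min_n:
            current = "centre"
        i = j
    total = sum(entries.values())
    frac = None
    if total > 0:
        frac = sum(entries[z] for z in EPM_OPEN) / total
    return EPMResult(frac, entries, total, total_distance(traj))


def occupancy_heatmap(
    traj: Trajectory, bin_cm: float = 5.0
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Seconds spent per spatial bin; mass equals recording duration.

    Returns (H, xedges, yedges) with H indexed [ix, iy].
    """
    nx = max(1, int(np.ceil(2 * traj.arena.half_x / bin_cm)))
    ny = max(1, int(np.ceil(2 * traj.arena.half_y / bin_cm)))
    H, xe, ye = np.histogram2d(
        traj.x,
        traj.y,
        bins=[nx, ny],
        range=[
            [-traj.arena.half_x, -traj.arena.half_x + nx * bin_cm],
            [-traj.arena.half_y, -traj.arena.half_y + ny * bin_cm],
        ],
    )
    return H * traj.dt, xe, ye


@dataclass
class MotionSummary:
    total_distance_m: float
    time_mobile_s: float
    max_speed_ms: float
    inner_zone_fraction: float | None = None
    open_arm_entry_fraction: float | None = None


def summarize_open_field(traj: Trajectory, **kwargs) -> MotionSummary:
    return MotionSummary(
        total_distance(traj),
        time_mobile(traj, **kwargs),
        max_speed(traj),
        inner_zone_fraction=zone_fractions(traj)["inner"],
    )


def summarize_epm(traj: Trajectory) -> MotionSummary:
    res = epm_entries(traj)
    return MotionSummary(
        res.total_distance_m,
        time_mobile(traj),
        max_speed(traj),
        open_arm_entry_fraction=res.open_arm_entry_fraction,
    )
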