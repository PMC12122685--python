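"""Correlated-random-walk trajectory generator.

The walk alternates mobile and immobile phases through a two-state
renewal process; while mobile, the heading follows a von Mises turning
kernel (directional persistence) and the per-step speed is
gamma-distributed around the mean.  Home-base attraction produces a
checking cycle: after each stop the animal departs on an undirected
excursion for an exponential time, then a homing drift (weight
attraction/(attraction+1)) steers the heading back toward the nearest
home-base centre, where an elevated stopping hazard makes it reliably
halt — one "check".  Stronger attraction gives straighter, faster
returns with fewer stops along the way, while attraction 0 disables
the drift entirely and leaves a spatially unbiased walk.  This is the
minimal construction producing both drug-like hyperlocomotion (high
mobility fraction, high speed) and excessive home-base revisiting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from ..arenas import ArenaSpec, checking_platform
from ..checking import ZoneGrid, build_zone_grid
from ..trajectory import Trajectory


@dataclass
class TrajectoryParams:
    duration: float = 2700.0  # s (45 min checking session)
    sample_rate: float = 5.0  # Hz
    arena: ArenaSpec = field(default_factory=checking_platform)
    mean_speed: float = 12.0  # cm/s while mobile
    speed_cv: float = 0.5
    turn_concentration: float = 4.0  # von Mises kappa; 0 = uncorrelated
    mobility_fraction: float = 0.35  # fraction of time in motion
    home_base_zones: tuple[int, ...] = ()
    attraction_strength: float = 0.0
    visit_dwell_mean: float = 4.0  # s, mean immobile dwell
    excursion_mean: float = 8.0  # s of undirected walking after each stop
    seed: int = 0

    def validate(self) -> None:
        scalars = {
            "duration": self.duration,
            "sample_rate": self.sample_rate,
            "mean_speed": self.mean_speed,
            "speed_cv": self.speed_cv,
            "turn_concentration": self.turn_concentration,
            "mobility_fraction": self.mobility_fraction,
            "attraction_strength": self.attraction_strength,
            "visit_dwell_mean": self.visit_dwell_mean,
        }
        for name, v in scalars.items():
            if not math.isfinite(v):
                raise ValueError(f"non-finite parameter {name}")
        if self.duration <= 0 or self.sample_rate <= 0:
            raise ValueError("duration and sample_rate must be positive")
        if not 0.0 <= self.mobility_fraction <= 1.0:
            raise ValueError("mobility_fraction must lie in [0, 1]")
        if self.attraction_strength < 0:
            raise ValueError("attraction_strength must be >= 0")
        if self.visit_dwell_mean <= 0 or self.mean_speed < 0:
            raise ValueError("visit_dwell_mean and mean_speed must be positive")
        if self.excursion_mean <= 0 or not math.isfinite(self.excursion_mean):
            raise ValueError("excursion_mean must be positive")


def _zone_grid_for(arena: ArenaSpec) -> ZoneGrid:
    # the checking proportions (zone = side/4, border = side/8 -> 5 x 5)
    # generalise to any square arena
    side = 2 * arena.half_x
    return build_zone_grid(side, side / 4, side / 8)


def _clamp_epm(arena: ArenaSpec, x: float, y: float) -> tuple[float, float]:
    """Project a proposal onto the plus-shaped track."""
    hw = arena.params["arm_width"] / 2
    c = arena.params["centre"] / 2
    half = arena.half_x
    x = min(max(x, -half), half)
    y = min(max(y, -half), half)
    if abs(x) <= c and abs(y) <= c:
        return x, y
    if abs(x) >= abs(y):  # open arms along x
        return x, min(max(y, -hw), hw)
    return min(max(x, -hw), hw), y


def gen_trajectory(params: TrajectoryParams) -> Trajectory:
    """Simulate one track; positions stay inside the arena bounds and
    time advances in strict 1/sample_rate steps."""
    params.validate()
    dt = 1.0 / params.sample_rate
    n = int(round(params.duration * params.sample_rate))
    rng = np.random.default_rng(params.seed)

    mf = params.mobility_fraction
    dwell = params.visit_dwell_mean
    p_go = 0.0 if mf == 0 else min(1.0, dt / dwell)
    if mf == 0:
        base_stop_hazard = 1.0
    elif mf == 1:
        base_stop_hazard = 0.0
    else:
        base_stop_hazard = min(1.0, dt * (1 - mf) / (dwell * mf))

    grid = None
    home_centres = np.zeros((0, 2))
    if params.home_base_zones and params.arena.kind != "epm":
        grid = _zone_grid_for(params.arena)
        home_centres = np.array(
            [grid.centre_of(z) for z in params.home_base_zones], dtype=float
        )
    attract = params.attraction_strength
    w_drift = attract / (1.0 + attract)

    # pre-drawn innovations keep the per-step loop cheap
    turns = (
        rng.vonmises(0.0, params.turn_concentration, size=n)
        if params.turn_concentration > 0
        else rng.uniform(-np.pi, np.pi, size=n)
    )
    if params.speed_cv > 0:
        shape = 1.0 / params.speed_cv**2
        speeds = rng.gamma(shape, params.mean_speed / shape, size=n)
    else:
        speeds = np.full(n, params.mean_speed)
    u_phase = rng.random(n)

    x = np.empty(n)
    y = np.empty(n)
    px, py = 0.0, 0.0  # start at the arena centre
    heading = rng.uniform(-np.pi, np.pi)
    mobile = u_phase[0] < mf
    hx, hy = params.arena.half_x, params.arena.half_y
    homing = home_centres.size > 0 and attract > 0
    excursion_left = 0.0  # s of undirected walking before homing resumes

    def in_home(px, py) -> bool:
        if grid is None:
            return False
        return int(grid.zone_of(px, py)) in params.home_base_zones

    for i in range(n):
        if mobile:
            heading += turns[i]
            returning = homing and excursion_left <= 0.0
            if returning:
                d2 = (home_centres[:, 0] - px) ** 2 + (home_centres[:, 1] - py) ** 2
                tx, ty = home_centres[int(np.argmin(d2))]
                target = math.atan2(ty - py, tx - px)
                delta = (target - heading + np.pi) % (2 * np.pi) - np.pi
                heading += w_drift * delta
            step = speeds[i] * dt
            nx = px + step * math.cos(heading)
            ny = py + step * math.sin(heading)
            if params.arena.kind == "epm":
                nx, ny = _clamp_epm(params.arena, nx, ny)
            else:
                if nx < -hx or nx > hx:
                    nx = min(max(nx, -hx), hx)
                    heading = math.pi - heading
                if ny < -hy or ny > hy:
                    ny = min(max(ny, -hy), hy)
                    heading = -heading
            px, py = nx, ny
            excursion_left -= dt
            hazard = base_stop_hazard
            if returning and in_home(px, py):
                # arriving back at the attended zone: stop reliably (a check)
                hazard = min(1.0, base_stop_hazard * (1.0 + attract) + w_drift)
            if u_phase[i] < hazard:
                mobile = False
        else:
            if u_phase[i] < p_go:
                mobile = True
                heading = rng.uniform(-np.pi, np.pi)
                if homing:
                    # preoccupation shortens trips away from the home base
                    excursion_left = rng.exponential(
                        params.excursion_mean / (1.0 + attract / 2.0)
                    )
        x[i] = px
        y[i] = py

    t = dt * np.arange(n)
    return Trajectory(
        t,
        x,
        y,
        params.arena,
        meta={"seed": params.seed, "generator": "crw", "sample_rate": params.sample_rate},
    )
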