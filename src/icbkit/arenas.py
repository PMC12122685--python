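"""Arena geometries and zone assignment.

All coordinates are arena-centred, in centimetres, y pointing up.
Region tests are half-open on shared boundaries, resolved toward the
zone with the lower index so assignment is deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

OPEN_FIELD_SIDE = 80.0
CHECKING_PLATFORM_SIDE = 140.0
EPM_ARM_LENGTH = 50.8
EPM_ARM_WIDTH = 10.2
EPM_CENTRE_SIDE = 10.2


@dataclass(frozen=True)
class ArenaSpec:
    """A named arena with its bounding half-extents (cm)."""

    kind: str  # open_field | epm | checking_platform
    half_x: float
    half_y: float
    params: dict = field(default_factory=dict)

    def contains(self, x, y, tol: float = 0.0) -> np.ndarray:
        return (
            (np.abs(np.asarray(x)) <= self.half_x + tol)
            & (np.abs(np.asarray(y)) <= self.half_y + tol)
        )


def open_field(side: float = OPEN_FIELD_SIDE) -> ArenaSpec:
    """Square open field; the inner zone is the centred square holding
    80% of the floor area (side * sqrt(0.8)), the 20% strip along the
    walls is the outer zone."""
    return ArenaSpec(
        "open_field",
        side / 2,
        side / 2,
        {"side": side, "inner_half": side * math.sqrt(0.8) / 2},
    )


def checking_platform(side: float = CHECKING_PLATFORM_SIDE) -> ArenaSpec:
    return ArenaSpec("checking_platform", side / 2, side / 2, {"side": side})


def epm(
    arm_length: float = EPM_ARM_LENGTH,
    arm_width: float = EPM_ARM_WIDTH,
    centre: float = EPM_CENTRE_SIDE,
) -> ArenaSpec:
    """Plus maze: open arms along the x axis, closed arms along y."""
    half = centre / 2 + arm_length
    return ArenaSpec(
        "epm",
        half,
        half,
        {"arm_length": arm_length, "arm_width": arm_width, "centre": centre},
    )


EPM_ZONES = ("centre", "open_east", "open_west", "closed_north", "closed_south")
EPM_OPEN = ("open_east", "open_west")
EPM_CLOSED = ("closed_north", "closed_south")


def epm_zone(arena: ArenaSpec, x: float, y: float) -> str:
    """Zone label for one tracked point on the plus maze.

    Points off the cross (possible with tracking jitter) are clamped to
    the nearest zone by axis dominance.
    """
    c = arena.params["centre"] / 2
    if abs(x) <= c and abs(y) <= c:
        return "centre"
    if abs(x) > abs(y):
        return "open_east" if x > 0 else "open_west"
    return "closed_north" if y > 0 else "closed_south"


def open_field_zone(arena: ArenaSpec, x, y) -> np.ndarray:
    """Vectorised inner/outer assignment; returns boolean 'is inner'."""
    h = arena.params["inner_half"]
    return (np.abs(np.asarray(x)) < h) & (np.abs(np.asarray(y)) < h)
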