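"""Screen model, dot stimuli, hit-testing and non-overlapping random placement.

Coordinate convention: 0-based integer pixels, origin at the top-left corner,
y increasing downward.  Distances are computed in floating point.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import ConfigurationError, PlacementError

__all__ = [
    "ScreenSpec",
    "DotStimulus",
    "TouchEvent",
    "sample_dot_placement",
    "hit_test",
]

#: hard budget for rejection sampling before giving up
DEFAULT_ATTEMPT_BUDGET = 10_000


@dataclass(frozen=True)
class ScreenSpec:
    """Pixel dimensions of the touch surface."""

    width_px: int = 1024
    height_px: int = 768

    def __post_init__(self) -> None:
        if self.width_px < 1 or self.height_px < 1:
            raise ConfigurationError(
                f"screen dimensions must be >= 1 px, got "
                f"{self.width_px}x{self.height_px}"
            )

    @property
    def min_dimension_px(self) -> int:
        return min(self.width_px, self.height_px)


@dataclass
class DotStimulus:
    """A circular touch target, optionally labeled with a numeral."""

    dot_id: str
    center_x_px: int
    center_y_px: int
    diameter_px: int
    label: Optional[str] = None  # None, "1" or "2"
    visible: bool = True

    def __post_init__(self) -> None:
        if self.diameter_px <= 0:
            raise ConfigurationError(
                f"dot {self.dot_id!r}: diameter must be positive, got "
                f"{self.diameter_px}"
            )
        if self.label not in (None, "1", "2"):
            raise ConfigurationError(
                f"dot {self.dot_id!r}: label must be None, '1' or '2'"
            )

    @property
    def radius_px(self) -> float:
        return self.diameter_px / 2.0


@dataclass(frozen=True)
class TouchEvent:
    """A single touch at a point on the screen, on the session clock."""

    time_s: float
    x_px: float
    y_px: float

    def __post_init__(self) -> None:
        if self.time_s < 0:
            raise ConfigurationError(f"touch time must be >= 0, got {self.time_s}")


def _center_bounds(extent_px: int, diameter_px: int) -> tuple[int, int]:
    """Inclusive integer range of centers keeping the dot fully on screen."""
    lo = (diameter_px + 1) // 2  # ceil(radius) for odd diameters
    hi = extent_px - lo
    if hi < lo:
        raise ConfigurationError(
            f"diameter {diameter_px} px does not fit in extent {extent_px} px"
        )
    return lo, hi


def feasible_center_box(
    screen: ScreenSpec, diameter_px: int
) -> tuple[tuple[int, int], tuple[int, int]]:
    """Inclusive (x, y) ranges of on-screen centers for a given diameter."""
    return (
        _center_bounds(screen.width_px, diameter_px),
        _center_bounds(screen.height_px, diameter_px),
    )


def dot_on_screen(dot: DotStimulus, screen: ScreenSpec) -> bool:
    r = dot.radius_px
    return (
        r <= dot.center_x_px <= screen.width_px - r
        and r <= dot.center_y_px <= screen.height_px - r
    )


def _pairwise_clear(
    centers: Sequence[tuple[int, int]],
    diameters: Sequence[int],
    min_gap_px: float,
) -> bool:
    for i in range(len(centers)):
        for j in range(i + 1, len(centers)):
            dx = centers[i][0] - centers[j][0]
            dy = centers[i][1] - centers[j][1]
            required = (diameters[i] + diameters[j]) / 2.0 + min_gap_px
            if math.hypot(dx, dy) <= required:
                return False
    return True


def sample_dot_placement(
    screen: ScreenSpec,
    diameters: Sequence[int],
    min_gap_px: float = 0.0,
    rng: np.random.Generator | None = None,
    max_attempts: int = DEFAULT_ATTEMPT_BUDGET,
) -> list[DotStimulus]:
    """Place dots uniformly at random, fully on screen and non-overlapping.

    Centers are drawn uniformly (integer pixels) over the feasible box for
    each diameter; configurations where any pair of dots overlaps (center
    distance <= sum of radii + ``min_gap_px``) are rejected and redrawn.

    Raises
    ------
    ConfigurationError
        If a diameter cannot fit on the screen.
    PlacementError
        If no clear configuration is found within ``max_attempts`` draws.
    """
    if rng is None:
        rng = np.random.default_rng()
    boxes = [feasible_center_box(screen, d) for d in diameters]
    for _ in range(max_attempts):
        centers = [
            (int(rng.integers(bx[0], bx[1] + 1)), int(rng.integers(by[0], by[1] + 1)))
            for (bx, by) in boxes
        ]
        if _pairwise_clear(centers, diameters, min_gap_px):
            return [
                DotStimulus(
                    dot_id=f"d{i + 1}",
                    center_x_px=cx,
                    center_y_px=cy,
                    diameter_px=d,
                )
                for i, ((cx, cy), d) in enumerate(zip(centers, diameters))
            ]
    raise PlacementError(
        f"no non-overlapping placement for diameters {list(diameters)} on "
        f"{screen.width_px}x{screen.height_px} within {max_attempts} attempts"
    )


def hit_test(dot: DotStimulus, touch: TouchEvent) -> bool:
    """True iff the touch lands on the visible dot (boundary inclusive).

    The numeral label plays no role: the hit region is the full disc.
    """
    if not dot.visible:
        return False
    dist = math.hypot(touch.x_px - dot.center_x_px, touch.y_px - dot.center_y_px)
    return dist <= dot.radius_px
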