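"""The 95-session shaping schedule and forced-choice trial sequencing.

The training ladder shrinks a single dot over ten sessions, adds a second
dot for five sessions, then runs the ordered two-number task for eighty
sessions, the last fifty-five of which interleave forced-choice trials
(only the "1" dot shown) at a 25% rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, List

import numpy as np

from .errors import ConfigurationError

__all__ = [
    "TASKS",
    "CurriculumStage",
    "Curriculum",
    "build_training_curriculum",
    "stage_for_session",
    "generate_trial_sequence",
    "forced_flag_stream",
]

TASKS = ("one_dot", "two_dot", "two_number_dot")

#: trials per balancing window; exactly one forced trial per full window
FORCED_WINDOW = 4


@dataclass(frozen=True)
class CurriculumStage:
    """One rung of the shaping ladder."""

    task: str
    n_sessions: int
    dot_diameter_px: int = 100
    forced_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.task not in TASKS:
            raise ConfigurationError(f"unknown task {self.task!r}")
        if self.n_sessions < 1:
            raise ConfigurationError("n_sessions must be >= 1")
        if not 0.0 <= self.forced_fraction <= 1.0:
            raise ConfigurationError("forced_fraction must lie in [0, 1]")
        if self.forced_fraction > 0 and self.task != "two_number_dot":
            raise ConfigurationError(
                "forced trials only exist in the two_number_dot task"
            )
        if self.dot_diameter_px <= 0:
            raise ConfigurationError("dot_diameter_px must be positive")


@dataclass(frozen=True)
class Curriculum:
    stages: tuple[CurriculumStage, ...]

    @property
    def total_sessions(self) -> int:
        return sum(s.n_sessions for s in self.stages)

    def __iter__(self) -> Iterator[CurriculumStage]:
        return iter(self.stages)


def build_training_curriculum() -> Curriculum:
    """The full 95-session training schedule.

    One Dot with diameters 550/400/200/100 px for 3/2/2/3 sessions, Two Dot
    for five sessions, then Two Number Dot for 25 sessions without and 55
    sessions with forced-choice trials.
    """
    return Curriculum(
        stages=(
            CurriculumStage("one_dot", 3, dot_diameter_px=550),
            CurriculumStage("one_dot", 2, dot_diameter_px=400),
            CurriculumStage("one_dot", 2, dot_diameter_px=200),
            CurriculumStage("one_dot", 3, dot_diameter_px=100),
            CurriculumStage("two_dot", 5),
            CurriculumStage("two_number_dot", 25, forced_fraction=0.0),
            CurriculumStage("two_number_dot", 55, forced_fraction=0.25),
        )
    )


def stage_for_session(curriculum: Curriculum, session_index: int) -> CurriculumStage:
    """Stage covering a 1-based session index under cumulative ordering."""
    if session_index < 1:
        raise IndexError(f"session_index must be >= 1, got {session_index}")
    upper = 0
    for stage in curriculum.stages:
        upper += stage.n_sessions
        if session_index <= upper:
            return stage
    raise IndexError(
        f"session_index {session_index} exceeds curriculum length {upper}"
    )


def forced_flag_stream(
    forced_fraction: float, rng: np.random.Generator
) -> Iterator[bool]:
    """Infinite stream of forced flags, balanced per window.

    Each consecutive window of ``FORCED_WINDOW`` trials carries exactly one
    forced trial at a uniformly random position (for fraction 0.25); a zero
    fraction yields no forced trials.  Fractions other than 0 or 0.25 fall
    back to per-window counts of round(fraction * window).
    """
    if forced_fraction == 0.0:
        while True:
            yield False
    n_forced = round(forced_fraction * FORCED_WINDOW)
    while True:
        positions = rng.choice(FORCED_WINDOW, size=n_forced, replace=False)
        window = [False] * FORCED_WINDOW
        for p in positions:
            window[int(p)] = True
        yield from window


def generate_trial_sequence(
    stage: CurriculumStage, n_trials: int, rng: np.random.Generator
) -> List["TrialSpec"]:
    """Trial specs for a stage with windowed forced-choice balancing.

    Full windows of ``FORCED_WINDOW`` trials each contain exactly one forced
    trial at a uniform position; a trailing partial window marks each trial
    forced independently with probability ``forced_fraction``.  Stimuli are
    left unplaced (the session runner places them per trial).
    """
    from .engine import TrialSpec  # deferred: engine imports this module

    if n_trials < 0:
        raise ConfigurationError("n_trials must be >= 0")
    flags: list[bool] = []
    if stage.forced_fraction == 0.0:
        flags = [False] * n_trials
    else:
        stream = forced_flag_stream(stage.forced_fraction, rng)
        n_full = (n_trials // FORCED_WINDOW) * FORCED_WINDOW
        flags = [next(stream) for _ in range(n_full)]
        flags += [
            bool(rng.random() < stage.forced_fraction)
            for _ in range(n_trials - n_full)
        ]
    return [
        TrialSpec(
            task=stage.task,
            trial_index=i + 1,
            stimuli=[],
            forced=flag,
            dot_diameter_px=stage.dot_diameter_px,
        )
        for i, flag in enumerate(flags)
    ]
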