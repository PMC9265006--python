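"""Discrete-trial state machines and the timed session runner.

Three tasks share one trial loop:

* ``one_dot`` — a single unlabeled dot; the first hit completes the trial.
* ``two_dot`` — two unlabeled dots; each hit hides its dot and the trial is
  correct once both are hidden, in either order.
* ``two_number_dot`` — dots labeled "1" and "2"; "1" must be hit first.
  Hitting "2" first ends the trial immediately as incorrect.  Forced trials
  show only the "1" dot and cannot be answered incorrectly.

Touches that land on no visible dot are logged but change nothing.  A
correct trial emits chime + green LED + pellet; an incorrect one emits
buzzer + red LED; a trial with no decisive touch before the per-trial
timeout is aborted with no feedback.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Protocol, Sequence, Tuple

import numpy as np

from .curriculum import CurriculumStage, forced_flag_stream
from .errors import SpecificationError
from .geometry import (
    DotStimulus,
    ScreenSpec,
    TouchEvent,
    hit_test,
    sample_dot_placement,
)

__all__ = [
    "FEEDBACK_KINDS",
    "TrialSpec",
    "FeedbackEvent",
    "TrialResult",
    "SessionSpec",
    "SessionLog",
    "Agent",
    "PlannedTouch",
    "run_trial",
    "run_session",
    "run_session_queue",
]

FEEDBACK_KINDS = (
    "session_start_chime",
    "chime",
    "buzzer",
    "led_green",
    "led_red",
    "led_blue",  # reserved by the hardware; unused by the dot tasks
    "pellet",
)

DEFAULT_SESSION_DURATION_S = 600.0
DEFAULT_ITI_S = 3.0
DEFAULT_MAX_TRIAL_DURATION_S = 60.0

#: clock granularity; every touch and trial onset consumes at least one tick,
#: which bounds throughput even under degenerate zero-latency timing
CLOCK_TICK_S = 0.001


@dataclass
class TrialSpec:
    """What a single trial presents."""

    task: str
    trial_index: int
    stimuli: List[DotStimulus]
    forced: bool = False
    dot_diameter_px: int = 100


@dataclass(frozen=True)
class FeedbackEvent:
    kind: str
    time_s: float

    def __post_init__(self) -> None:
        if self.kind not in FEEDBACK_KINDS:
            raise SpecificationError(f"unknown feedback kind {self.kind!r}")


@dataclass
class TrialResult:
    """What happened during one trial."""

    trial_index: int
    task: str
    forced: bool
    outcome: str  # "correct" | "incorrect" | "aborted"
    rewarded: bool
    touches: List[Tuple[TouchEvent, Optional[str]]]
    response_latency_s: Optional[float]
    onset_s: float
    end_s: float
    stimuli: List[DotStimulus] = field(default_factory=list)


@dataclass
class SessionSpec:
    """Parameters of one timed session."""

    session_index: int = 1
    stage: CurriculumStage = field(
        default_factory=lambda: CurriculumStage("one_dot", 1, dot_diameter_px=100)
    )
    duration_s: float = DEFAULT_SESSION_DURATION_S
    iti_s: float = DEFAULT_ITI_S
    max_trial_duration_s: float = DEFAULT_MAX_TRIAL_DURATION_S
    seed: int = 0
    group_id: str = "sim"
    screen: ScreenSpec = field(default_factory=ScreenSpec)

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise SpecificationError("duration_s must be > 0")
        if self.iti_s < 0:
            raise SpecificationError("iti_s must be >= 0")


@dataclass
class SessionLog:
    spec: SessionSpec
    trials: List[TrialResult]
    events: List[FeedbackEvent]

    @property
    def task(self) -> str:
        return self.spec.stage.task


@dataclass(frozen=True)
class PlannedTouch:
    """An agent's next touch: delay after the previous event, and location."""

    dt_s: float
    x_px: float
    y_px: float


class Agent(Protocol):
    """Simulated-subject contract used by the trial loop."""

    def begin_trial(self, spec: TrialSpec, screen: ScreenSpec) -> None: ...

    def next_touch(
        self,
        visible: Sequence[DotStimulus],
        screen: ScreenSpec,
        elapsed_s: float,
    ) -> Optional[PlannedTouch]: ...

    def end_trial(self, result: TrialResult) -> None: ...


def validate_trial_spec(spec: TrialSpec) -> None:
    """Check structural invariants of a fully placed trial spec."""
    labels = [d.label for d in spec.stimuli]
    if spec.task == "one_dot":
        if len(spec.stimuli) != 1 or labels != [None]:
            raise SpecificationError("one_dot requires exactly 1 unlabeled dot")
        if spec.forced:
            raise SpecificationError("one_dot has no forced trials")
    elif spec.task == "two_dot":
        if len(spec.stimuli) != 2 or labels != [None, None]:
            raise SpecificationError("two_dot requires exactly 2 unlabeled dots")
        if spec.forced:
            raise SpecificationError("two_dot has no forced trials")
    elif spec.task == "two_number_dot":
        if spec.forced:
            if labels != ["1"]:
                raise SpecificationError(
                    "forced two_number_dot requires a single dot labeled '1'"
                )
        elif sorted(x or "" for x in labels) != ["1", "2"]:
            raise SpecificationError(
                "two_number_dot requires dots labeled '1' and '2'"
            )
    else:
        raise SpecificationError(f"unknown task {spec.task!r}")


def _required_count(spec: TrialSpec) -> int:
    return 1 if (spec.task == "one_dot" or spec.forced) else 2


def run_trial(
    spec: TrialSpec,
    agent: Agent,
    screen: ScreenSpec,
    onset_s: float = 0.0,
    max_trial_duration_s: float = DEFAULT_MAX_TRIAL_DURATION_S,
) -> Tuple[TrialResult, List[FeedbackEvent]]:
    """Run one trial's state machine against an agent.

    Returns the trial result and the feedback events it generated (stamped
    on the session clock).  The trial aborts with no feedback if no decisive
    touch arrives within ``max_trial_duration_s`` of onset.
    """
    validate_trial_spec(spec)
    agent.begin_trial(spec, screen)

    hidden: set[str] = set()
    touches: List[Tuple[TouchEvent, Optional[str]]] = []
    deadline = onset_s + max_trial_duration_s
    now = onset_s
    outcome: Optional[str] = None
    end_s = deadline

    while outcome is None:
        visible = [d for d in spec.stimuli if d.dot_id not in hidden]
        planned = agent.next_touch(visible, screen, now - onset_s)
        if planned is None:
            outcome = "aborted"
            end_s = deadline
            break
        dt = max(planned.dt_s, CLOCK_TICK_S)
        if now + dt > deadline:
            outcome = "aborted"
            end_s = deadline
            break
        now += dt
        touch = TouchEvent(time_s=now, x_px=planned.x_px, y_px=planned.y_px)
        hit = next((d for d in visible if hit_test(d, touch)), None)
        touches.append((touch, hit.dot_id if hit else None))
        if hit is None:
            continue  # background touches never change state
        if spec.task == "two_number_dot" and not spec.forced:
            if hit.label == "2" and any(
                d.label == "1" and d.dot_id not in hidden for d in spec.stimuli
            ):
                outcome = "incorrect"
                end_s = now
                break
        hidden.add(hit.dot_id)
        if len(hidden) == _required_count(spec):
            outcome = "correct"
            end_s = now

    events: List[FeedbackEvent] = []
    if outcome == "correct":
        events = [
            FeedbackEvent("chime", end_s),
            FeedbackEvent("led_green", end_s),
            FeedbackEvent("pellet", end_s),
        ]
    elif outcome == "incorrect":
        events = [FeedbackEvent("buzzer", end_s), FeedbackEvent("led_red", end_s)]

    first_touch = touches[0][0].time_s if touches else None
    result = TrialResult(
        trial_index=spec.trial_index,
        task=spec.task,
        forced=spec.forced,
        outcome=outcome,
        rewarded=outcome == "correct",
        touches=touches,
        response_latency_s=None if first_touch is None else first_touch - onset_s,
        onset_s=onset_s,
        end_s=end_s,
        stimuli=list(spec.stimuli),
    )
    agent.end_trial(result)
    return result, events


def _place_trial_stimuli(
    task: str,
    forced: bool,
    diameter_px: int,
    screen: ScreenSpec,
    rng: np.random.Generator,
) -> List[DotStimulus]:
    if task == "one_dot":
        return sample_dot_placement(screen, [diameter_px], rng=rng)
    if task == "two_dot":
        return sample_dot_placement(screen, [diameter_px, diameter_px], rng=rng)
    if forced:
        dots = sample_dot_placement(screen, [diameter_px], rng=rng)
        dots[0].label = "1"
        return dots
    dots = sample_dot_placement(screen, [diameter_px, diameter_px], rng=rng)
    # which dot carries the "1" is itself randomized
    order = ["1", "2"] if rng.random() < 0.5 else ["2", "1"]
    for dot, label in zip(dots, order):
        dot.label = label
    return dots


def run_session(spec: SessionSpec, agent: Agent) -> SessionLog:
    """Run one timed session.

    The session chime sounds at t = 0 together with the first trial's onset;
    trials are separated by the inter-trial interval; no trial starts at or
    after ``duration_s``, but a trial in flight at the cutoff completes.
    Stimuli are freshly placed for every trial.  Given a seed and a
    deterministic agent the log is fully reproducible.
    """
    rng = np.random.default_rng(spec.seed)
    stage = spec.stage
    flags = forced_flag_stream(stage.forced_fraction, rng)

    events: List[FeedbackEvent] = [FeedbackEvent("session_start_chime", 0.0)]
    trials: List[TrialResult] = []
    t = 0.0
    index = 1
    while t < spec.duration_s:
        forced = next(flags)
        stimuli = _place_trial_stimuli(
            stage.task, forced, stage.dot_diameter_px, spec.screen, rng
        )
        trial_spec = TrialSpec(
            task=stage.task,
            trial_index=index,
            stimuli=stimuli,
            forced=forced,
            dot_diameter_px=stage.dot_diameter_px,
        )
        result, trial_events = run_trial(
            trial_spec,
            agent,
            spec.screen,
            onset_s=t,
            max_trial_duration_s=spec.max_trial_duration_s,
        )
        trials.append(result)
        events.extend(trial_events)
        t = max(result.end_s + spec.iti_s, t + CLOCK_TICK_S)
        index += 1
    return SessionLog(spec=spec, trials=trials, events=events)


def run_session_queue(
    specs: Iterable[SessionSpec], agent: Agent
) -> List[SessionLog]:
    """Run sessions in order on independent clocks, sharing one agent."""
    return [run_session(spec, agent) for spec in specs]
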