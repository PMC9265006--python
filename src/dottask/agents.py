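"""Simulated subjects that drive the trial engine.

Four agents cover the behaviors the analyses need to see:

* :class:`IdealAgent` — always touches the required stimulus after a fixed
  latency; defines the throughput ceiling.
* :class:`StimulusDirectedRandomAgent` — touches a uniformly chosen visible
  dot; the chance-level oracle for the ordered task (accuracy 0.5).
* :class:`RandomLocationAgent` — touches uniform random screen points; hit
  probability per touch equals the dot-area fraction of the screen.
* :class:`RescorlaWagnerAgent` — a two-action value learner with softmax
  choice, the minimal model that can actually *acquire* the ordered task.

All agents draw every random number from their own seeded generator, so any
seeded agent paired with a seeded session is fully reproducible.

The module also provides a fast standalone choice-sequence simulator and a
likelihood grid-search fitter for synthetic parameter recovery.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import List, NamedTuple, Optional, Sequence, Tuple

import numpy as np

from .engine import PlannedTouch, TrialResult, TrialSpec
from .errors import ConfigurationError
from .geometry import DotStimulus, ScreenSpec

__all__ = [
    "AgentConfig",
    "IdealAgent",
    "StimulusDirectedRandomAgent",
    "RandomLocationAgent",
    "RescorlaWagnerAgent",
    "make_agent",
    "AGENT_NAMES",
    "ChoiceSequence",
    "simulate_choice_sequence",
    "fit_rescorla_wagner",
]


@dataclass(frozen=True)
class AgentConfig:
    """Shared agent parameters; learning fields matter only to the RW agent."""

    latency_mean_s: float = 1.0
    latency_jitter_s: float = 0.0
    learning_rate: float = 0.1  # alpha in [0, 1]
    inverse_temperature: float = 5.0  # beta >= 0
    value_touch1_first: float = 0.5  # v0
    value_touch2_first: float = 0.5  # w0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.latency_mean_s < 0 or self.latency_jitter_s < 0:
            raise ConfigurationError("latencies must be >= 0")
        if not 0.0 <= self.learning_rate <= 1.0:
            raise ConfigurationError("learning_rate must lie in [0, 1]")
        if self.inverse_temperature < 0:
            raise ConfigurationError("inverse_temperature must be >= 0")


class _BaseAgent:
    def __init__(self, cfg: AgentConfig | None = None):
        self.cfg = cfg or AgentConfig()
        self.rng = np.random.default_rng(self.cfg.seed)

    def _latency(self) -> float:
        j = self.cfg.latency_jitter_s
        dt = self.cfg.latency_mean_s
        if j > 0:
            dt += self.rng.uniform(-j, j)
        return max(dt, 0.0)

    def begin_trial(self, spec: TrialSpec, screen: ScreenSpec) -> None:
        pass

    def end_trial(self, result: TrialResult) -> None:
        pass


def _lowest_label_first(visible: Sequence[DotStimulus]) -> DotStimulus:
    labeled = [d for d in visible if d.label is not None]
    if labeled:
        return min(labeled, key=lambda d: d.label)
    return visible[0]


def _uniform_point_in_dot(
    dot: DotStimulus, rng: np.random.Generator
) -> Tuple[float, float]:
    r = dot.radius_px * math.sqrt(rng.random())
    theta = rng.uniform(0.0, 2.0 * math.pi)
    return dot.center_x_px + r * math.cos(theta), dot.center_y_px + r * math.sin(theta)


class IdealAgent(_BaseAgent):
    """Touches the currently required stimulus (lowest numeral first)."""

    def next_touch(self, visible, screen, elapsed_s) -> Optional[PlannedTouch]:
        if not visible:
            return None
        target = _lowest_label_first(visible)
        return PlannedTouch(self._latency(), target.center_x_px, target.center_y_px)


class StimulusDirectedRandomAgent(_BaseAgent):
    """Touches a uniformly chosen visible dot at a uniform point within it."""

    def next_touch(self, visible, screen, elapsed_s) -> Optional[PlannedTouch]:
        if not visible:
            return None
        dot = visible[int(self.rng.integers(len(visible)))]
        x, y = _uniform_point_in_dot(dot, self.rng)
        return PlannedTouch(self._latency(), x, y)


class RandomLocationAgent(_BaseAgent):
    """Touches uniform random screen points, oblivious to the stimuli."""

    def next_touch(self, visible, screen, elapsed_s) -> Optional[PlannedTouch]:
        x = self.rng.uniform(0.0, screen.width_px)
        y = self.rng.uniform(0.0, screen.height_px)
        return PlannedTouch(self._latency(), x, y)


def _softmax_p1(v: float, w: float, beta: float) -> float:
    """P(choose touch-1-first) under a two-action softmax."""
    return 1.0 / (1.0 + math.exp(-beta * (v - w)))


class RescorlaWagnerAgent(_BaseAgent):
    """Two-action value learner for the ordered two-number task.

    On each choice trial the agent picks "touch-1-first" with softmax
    probability exp(beta*v) / (exp(beta*v) + exp(beta*w)) and afterwards
    updates the chosen action's value by value += alpha * (reward - value).
    Forced trials reward and update the "touch-1-first" value.  On the
    simpler tasks the agent behaves ideally (they have no choice to learn).
    """

    def __init__(self, cfg: AgentConfig | None = None):
        super().__init__(cfg)
        self.v = self.cfg.value_touch1_first
        self.w = self.cfg.value_touch2_first
        self._action: Optional[str] = None

    def begin_trial(self, spec: TrialSpec, screen: ScreenSpec) -> None:
        self._action = None
        if spec.task == "two_number_dot" and not spec.forced:
            p1 = _softmax_p1(self.v, self.w, self.cfg.inverse_temperature)
            self._action = "1" if self.rng.random() < p1 else "2"

    def next_touch(self, visible, screen, elapsed_s) -> Optional[PlannedTouch]:
        if not visible:
            return None
        if self._action == "2":
            target = next((d for d in visible if d.label == "2"), visible[0])
        else:
            target = _lowest_label_first(visible)
        return PlannedTouch(self._latency(), target.center_x_px, target.center_y_px)

    def end_trial(self, result: TrialResult) -> None:
        if result.task != "two_number_dot" or result.outcome == "aborted":
            return
        alpha = self.cfg.learning_rate
        r = 1.0 if result.rewarded else 0.0
        if result.forced or self._action == "1":
            self.v += alpha * (r - self.v)
        elif self._action == "2":
            self.w += alpha * (r - self.w)


AGENT_NAMES = {
    "ideal": IdealAgent,
    "stimulus-random": StimulusDirectedRandomAgent,
    "random-location": RandomLocationAgent,
    "rw": RescorlaWagnerAgent,
}


def make_agent(name: str, cfg: AgentConfig | None = None) -> _BaseAgent:
    try:
        cls = AGENT_NAMES[name]
    except KeyError:
        raise ConfigurationError(
            f"unknown agent {name!r}; choose from {sorted(AGENT_NAMES)}"
        ) from None
    return cls(cfg)


# ---------------------------------------------------------------------------
# Standalone choice-sequence simulation and parameter recovery
# ---------------------------------------------------------------------------

class ChoiceSequence(NamedTuple):
    """One simulated two-number-dot trial sequence."""

    actions: List[str]  # "1" (correct first touch) or "2"; forced trials "1"
    rewards: List[int]
    forced: List[bool]
    #: probability of a correct choice at each trial *before* the draw; this
    #: is the trial's expected accuracy, an exact (zero-variance) stand-in
    #: for the realized 0/1 outcome.  Forced trials carry 1.0.
    p_correct: List[float]


def simulate_choice_sequence(
    cfg: AgentConfig,
    n_trials: int,
    forced_mask: Sequence[bool] | None = None,
    rng: np.random.Generator | None = None,
) -> ChoiceSequence:
    """Simulate the RW agent's two-number-dot trial sequence directly.

    Bypasses the screen/timing machinery: choosing "1" first is always
    rewarded, choosing "2" first never is, and forced trials reward the
    "touch-1-first" action.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    if forced_mask is None:
        forced_mask = [False] * n_trials
    v, w = cfg.value_touch1_first, cfg.value_touch2_first
    alpha, beta = cfg.learning_rate, cfg.inverse_temperature
    actions: List[str] = []
    rewards: List[int] = []
    probs: List[float] = []
    for forced in forced_mask:
        if forced:
            action, r = "1", 1
            probs.append(1.0)
            v += alpha * (r - v)
        else:
            p1 = _softmax_p1(v, w, beta)
            probs.append(p1)
            action = "1" if rng.random() < p1 else "2"
            r = 1 if action == "1" else 0
            if action == "1":
                v += alpha * (r - v)
            else:
                w += alpha * (r - w)
        actions.append(action)
        rewards.append(r)
    return ChoiceSequence(actions, rewards, list(forced_mask), probs)


def _choice_log_likelihood(
    actions: Sequence[str],
    rewards: Sequence[int],
    forced: Sequence[bool],
    alpha: float,
    beta: float,
    v0: float = 0.5,
    w0: float = 0.5,
) -> float:
    """Log-likelihood of choice trials under the RW/softmax model."""
    v, w = v0, w0
    ll = 0.0
    for action, r, f in zip(actions, rewards, forced):
        if f:
            v += alpha * (1.0 - v)
            continue
        p1 = _softmax_p1(v, w, beta)
        p = p1 if action == "1" else 1.0 - p1
        ll += math.log(max(p, 1e-300))
        if action == "1":
            v += alpha * (r - v)
        else:
            w += alpha * (r - w)
    return ll


def fit_rescorla_wagner(
    sequences: Sequence[ChoiceSequence | Tuple[Sequence[str], Sequence[int], Sequence[bool]]],
    alpha_grid: Sequence[float],
    beta_grid: Sequence[float],
    v0: float = 0.5,
    w0: float = 0.5,
) -> Tuple[float, float, float]:
    """Grid-search maximum likelihood over (alpha, beta), pooling sequences.

    Returns (alpha_hat, beta_hat, max log-likelihood).
    """
    best = (-math.inf, None, None)
    for alpha in alpha_grid:
        for beta in beta_grid:
            ll = sum(
                _choice_log_likelihood(s[0], s[1], s[2], alpha, beta, v0, w0)
                for s in sequences
            )
            if ll > best[0]:
                best = (ll, alpha, beta)
    return best[1], best[2], best[0]
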