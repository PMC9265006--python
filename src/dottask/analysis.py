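"""Engagement and performance analyses over session logs.

Engagement is measured as completed trials per minute.  Performance on the
ordered two-number task is scored over consecutive blocks of sessions:
choice trials are pooled across each block, forced and aborted trials are
excluded, and each block's proportion correct is tested against chance with
an exact binomial test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

from .engine import SessionLog
from .errors import ConfigurationError

__all__ = [
    "AnalysisConfig",
    "BlockPerformance",
    "trials_per_minute",
    "engagement_table",
    "block_performance",
    "binomial_test_vs_chance",
]


@dataclass(frozen=True)
class AnalysisConfig:
    block_size_sessions: int = 5
    chance_level: float = 0.5
    test_sidedness: str = "greater"  # or "two_sided"
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not 0.0 < self.chance_level < 1.0:
            raise ConfigurationError("chance_level must lie in (0, 1)")
        if self.block_size_sessions < 1:
            raise ConfigurationError("block_size_sessions must be >= 1")
        if self.test_sidedness not in ("greater", "two_sided"):
            raise ConfigurationError("test_sidedness must be greater or two_sided")


@dataclass(frozen=True)
class BlockPerformance:
    block_index: int
    session_range: Tuple[int, int]  # inclusive first/last session index
    n_choice_trials: int
    n_correct: int
    proportion_correct: Optional[float]
    p_value: Optional[float]
    above_chance: bool
    partial: bool  # trailing block with fewer than block_size sessions


def trials_per_minute(log: SessionLog) -> float:
    """Completed (non-aborted) trials divided by session minutes."""
    if log.spec.duration_s <= 0:
        raise ConfigurationError("session duration must be > 0")
    completed = sum(1 for t in log.trials if t.outcome != "aborted")
    return completed / (log.spec.duration_s / 60.0)


def engagement_table(logs: Sequence[SessionLog]) -> Dict[str, Dict[str, float]]:
    """First- and last-session engagement rate per task.

    Returns {task: {first_session, last_session, first_rate, last_rate}};
    tasks absent from the logs are omitted.
    """
    if not logs:
        raise ConfigurationError("engagement_table requires at least one session")
    ordered = sorted(logs, key=lambda lg: lg.spec.session_index)
    table: Dict[str, Dict[str, float]] = {}
    for log in ordered:
        task = log.task
        rate = trials_per_minute(log)
        idx = log.spec.session_index
        if task not in table:
            table[task] = {
                "first_session": idx,
                "last_session": idx,
                "first_rate": rate,
                "last_rate": rate,
            }
        else:
            table[task]["last_session"] = idx
            table[task]["last_rate"] = rate
    return table


def binomial_test_vs_chance(
    n_correct: int,
    n: int,
    chance: float = 0.5,
    sidedness: str = "greater",
) -> float:
    """Exact binomial test p-value by direct summation of point probabilities.

    "greater" sums the upper tail P(X >= n_correct); "two_sided" sums every
    outcome whose point probability does not exceed that of the observed
    count (the standard minlike definition).  No normal approximation.
    """
    if n < 1:
        raise ConfigurationError("n must be >= 1")
    if not 0 <= n_correct <= n:
        raise ConfigurationError(f"n_correct must lie in [0, {n}], got {n_correct}")
    if not 0.0 < chance < 1.0:
        raise ConfigurationError("chance must lie in (0, 1)")
    pmf = [
        math.comb(n, k) * chance**k * (1.0 - chance) ** (n - k) for k in range(n + 1)
    ]
    if sidedness == "greater":
        p = sum(pmf[n_correct:])
    elif sidedness == "two_sided":
        threshold = pmf[n_correct] * (1.0 + 1e-9)  # guard float ties
        p = sum(q for q in pmf if q <= threshold)
    else:
        raise ConfigurationError("sidedness must be 'greater' or 'two_sided'")
    return min(p, 1.0)


def block_performance(
    logs: Sequence[SessionLog],
    cfg: AnalysisConfig | None = None,
) -> List[BlockPerformance]:
    """Block-wise accuracy on choice trials with exact tests against chance.

    Sessions of the ordered two-number task are grouped, in order, into
    consecutive non-overlapping blocks of ``block_size_sessions``; a
    trailing shorter block is flagged partial.  Forced and aborted trials
    contribute to neither count; a block with zero choice trials reports
    missing proportion and p-value.
    """
    cfg = cfg or AnalysisConfig()
    ordered = [lg for lg in logs if lg.task == "two_number_dot"]
    ordered.sort(key=lambda lg: lg.spec.session_index)
    size = cfg.block_size_sessions
    blocks: List[BlockPerformance] = []
    for b, start in enumerate(range(0, len(ordered), size), start=1):
        chunk = ordered[start : start + size]
        n_choice = 0
        n_correct = 0
        for log in chunk:
            for trial in log.trials:
                if trial.forced or trial.outcome == "aborted":
                    continue
                n_choice += 1
                n_correct += trial.outcome == "correct"
        if n_choice > 0:
            proportion = n_correct / n_choice
            p = binomial_test_vs_chance(
                n_correct, n_choice, cfg.chance_level, cfg.test_sidedness
            )
            above = p <= cfg.alpha
        else:
            proportion = None
            p = None
            above = False
        blocks.append(
            BlockPerformance(
                block_index=b,
                session_range=(
                    chunk[0].spec.session_index,
                    chunk[-1].spec.session_index,
                ),
                n_choice_trials=n_choice,
                n_correct=n_correct,
                proportion_correct=proportion,
                p_value=p,
                above_chance=above,
                partial=len(chunk) < size,
            )
        )
    return blocks
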