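"""JSON protocol configuration: screen, timing and curriculum sections.

All sections are optional; missing ones fall back to the built-in defaults
(1024x768 screen, 600 s sessions with a 3 s inter-trial interval, and the
standard 95-session training curriculum).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

from .curriculum import Curriculum, CurriculumStage, build_training_curriculum
from .engine import (
    DEFAULT_ITI_S,
    DEFAULT_MAX_TRIAL_DURATION_S,
    DEFAULT_SESSION_DURATION_S,
)
from .errors import ConfigurationError
from .geometry import ScreenSpec

__all__ = ["ProtocolConfig", "load_config", "curriculum_to_json", "curriculum_from_json"]


@dataclass(frozen=True)
class ProtocolConfig:
    screen: ScreenSpec = field(default_factory=ScreenSpec)
    min_gap_px: float = 0.0
    duration_s: float = DEFAULT_SESSION_DURATION_S
    iti_s: float = DEFAULT_ITI_S
    max_trial_duration_s: float = DEFAULT_MAX_TRIAL_DURATION_S
    curriculum: Curriculum = field(default_factory=build_training_curriculum)


def curriculum_to_json(curriculum: Curriculum) -> list[dict]:
    return [
        {
            "task": s.task,
            "n_sessions": s.n_sessions,
            "dot_diameter_px": s.dot_diameter_px,
            "forced_fraction": s.forced_fraction,
        }
        for s in curriculum.stages
    ]


def curriculum_from_json(items: list[dict]) -> Curriculum:
    try:
        return Curriculum(tuple(CurriculumStage(**item) for item in items))
    except TypeError as exc:
        raise ConfigurationError(f"bad curriculum entry: {exc}") from exc


def load_config(path) -> ProtocolConfig:
    try:
        raw = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ConfigurationError(f"{path}: invalid JSON ({exc.msg})") from exc
    screen_raw = raw.get("screen", {})
    screen = ScreenSpec(
        width_px=screen_raw.get("width_px", 1024),
        height_px=screen_raw.get("height_px", 768),
    )
    timing = raw.get("timing", {})
    curriculum = (
        curriculum_from_json(raw["curriculum"])
        if "curriculum" in raw
        else build_training_curriculum()
    )
    return ProtocolConfig(
        screen=screen,
        min_gap_px=screen_raw.get("min_gap_px", 0.0),
        duration_s=timing.get("duration_s", DEFAULT_SESSION_DURATION_S),
        iti_s=timing.get("iti_s", DEFAULT_ITI_S),
        max_trial_duration_s=timing.get(
            "max_trial_duration_s", DEFAULT_MAX_TRIAL_DURATION_S
        ),
        curriculum=curriculum,
    )
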