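import numpy as np
import pytest

from dottask.agents import AgentConfig, IdealAgent, StimulusDirectedRandomAgent
from dottask.curriculum import CurriculumStage, build_training_curriculum
from dottask.engine import SessionSpec
from dottask.geometry import ScreenSpec


@pytest.fixture
def screen() -> ScreenSpec:
    return ScreenSpec()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture
def curriculum():
    return build_training_curriculum()


@pytest.fixture
def one_dot_stage() -> CurriculumStage:
    return CurriculumStage("one_dot", 1, dot_diameter_px=100)


@pytest.fixture
def choice_stage() -> CurriculumStage:
    return CurriculumStage("two_number_dot", 1, forced_fraction=0.0)


@pytest.fixture
def forced_stage() -> CurriculumStage:
    return CurriculumStage("two_number_dot", 1, forced_fraction=0.25)


@pytest.fixture
def ideal_agent() -> IdealAgent:
    return IdealAgent(AgentConfig(latency_mean_s=1.0, seed=0))


@pytest.fixture
def stimulus_random_agent() -> StimulusDirectedRandomAgent:
    return StimulusDirectedRandomAgent(AgentConfig(latency_mean_s=1.0, seed=0))


def make_session_spec(stage, **overrides) -> SessionSpec:
    defaults = dict(session_index=1, stage=stage, seed=7, group_id="testgrp")
    defaults.update(overrides)
    return SessionSpec(**defaults)
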