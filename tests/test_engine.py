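import math

import numpy as np
import pytest

from dottask.agents import (
    AgentConfig,
    IdealAgent,
    RandomLocationAgent,
    StimulusDirectedRandomAgent,
)
from dottask.curriculum import CurriculumStage
from dottask.engine import (
    PlannedTouch,
    SessionSpec,
    TrialSpec,
    run_session,
    run_session_queue,
    run_trial,
    validate_trial_spec,
)
from dottask.errors import SpecificationError
from dottask.geometry import DotStimulus, ScreenSpec

from conftest import make_session_spec


def labeled_pair(d=100):
    return [
        DotStimulus("d1", 300, 300, d, label="1"),
        DotStimulus("d2", 700, 500, d, label="2"),
    ]


class ScriptedAgent:
    """Touches a fixed list of (dt, x, y) points, then stops responding."""

    def __init__(self, touches):
        self._touches = list(touches)

    def begin_trial(self, spec, screen):
        pass

    def next_touch(self, visible, screen, elapsed_s):
        if not self._touches:
            return None
        return PlannedTouch(*self._touches.pop(0))

    def end_trial(self, result):
        pass


class NoTouchAgent(ScriptedAgent):
    def __init__(self):
        super().__init__([])


class TestRunTrial:
    def test_one_dot_first_hit_is_correct(self, screen):
        spec = TrialSpec("one_dot", 1, [DotStimulus("d1", 512, 384, 100)])
        result, events = run_trial(spec, ScriptedAgent([(1.0, 512, 384)]), screen)
        assert result.outcome == "correct"
        assert result.rewarded
        assert result.response_latency_s == 1.0
        assert [e.kind for e in events] == ["chime", "led_green", "pellet"]

    def test_two_dot_order_free(self, screen):
        dots = [DotStimulus("d1", 300, 300, 100), DotStimulus("d2", 700, 500, 100)]
        spec = TrialSpec("two_dot", 1, dots)
        result, events = run_trial(
            spec, ScriptedAgent([(1.0, 700, 500), (1.0, 300, 300)]), screen
        )
        assert result.outcome == "correct"
        assert [e.kind for e in events] == ["chime", "led_green", "pellet"]
        assert result.end_s == 2.0

    def test_two_number_dot_ordered_touches_correct(self, screen):
        spec = TrialSpec("two_number_dot", 1, labeled_pair())
        result, events = run_trial(
            spec, ScriptedAgent([(1.0, 300, 300), (1.0, 700, 500)]), screen
        )
        assert result.outcome == "correct"
        assert [e.kind for e in events] == ["chime", "led_green", "pellet"]

    def test_two_number_dot_wrong_order_ends_immediately(self, screen):
        spec = TrialSpec("two_number_dot", 1, labeled_pair())
        result, events = run_trial(
            spec, ScriptedAgent([(1.0, 700, 500), (1.0, 300, 300)]), screen
        )
        assert result.outcome == "incorrect"
        assert not result.rewarded
        assert [e.kind for e in events] == ["buzzer", "led_red"]
        assert len(result.touches) == 1  # the second touch never happens
        assert result.end_s == 1.0

    def test_forced_trial_single_touch_correct(self, screen):
        spec = TrialSpec(
            "two_number_dot",
            1,
            [DotStimulus("d1", 512, 384, 100, label="1")],
            forced=True,
        )
        result, events = run_trial(spec, ScriptedAgent([(1.0, 512, 384)]), screen)
        assert result.outcome == "correct"
        assert result.forced
        assert result.rewarded
        assert "pellet" in [e.kind for e in events]

    def test_background_touches_logged_but_ignored(self, screen):
        spec = TrialSpec("one_dot", 1, [DotStimulus("d1", 512, 384, 100)])
        result, _ = run_trial(
            spec, ScriptedAgent([(1.0, 5, 5), (1.0, 10, 10), (1.0, 512, 384)]), screen
        )
        assert result.outcome == "correct"
        assert [hit for _, hit in result.touches] == [None, None, "d1"]
        assert result.response_latency_s == 1.0  # first touch, even off-target

    def test_touch_on_hidden_dot_is_background(self, screen):
        spec = TrialSpec("two_number_dot", 1, labeled_pair())
        result, _ = run_trial(
            spec,
            ScriptedAgent([(1.0, 300, 300), (1.0, 300, 300), (1.0, 700, 500)]),
            screen,
        )
        assert result.outcome == "correct"
        assert [hit for _, hit in result.touches] == ["d1", None, "d2"]

    def test_no_touch_aborts_at_deadline(self, screen):
        spec = TrialSpec("one_dot", 1, [DotStimulus("d1", 512, 384, 100)])
        result, events = run_trial(
            spec, NoTouchAgent(), screen, onset_s=10.0, max_trial_duration_s=60.0
        )
        assert result.outcome == "aborted"
        assert not result.rewarded
        assert events == []
        assert result.end_s == 70.0
        assert result.response_latency_s is None

    def test_malformed_specs_rejected(self, screen):
        bad = [
            TrialSpec("one_dot", 1, labeled_pair()),
            TrialSpec("two_dot", 1, [DotStimulus("d1", 512, 384, 100)]),
            TrialSpec("two_number_dot", 1, [DotStimulus("d1", 1, 1, 9)]),
            TrialSpec("two_number_dot", 1, labeled_pair(), forced=True),
            TrialSpec("no_dot", 1, []),
        ]
        for spec in bad:
            with pytest.raises(SpecificationError):
                validate_trial_spec(spec)


class TestRunSession:
    def test_ideal_one_dot_timeline(self, one_dot_stage, ideal_agent):
        # oracle: trial k starts at (k-1)*(latency+iti); count onsets < 600
        spec = make_session_spec(one_dot_stage)
        log = run_session(spec, ideal_agent)
        period = 1.0 + 3.0
        expected = math.ceil(600.0 / period)
        assert len(log.trials) == expected == 150
        for k, trial in enumerate(log.trials):
            assert trial.onset_s == pytest.approx((k) * period)
            assert trial.outcome == "correct"

    def test_session_chime_first_and_onsets_increasing(self, one_dot_stage, ideal_agent):
        log = run_session(make_session_spec(one_dot_stage), ideal_agent)
        assert log.events[0].kind == "session_start_chime"
        assert log.events[0].time_s == 0.0
        onsets = [t.onset_s for t in log.trials]
        assert all(b > a for a, b in zip(onsets, onsets[1:]))
        assert all(t.onset_s < log.spec.duration_s for t in log.trials)
        assert all(t.end_s >= t.onset_s for t in log.trials)

    def test_trial_in_flight_at_cutoff_completes(self, one_dot_stage):
        # 4 s latency, 10 s session: onsets 0 and 7; the second trial is in
        # flight at the 10 s cutoff and completes at 11 s; no third trial
        agent = IdealAgent(AgentConfig(latency_mean_s=4.0))
        spec = make_session_spec(one_dot_stage, duration_s=10.0, iti_s=3.0)
        log = run_session(spec, agent)
        assert [t.onset_s for t in log.trials] == [0.0, 7.0]
        assert log.trials[-1].end_s == 11.0
        assert log.trials[-1].outcome == "correct"

    def test_never_touching_agent_all_aborted(self, one_dot_stage):
        spec = make_session_spec(
            one_dot_stage, duration_s=600.0, max_trial_duration_s=60.0
        )
        log = run_session(spec, NoTouchAgent())
        assert len(log.trials) == 10  # 60 s abort + 3 s iti -> one per 63 s
        assert all(t.outcome == "aborted" for t in log.trials)
        assert sum(1 for e in log.events if e.kind == "pellet") == 0

    def test_reproducible_with_same_seed(self, choice_stage):
        logs = []
        for _ in range(2):
            agent = StimulusDirectedRandomAgent(AgentConfig(seed=5))
            logs.append(run_session(make_session_spec(choice_stage, seed=11), agent))
        a, b = logs
        assert len(a.trials) == len(b.trials)
        assert [t.outcome for t in a.trials] == [t.outcome for t in b.trials]
        assert [t.touches for t in a.trials] == [t.touches for t in b.trials]
        assert a.events == b.events

    def test_stimuli_freshly_placed_each_trial(self, one_dot_stage, ideal_agent):
        log = run_session(make_session_spec(one_dot_stage), ideal_agent)
        centers = {
            (t.stimuli[0].center_x_px, t.stimuli[0].center_y_px) for t in log.trials
        }
        assert len(centers) > 100  # 150 independent draws collide rarely

    def test_pellets_equal_correct_trials_random_agents(self, choice_stage):
        for seed in range(3):
            agent = StimulusDirectedRandomAgent(AgentConfig(seed=seed))
            spec = make_session_spec(choice_stage, duration_s=120.0, seed=seed)
            log = run_session(spec, agent)
            pellets = sum(1 for e in log.events if e.kind == "pellet")
            assert pellets == sum(1 for t in log.trials if t.outcome == "correct")

    def test_forced_trials_never_incorrect(self, forced_stage):
        agent = StimulusDirectedRandomAgent(AgentConfig(seed=3))
        log = run_session(make_session_spec(forced_stage, seed=3), agent)
        forced = [t for t in log.trials if t.forced]
        assert forced, "forced stage should schedule forced trials"
        assert all(t.outcome == "correct" for t in forced)

    def test_trial_count_monotone_in_iti_and_latency(self, one_dot_stage):
        counts_by_iti = []
        for iti in (0.0, 2.0, 5.0, 10.0):
            log = run_session(
                make_session_spec(one_dot_stage, iti_s=iti), IdealAgent()
            )
            counts_by_iti.append(len(log.trials))
        assert counts_by_iti == sorted(counts_by_iti, reverse=True)

        counts_by_latency = []
        for latency in (0.5, 1.0, 2.0, 4.0):
            agent = IdealAgent(AgentConfig(latency_mean_s=latency))
            log = run_session(make_session_spec(one_dot_stage), agent)
            counts_by_latency.append(len(log.trials))
        assert counts_by_latency == sorted(counts_by_latency, reverse=True)

    def test_zero_latency_zero_iti_bounded_by_clock_tick(self, one_dot_stage):
        agent = IdealAgent(AgentConfig(latency_mean_s=0.0))
        spec = make_session_spec(one_dot_stage, duration_s=1.0, iti_s=0.0)
        log = run_session(spec, agent)
        assert 0 < len(log.trials) <= 1000  # 1 s / 1 ms tick

    def test_choice_accuracy_near_half_monte_carlo(self, choice_stage):
        # uniform choice between two visible dots -> exact chance 1/2
        agent = StimulusDirectedRandomAgent(AgentConfig(latency_mean_s=0.1, seed=21))
        n_correct = n = 0
        session = 0
        while n < 10_000:
            spec = make_session_spec(
                choice_stage, iti_s=0.0, seed=100 + session, session_index=session + 1
            )
            log = run_session(spec, agent)
            for t in log.trials:
                if t.outcome == "aborted":
                    continue
                n += 1
                n_correct += t.outcome == "correct"
            session += 1
        se = math.sqrt(0.25 / n)
        assert abs(n_correct / n - 0.5) <= 3 * se


class TestRunSessionQueue:
    def test_queue_runs_in_order(self, one_dot_stage, ideal_agent):
        specs = [
            make_session_spec(one_dot_stage, session_index=i, duration_s=20.0)
            for i in (1, 2, 3)
        ]
        logs = run_session_queue(specs, ideal_agent)
        assert [lg.spec.session_index for lg in logs] == [1, 2, 3]

    def test_empty_queue(self, ideal_agent):
        assert run_session_queue([], ideal_agent) == []

    def test_first_ten_curriculum_sessions_are_one_dot(self, curriculum, ideal_agent):
        from dottask.curriculum import stage_for_session

        specs = [
            make_session_spec(
                stage_for_session(curriculum, i),
                session_index=i,
                duration_s=30.0,
                seed=i,
            )
            for i in range(1, 11)
        ]
        logs = run_session_queue(specs, ideal_agent)
        assert len(logs) == 10
        assert all(lg.task == "one_dot" for lg in logs)
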