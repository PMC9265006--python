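# dottask

A headless, fully testable engine for touchscreen "dot task" training with
group-housed primates — trial state machines, a step-by-step shaping
curriculum, feedback/reward event emission, timed session scheduling,
durable trial/event logs, and the engagement/performance analyses — driven
by simulated subjects instead of animals.

## What's inside

| module | role |
|---|---|
| `dottask.geometry` | screen model, dot stimuli, hit-testing, non-overlapping random placement |
| `dottask.engine` | trial state machines for the three tasks, 10-minute session runner, session queues |
| `dottask.curriculum` | the 95-session shaping schedule and forced-choice trial sequencing |
| `dottask.agents` | simulated subjects: ideal, stimulus-random, random-location, Rescorla–Wagner learner (+ likelihood fitting) |
| `dottask.session_io` | CSV trial logs, JSONL event logs, JSON metadata; validation with line-level errors |
| `dottask.analysis` | trials/minute engagement, block-wise accuracy with exact binomial tests vs chance |
| `dottask.config` | JSON protocol configuration (screen, timing, curriculum) |
| `dottask.cli` | the `dottask` command |

The three tasks: **one_dot** (touch the single dot), **two_dot** (touch both
dots, any order), **two_number_dot** (touch "1" then "2"; touching "2" first
is an immediate error). The curriculum shrinks the dot 550→400→200→100 px
over ten sessions, runs two_dot for five, then two_number_dot for eighty —
the final fifty-five with 25% forced-choice trials (only the "1" dot shown,
exactly one per window of four trials).

## CLI

```sh
# print the stage table (95 sessions)
dottask curriculum show

# run sessions 41..95 with a learning agent, write logs
dottask simulate --agent rw --agent-param learning_rate=0.1 \
    --sessions 41..95 --seed 7 --out logs/

# check every persisted session against the log schema
dottask validate logs/

# engagement + block-performance report (and optional plot)
dottask analyze logs/ --out report.json --plot blocks.png
```

A JSON config can override screen geometry, timing and curriculum:

```json
{
  "screen": {"width_px": 1024, "height_px": 768, "min_gap_px": 0},
  "timing": {"duration_s": 600, "iti_s": 3.0, "max_trial_duration_s": 60},
  "curriculum": [
    {"task": "one_dot", "n_sessions": 3, "dot_diameter_px": 550}
  ]
}
```

## Defaults worth knowing

* screen 1024×768 px; hit boundary inclusive; coordinates origin top-left.
* inter-trial interval 3.0 s, ideal-agent latency 1.0 s — an ideal subject
  completes a 600 s one-dot session at exactly 15 trials/min.
* per-trial timeout 60 s → outcome `aborted`, no feedback; a trial in
  flight at the session cutoff completes.
* analysis: blocks of 5 sessions, forced and aborted trials excluded,
  exact one-sided binomial test vs 0.5 at α = 0.05 (two-sided available).
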