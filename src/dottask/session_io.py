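"""Durable text formats for trial logs, feedback events and session metadata.

Trial logs are flat CSV with a fixed column order, feedback events are JSON
lines, and per-session metadata is a small JSON sidecar.  Times are recorded
to millisecond precision on the session clock (t = 0 at session start).
Reading validates every row and reports the offending line number.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, asdict, fields
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

from .curriculum import CurriculumStage
from .engine import (
    FEEDBACK_KINDS,
    FeedbackEvent,
    SessionLog,
    SessionSpec,
    TrialResult,
)
from .errors import LogFormatError
from .geometry import ScreenSpec, TouchEvent

__all__ = [
    "TRIAL_LOG_COLUMNS",
    "TrialLogRecord",
    "EventRecord",
    "records_from_log",
    "write_trial_log",
    "read_trial_log",
    "write_event_log",
    "read_event_log",
    "write_session_dir",
    "read_session_dir",
    "validate_session_dir",
]

TRIAL_LOG_COLUMNS = (
    "group_id",
    "session_index",
    "task",
    "trial_index",
    "forced",
    "outcome",
    "rewarded",
    "onset_s",
    "end_s",
    "response_latency_s",
    "n_touches",
    "dot1_x",
    "dot1_y",
    "dot1_diam",
    "dot1_label",
    "dot2_x",
    "dot2_y",
    "dot2_diam",
    "dot2_label",
    "first_touch_x",
    "first_touch_y",
)

OUTCOMES = ("correct", "incorrect", "aborted")


def _ms(x: float) -> float:
    return round(x, 3)


@dataclass(frozen=True)
class TrialLogRecord:
    """One flat row of the trial CSV."""

    group_id: str
    session_index: int
    task: str
    trial_index: int
    forced: int
    outcome: str
    rewarded: int
    onset_s: float
    end_s: float
    response_latency_s: Optional[float]
    n_touches: int
    dot1_x: int
    dot1_y: int
    dot1_diam: int
    dot1_label: str
    dot2_x: Optional[int]
    dot2_y: Optional[int]
    dot2_diam: Optional[int]
    dot2_label: str
    first_touch_x: Optional[float]
    first_touch_y: Optional[float]


@dataclass(frozen=True)
class EventRecord:
    """One feedback event line of the JSONL event log."""

    kind: str
    time_s: float
    session_index: int


def _record_from_trial(
    trial: TrialResult, group_id: str, session_index: int
) -> TrialLogRecord:
    dots = trial.stimuli
    d1 = dots[0]
    d2 = dots[1] if len(dots) > 1 else None
    first = trial.touches[0][0] if trial.touches else None
    return TrialLogRecord(
        group_id=group_id,
        session_index=session_index,
        task=trial.task,
        trial_index=trial.trial_index,
        forced=int(trial.forced),
        outcome=trial.outcome,
        rewarded=int(trial.rewarded),
        onset_s=_ms(trial.onset_s),
        end_s=_ms(trial.end_s),
        response_latency_s=(
            None if trial.response_latency_s is None else _ms(trial.response_latency_s)
        ),
        n_touches=len(trial.touches),
        dot1_x=d1.center_x_px,
        dot1_y=d1.center_y_px,
        dot1_diam=d1.diameter_px,
        dot1_label=d1.label or "",
        dot2_x=None if d2 is None else d2.center_x_px,
        dot2_y=None if d2 is None else d2.center_y_px,
        dot2_diam=None if d2 is None else d2.diameter_px,
        dot2_label="" if d2 is None else (d2.label or ""),
        first_touch_x=None if first is None else _ms(first.x_px),
        first_touch_y=None if first is None else _ms(first.y_px),
    )


def records_from_log(log: SessionLog) -> List[TrialLogRecord]:
    return [
        _record_from_trial(t, log.spec.group_id, log.spec.session_index)
        for t in log.trials
    ]


def _cell(value) -> str:
    if value is None:
        return ""
    return str(value)


def write_trial_log(log_or_records, path) -> None:
    """Write a session's trials (or a prepared record list) as CSV."""
    records = (
        records_from_log(log_or_records)
        if isinstance(log_or_records, SessionLog)
        else list(log_or_records)
    )
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(TRIAL_LOG_COLUMNS)
        for rec in records:
            d = asdict(rec)
            writer.writerow([_cell(d[c]) for c in TRIAL_LOG_COLUMNS])


def _parse_int(raw: str, col: str, line: int) -> int:
    try:
        return int(raw)
    except ValueError:
        raise LogFormatError(f"column {col}: expected integer, got {raw!r}", line)


def _parse_float(raw: str, col: str, line: int) -> float:
    try:
        return float(raw)
    except ValueError:
        raise LogFormatError(f"column {col}: expected number, got {raw!r}", line)


def _validate_record(rec: TrialLogRecord, line: int) -> None:
    if rec.task not in ("one_dot", "two_dot", "two_number_dot"):
        raise LogFormatError(f"column task: unknown task {rec.task!r}", line)
    if rec.outcome not in OUTCOMES:
        raise LogFormatError(f"column outcome: unknown outcome {rec.outcome!r}", line)
    if rec.forced not in (0, 1):
        raise LogFormatError("column forced: must be 0 or 1", line)
    if rec.rewarded not in (0, 1):
        raise LogFormatError("column rewarded: must be 0 or 1", line)
    if bool(rec.rewarded) != (rec.outcome == "correct"):
        raise LogFormatError(
            f"column rewarded: rewarded={rec.rewarded} inconsistent with "
            f"outcome={rec.outcome!r}",
            line,
        )
    if rec.forced and rec.outcome == "incorrect":
        raise LogFormatError("column outcome: forced trial marked incorrect", line)
    if rec.end_s < rec.onset_s:
        raise LogFormatError("column end_s: trial ends before its onset", line)
    if rec.response_latency_s is not None and rec.response_latency_s < 0:
        raise LogFormatError("column response_latency_s: negative latency", line)


def read_trial_log(path) -> List[TrialLogRecord]:
    """Read and validate a trial CSV; errors name the offending line."""
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise LogFormatError("empty file: missing header row", 1)
        if tuple(header) != TRIAL_LOG_COLUMNS:
            raise LogFormatError(
                f"bad header: expected {list(TRIAL_LOG_COLUMNS)}, got {header}", 1
            )
        records: List[TrialLogRecord] = []
        for lineno, row in enumerate(reader, start=2):
            if len(row) != len(TRIAL_LOG_COLUMNS):
                raise LogFormatError(
                    f"expected {len(TRIAL_LOG_COLUMNS)} fields, got {len(row)}",
                    lineno,
                )
            d = dict(zip(TRIAL_LOG_COLUMNS, row))
            rec = TrialLogRecord(
                group_id=d["group_id"],
                session_index=_parse_int(d["session_index"], "session_index", lineno),
                task=d["task"],
                trial_index=_parse_int(d["trial_index"], "trial_index", lineno),
                forced=_parse_int(d["forced"], "forced", lineno),
                outcome=d["outcome"],
                rewarded=_parse_int(d["rewarded"], "rewarded", lineno),
                onset_s=_parse_float(d["onset_s"], "onset_s", lineno),
                end_s=_parse_float(d["end_s"], "end_s", lineno),
                response_latency_s=(
                    None
                    if d["response_latency_s"] == ""
                    else _parse_float(
                        d["response_latency_s"], "response_latency_s", lineno
                    )
                ),
                n_touches=_parse_int(d["n_touches"], "n_touches", lineno),
                dot1_x=_parse_int(d["dot1_x"], "dot1_x", lineno),
                dot1_y=_parse_int(d["dot1_y"], "dot1_y", lineno),
                dot1_diam=_parse_int(d["dot1_diam"], "dot1_diam", lineno),
                dot1_label=d["dot1_label"],
                dot2_x=(
                    None if d["dot2_x"] == "" else _parse_int(d["dot2_x"], "dot2_x", lineno)
                ),
                dot2_y=(
                    None if d["dot2_y"] == "" else _parse_int(d["dot2_y"], "dot2_y", lineno)
                ),
                dot2_diam=(
                    None
                    if d["dot2_diam"] == ""
                    else _parse_int(d["dot2_diam"], "dot2_diam", lineno)
                ),
                dot2_label=d["dot2_label"],
                first_touch_x=(
                    None
                    if d["first_touch_x"] == ""
                    else _parse_float(d["first_touch_x"], "first_touch_x", lineno)
                ),
                first_touch_y=(
                    None
                    if d["first_touch_y"] == ""
                    else _parse_float(d["first_touch_y"], "first_touch_y", lineno)
                ),
            )
            _validate_record(rec, lineno)
            records.append(rec)
    return records


def write_event_log(events: Sequence[FeedbackEvent], path, session_index: int) -> None:
    """Write feedback events as one JSON object per line."""
    with open(path, "w") as fh:
        for ev in events:
            fh.write(
                json.dumps(
                    {
                        "kind": ev.kind,
                        "time_s": _ms(ev.time_s),
                        "session_index": session_index,
                    }
                )
                + "\n"
            )


def read_event_log(path) -> List[EventRecord]:
    records: List[EventRecord] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            raw = raw.strip()
            if not raw:
                continue
            try:
                obj = json.loads(raw)
            except json.JSONDecodeError as exc:
                raise LogFormatError(f"invalid JSON: {exc.msg}", lineno)
            for key in ("kind", "time_s", "session_index"):
                if key not in obj:
                    raise LogFormatError(f"missing key {key!r}", lineno)
            if obj["kind"] not in FEEDBACK_KINDS:
                raise LogFormatError(f"unknown event kind {obj['kind']!r}", lineno)
            if not isinstance(obj["time_s"], (int, float)) or obj["time_s"] < 0:
                raise LogFormatError("time_s must be a non-negative number", lineno)
            records.append(
                EventRecord(
                    kind=obj["kind"],
                    time_s=float(obj["time_s"]),
                    session_index=int(obj["session_index"]),
                )
            )
    return records


# ---------------------------------------------------------------------------
# Session directories: trials CSV + events JSONL + metadata JSON per session
# ---------------------------------------------------------------------------

def _session_paths(directory: Path, session_index: int) -> Tuple[Path, Path, Path]:
    stem = f"session_{session_index:04d}"
    return (
        directory / f"{stem}_trials.csv",
        directory / f"{stem}_events.jsonl",
        directory / f"{stem}_meta.json",
    )


def write_session_dir(log: SessionLog, directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    trials_path, events_path, meta_path = _session_paths(
        directory, log.spec.session_index
    )
    write_trial_log(log, trials_path)
    write_event_log(log.events, events_path, log.spec.session_index)
    spec = log.spec
    meta = {
        "group_id": spec.group_id,
        "session_index": spec.session_index,
        "task": spec.stage.task,
        "dot_diameter_px": spec.stage.dot_diameter_px,
        "forced_fraction": spec.stage.forced_fraction,
        "duration_s": spec.duration_s,
        "iti_s": spec.iti_s,
        "max_trial_duration_s": spec.max_trial_duration_s,
        "seed": spec.seed,
        "screen": {"width_px": spec.screen.width_px, "height_px": spec.screen.height_px},
    }
    meta_path.write_text(json.dumps(meta, indent=2) + "\n")


def _log_from_records(
    records: Sequence[TrialLogRecord],
    events: Sequence[EventRecord],
    meta: dict,
) -> SessionLog:
    """Rebuild a SessionLog view sufficient for analysis from persisted rows."""
    from .geometry import DotStimulus  # local to avoid cycle at import time

    spec = SessionSpec(
        session_index=meta["session_index"],
        stage=CurriculumStage(
            meta["task"],
            1,
            dot_diameter_px=meta.get("dot_diameter_px", 100),
            forced_fraction=meta.get("forced_fraction", 0.0),
        ),
        duration_s=meta["duration_s"],
        iti_s=meta["iti_s"],
        max_trial_duration_s=meta.get("max_trial_duration_s", 60.0),
        seed=meta.get("seed", 0),
        group_id=meta.get("group_id", "sim"),
        screen=ScreenSpec(**meta.get("screen", {})),
    )
    trials = []
    for rec in records:
        stimuli = [
            DotStimulus("d1", rec.dot1_x, rec.dot1_y, rec.dot1_diam,
                        rec.dot1_label or None)
        ]
        if rec.dot2_x is not None:
            stimuli.append(
                DotStimulus("d2", rec.dot2_x, rec.dot2_y, rec.dot2_diam,
                            rec.dot2_label or None)
            )
        touches = []
        if rec.first_touch_x is not None:
            t0 = rec.onset_s + (rec.response_latency_s or 0.0)
            touches = [(TouchEvent(t0, rec.first_touch_x, rec.first_touch_y), None)]
        trials.append(
            TrialResult(
                trial_index=rec.trial_index,
                task=rec.task,
                forced=bool(rec.forced),
                outcome=rec.outcome,
                rewarded=bool(rec.rewarded),
                touches=touches,
                response_latency_s=rec.response_latency_s,
                onset_s=rec.onset_s,
                end_s=rec.end_s,
                stimuli=stimuli,
            )
        )
    fb = [FeedbackEvent(e.kind, e.time_s) for e in events]
    return SessionLog(spec=spec, trials=trials, events=fb)


def read_session_dir(directory) -> List[SessionLog]:
    """Load every persisted session in a directory, ordered by session index."""
    directory = Path(directory)
    logs = []
    for meta_path in sorted(directory.glob("session_*_meta.json")):
        meta = json.loads(meta_path.read_text())
        trials_path, events_path, _ = _session_paths(directory, meta["session_index"])
        records = read_trial_log(trials_path)
        events = read_event_log(events_path) if events_path.exists() else []
        logs.append(_log_from_records(records, events, meta))
    logs.sort(key=lambda lg: lg.spec.session_index)
    return logs


def validate_session_dir(directory) -> int:
    """Validate every session in a directory; returns the session count."""
    return len(read_session_dir(directory))
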