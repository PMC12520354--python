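"""Session event-log data model, JSON I/O, validation, and timing structure.

One assessment session is a single JSON document (schema ``r2play-session/1``)
holding the participant metadata, the configuration interval (set-up,
customization, baseline measures), every repetition's tap events and pauses,
the post-level check-ins (perceived exertion and symptom response), and the
heart-rate stream.  The HR stream may be stored inline or in a sidecar CSV
(``t_s,bpm``) referenced by relative path.

All timestamps are seconds from session start (floats, no time zones).
"""

from __future__ import annotations

import csv
import json
import os
from dataclasses import dataclass

__all__ = [
    "TapEvent",
    "HRSample",
    "RepetitionRecord",
    "CheckInRecord",
    "Participant",
    "SessionRecord",
    "SessionParseError",
    "read_session",
    "write_session",
    "session_to_json",
    "session_from_json",
    "validate_session",
    "active_windows",
    "duration_breakdown",
]

SCHEMA = "r2play-session/1"

#: HR samples within this many seconds after a repetition ends still count as
#: active assessment (the exertion tail of the effort).
ACTIVE_TAIL_S = 10.0


class SessionParseError(ValueError):
    """Schema violation while reading a session document; names the field."""


@dataclass(frozen=True)
class TapEvent:
    t_s: float
    tablet_id: str
    displayed_character: str
    correct: bool


@dataclass(frozen=True)
class HRSample:
    t_s: float
    bpm: float


@dataclass(frozen=True)
class RepetitionRecord:
    """Executed repetition: interval, taps, and exercise-beep pauses."""

    level_kind: str
    condition: str
    rep_number: int  # 1-based within the level
    start_s: float
    end_s: float
    taps: tuple[TapEvent, ...] = ()
    pause_intervals: tuple[tuple[float, float], ...] = ()

    @property
    def span_s(self) -> float:
        return self.end_s - self.start_s

    @property
    def pause_s(self) -> float:
        return sum(e - s for s, e in self.pause_intervals)

    @property
    def n_correct(self) -> int:
        return sum(1 for t in self.taps if t.correct)

    @property
    def n_errors(self) -> int:
        return sum(1 for t in self.taps if not t.correct)


@dataclass(frozen=True)
class CheckInRecord:
    after_level: str
    rpe: int
    symptom_response: int


@dataclass(frozen=True)
class Participant:
    id: str
    age_years: float
    wheelchair: bool = False


@dataclass(frozen=True)
class SessionRecord:
    participant: Participant
    configuration_interval: tuple[float, float]
    levels: tuple[tuple[str, tuple[RepetitionRecord, ...]], ...]
    hr_stream: tuple[HRSample, ...] = ()
    checkins: tuple[CheckInRecord, ...] = ()
    break_intervals: tuple[tuple[float, float], ...] = ()
    baseline_pcsi_total: int = 0
    resting_hr_bpm: float | None = None
    sus_responses: tuple[int, ...] | None = None

    @property
    def repetitions(self) -> tuple[RepetitionRecord, ...]:
        out: list[RepetitionRecord] = []
        for _, reps in self.levels:
            out.extend(reps)
        return tuple(out)

    def level(self, level_kind: str) -> tuple[RepetitionRecord, ...]:
        for kind, reps in self.levels:
            if kind == level_kind:
                return reps
        raise KeyError(f"session has no level {level_kind!r}")

    def has_level(self, level_kind: str) -> bool:
        return any(kind == level_kind for kind, _ in self.levels)


# ---------------------------------------------------------------------------
# JSON serialization (canonical key order, so round trips are byte-identical)

def _session_doc(session: SessionRecord, hr_csv: str | None = None) -> dict:
    doc: dict = {
        "schema": SCHEMA,
        "participant": {
            "id": session.participant.id,
            "age_years": session.participant.age_years,
            "wheelchair": session.participant.wheelchair,
        },
        "configuration_interval": list(session.configuration_interval),
        "resting_hr_bpm": session.resting_hr_bpm,
        "baseline_pcsi_total": session.baseline_pcsi_total,
        "sus_responses": list(session.sus_responses) if session.sus_responses is not None else None,
        "break_intervals": [list(b) for b in session.break_intervals],
        "levels": [
            {
                "level_kind": kind,
                "repetitions": [
                    {
                        "level_kind": r.level_kind,
                        "condition": r.condition,
                        "rep_number": r.rep_number,
                        "start_s": r.start_s,
                        "end_s": r.end_s,
                        "pause_intervals": [list(p) for p in r.pause_intervals],
                        "taps": [
                            {
                                "t_s": t.t_s,
                                "tablet_id": t.tablet_id,
                                "displayed_character": t.displayed_character,
                                "correct": t.correct,
                            }
                            for t in r.taps
                        ],
                    }
                    for r in reps
                ],
            }
            for kind, reps in session.levels
        ],
        "checkins": [
            {"after_level": c.after_level, "rpe": c.rpe, "symptom_response": c.symptom_response}
            for c in session.checkins
        ],
    }
    if hr_csv is not None:
        doc["hr_csv"] = hr_csv
    else:
        doc["hr_stream"] = [[h.t_s, h.bpm] for h in session.hr_stream]
    return doc


def session_to_json(session: SessionRecord, hr_csv: str | None = None) -> str:
    return json.dumps(_session_doc(session, hr_csv=hr_csv), indent=2) + "\n"


class _Path:
    """Dotted-path bookkeeping for parse errors."""

    def __init__(self, *parts):
        self.parts = parts

    def __truediv__(self, part) -> "_Path":
        return _Path(*self.parts, part)

    def __str__(self) -> str:
        return ".".join(str(p) for p in self.parts) or "<root>"


def _req(obj: dict, key: str, path: _Path):
    if not isinstance(obj, dict) or key not in obj:
        raise SessionParseError(f"{path}: missing field '{key}'")
    return obj[key]


def session_from_json(text: str, hr_loader=None) -> SessionRecord:
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise SessionParseError(f"<root>: invalid JSON ({exc})") from exc
    root = _Path()
    if _req(doc, "schema", root) != SCHEMA:
        raise SessionParseError(f"schema: expected {SCHEMA!r}, got {doc.get('schema')!r}")

    p = _req(doc, "participant", root)
    participant = Participant(
        id=str(_req(p, "id", root / "participant")),
        age_years=float(_req(p, "age_years", root / "participant")),
        wheelchair=bool(_req(p, "wheelchair", root / "participant")),
    )

    cfg = _req(doc, "configuration_interval", root)
    if not (isinstance(cfg, list) and len(cfg) == 2):
        raise SessionParseError("configuration_interval: expected [start_s, end_s]")

    levels = []
    for i, lv in enumerate(_req(doc, "levels", root)):
        lv_path = root / "levels" / i
        reps = []
        for j, r in enumerate(_req(lv, "repetitions", lv_path)):
            r_path = lv_path / "repetitions" / j
            taps = tuple(
                TapEvent(
                    t_s=float(_req(t, "t_s", r_path / "taps" / k)),
                    tablet_id=str(_req(t, "tablet_id", r_path / "taps" / k)),
                    displayed_character=str(_req(t, "displayed_character", r_path / "taps" / k)),
                    correct=bool(_req(t, "correct", r_path / "taps" / k)),
                )
                for k, t in enumerate(_req(r, "taps", r_path))
            )
            reps.append(RepetitionRecord(
                level_kind=str(_req(r, "level_kind", r_path)),
                condition=str(_req(r, "condition", r_path)),
                rep_number=int(_req(r, "rep_number", r_path)),
                start_s=float(_req(r, "start_s", r_path)),
                end_s=float(_req(r, "end_s", r_path)),
                taps=taps,
                pause_intervals=tuple(
                    (float(a), float(b)) for a, b in _req(r, "pause_intervals", r_path)
                ),
            ))
        levels.append((str(_req(lv, "level_kind", lv_path)), tuple(reps)))

    checkins = tuple(
        CheckInRecord(
            after_level=str(_req(c, "after_level", root / "checkins" / i)),
            rpe=int(_req(c, "rpe", root / "checkins" / i)),
            symptom_response=int(_req(c, "symptom_response", root / "checkins" / i)),
        )
        for i, c in enumerate(_req(doc, "checkins", root))
    )

    if "hr_csv" in doc:
        if hr_loader is None:
            raise SessionParseError("hr_csv: sidecar referenced but no loader available")
        hr_stream = hr_loader(doc["hr_csv"])
    else:
        hr_stream = tuple(
            HRSample(t_s=float(t), bpm=float(b)) for t, b in _req(doc, "hr_stream", root)
        )

    sus = doc.get("sus_responses")
    return SessionRecord(
        participant=participant,
        configuration_interval=(float(cfg[0]), float(cfg[1])),
        levels=tuple(levels),
        hr_stream=tuple(hr_stream),
        checkins=checkins,
        break_intervals=tuple((float(a), float(b)) for a, b in doc.get("break_intervals", [])),
        baseline_pcsi_total=int(_req(doc, "baseline_pcsi_total", root)),
        resting_hr_bpm=(None if doc.get("resting_hr_bpm") is None else float(doc["resting_hr_bpm"])),
        sus_responses=tuple(int(v) for v in sus) if sus is not None else None,
    )


def read_hr_csv(path) -> tuple[HRSample, ...]:
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header != ["t_s", "bpm"]:
            raise SessionParseError(f"{path}: HR CSV header must be 't_s,bpm', got {header!r}")
        return tuple(HRSample(t_s=float(row[0]), bpm=float(row[1])) for row in reader)


def write_hr_csv(hr_stream, path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["t_s", "bpm"])
        for h in hr_stream:
            writer.writerow([h.t_s, h.bpm])


def read_session(path) -> SessionRecord:
    """Read a session JSON file, resolving any HR sidecar relative to it."""
    with open(path) as fh:
        text = fh.read()
    base = os.path.dirname(os.path.abspath(path))

    def loader(rel):
        return read_hr_csv(os.path.join(base, rel))

    return session_from_json(text, hr_loader=loader)


def write_session(session: SessionRecord, path, hr_sidecar: bool = False) -> None:
    """Write a session JSON file; optionally split the HR stream into a CSV.

    With ``hr_sidecar`` the stream goes to ``<path stem>_hr.csv`` next to the
    session file and the document references it by relative path.
    """
    violations = validate_session(session)
    if violations:
        first = violations[0]
        raise ValueError(
            f"refusing to write invalid session: {first['invariant']} ({first['detail']})"
        )
    if hr_sidecar:
        stem, _ = os.path.splitext(os.path.basename(path))
        rel = f"{stem}_hr.csv"
        write_hr_csv(session.hr_stream, os.path.join(os.path.dirname(os.path.abspath(path)), rel))
        text = session_to_json(session, hr_csv=rel)
    else:
        text = session_to_json(session)
    with open(path, "w") as fh:
        fh.write(text)


# ---------------------------------------------------------------------------
# Validation

def _violation(invariant: str, location: str, detail: str) -> dict:
    return {"invariant": invariant, "location": location, "detail": detail}


def validate_session(session: SessionRecord) -> list[dict]:
    """Check every structural invariant; violations are data, not exceptions."""
    out: list[dict] = []
    cfg_start, cfg_end = session.configuration_interval
    if cfg_start > cfg_end:
        out.append(_violation("configuration interval inverted", "configuration_interval",
                              f"start {cfg_start} > end {cfg_end}"))

    reps = session.repetitions
    if reps and cfg_end > reps[0].start_s:
        out.append(_violation("configuration precedes first repetition", "configuration_interval",
                              f"configuration ends at {cfg_end} after first repetition start "
                              f"{reps[0].start_s}"))

    prev_end = None
    for i, rep in enumerate(reps):
        loc = f"levels[{rep.level_kind}].repetitions[{rep.rep_number}]"
        if rep.start_s >= rep.end_s:
            out.append(_violation("repetition interval inverted", loc,
                                  f"start {rep.start_s} >= end {rep.end_s}"))
        if prev_end is not None and rep.start_s < prev_end:
            out.append(_violation("repetition intervals overlap", loc,
                                  f"starts at {rep.start_s} before previous end {prev_end}"))
        prev_end = rep.end_s
        last_t = None
        for t in rep.taps:
            if t.t_s < rep.start_s or t.t_s > rep.end_s:
                out.append(_violation("tap outside repetition interval", loc,
                                      f"tap at {t.t_s} outside [{rep.start_s}, {rep.end_s}]"))
            if last_t is not None and t.t_s <= last_t:
                out.append(_violation("tap timestamps not strictly increasing", loc,
                                      f"tap at {t.t_s} after tap at {last_t}"))
            last_t = t.t_s
        prev_pause_end = None
        for ps, pe in rep.pause_intervals:
            if ps >= pe or ps < rep.start_s or pe > rep.end_s:
                out.append(_violation("pause interval outside repetition", loc,
                                      f"pause [{ps}, {pe}] not inside [{rep.start_s}, {rep.end_s}]"))
            if prev_pause_end is not None and ps < prev_pause_end:
                out.append(_violation("pause intervals overlap", loc, f"pause starts at {ps}"))
            prev_pause_end = pe

    last_hr_t = None
    for i, h in enumerate(session.hr_stream):
        if not (30.0 <= h.bpm <= 250.0):
            out.append(_violation("bpm out of physiological range", f"hr_stream[{i}]",
                                  f"bpm {h.bpm} outside [30, 250]"))
        if last_hr_t is not None and h.t_s < last_hr_t:
            out.append(_violation("HR timestamps decreasing", f"hr_stream[{i}]",
                                  f"t_s {h.t_s} before {last_hr_t}"))
        last_hr_t = h.t_s

    for i, c in enumerate(session.checkins):
        if not (0 <= c.rpe <= 10):
            out.append(_violation("rpe out of range", f"checkins[{i}]",
                                  f"rpe {c.rpe} outside [0, 10]"))
        if c.symptom_response not in (1, 2, 3, 4):
            out.append(_violation("symptom response out of range", f"checkins[{i}]",
                                  f"symptom_response {c.symptom_response} not in 1-4"))

    if session.baseline_pcsi_total < 0:
        out.append(_violation("negative PCSI total", "baseline_pcsi_total",
                              f"{session.baseline_pcsi_total} < 0"))
    if session.sus_responses is not None:
        if len(session.sus_responses) != 10 or any(not (1 <= v <= 5) for v in session.sus_responses):
            out.append(_violation("malformed SUS responses", "sus_responses",
                                  f"{session.sus_responses!r}"))
    return out


# ---------------------------------------------------------------------------
# Timing structure

def active_windows(session: SessionRecord, merge: bool = True) -> list[tuple[float, float]]:
    """Active-assessment windows: each repetition span plus a 10 s tail.

    Overlapping windows are merged by default, so the result is sorted and
    disjoint and covers every repetition span.
    """
    windows = sorted((r.start_s, r.end_s + ACTIVE_TAIL_S) for r in session.repetitions)
    if not windows:
        return []
    if not merge:
        return windows
    merged = [windows[0]]
    for s, e in windows[1:]:
        ls, le = merged[-1]
        if s <= le:
            merged[-1] = (ls, max(le, e))
        else:
            merged.append((s, e))
    return merged


def duration_breakdown(session: SessionRecord, convention: str = "span") -> tuple[float, float, float]:
    """(configuration, active, total) assessment durations in minutes (2 dp).

    ``convention="span"`` (default): active time runs from the first
    repetition's start to the last repetition's end, minus any explicitly
    marked break intervals.  ``convention="sum"``: active time is the sum of
    the repetition spans only.
    """
    cfg_start, cfg_end = session.configuration_interval
    if cfg_end < cfg_start:
        raise ValueError("configuration interval inverted")
    config_s = cfg_end - cfg_start
    reps = session.repetitions
    if not reps:
        active_s = 0.0
    elif convention == "span":
        span_start, span_end = reps[0].start_s, reps[-1].end_s
        active_s = span_end - span_start
        # only break time inside the active span is subtracted
        active_s -= sum(min(e, span_end) - max(s, span_start)
                        for s, e in session.break_intervals
                        if min(e, span_end) > max(s, span_start))
    elif convention == "sum":
        active_s = sum(r.span_s for r in reps)
    else:
        raise ValueError(f"unknown active-time convention {convention!r}")
    config_min = round(config_s / 60.0, 2)
    active_min = round(active_s / 60.0, 2)
    return (config_min, active_min, round(config_min + active_min, 2))
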