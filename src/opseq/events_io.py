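"""Canonical event data model and tidy CSV I/O for operant session logs.

Every downstream stage consumes :class:`SessionLog`, a time-ordered record of
the observable events in an operant chamber: lever presses, food-cup
photobeam entries/exits, pellet deliveries, pellet-dispenser cue emissions,
and conditioned-stimulus (CS) onsets/offsets.

Conventions
-----------
* Time is measured in seconds from session start (t = 0 at start).
* Simultaneous events are ordered deterministically by event type
  (press < pellet_delivery < dispenser_cue < foodcup_entry < foodcup_exit),
  so that a press and its instantaneous dispenser feedback always classify
  the same way.
* A "food-cup approach" is a ``foodcup_entry`` (beam-break onset);
  ``foodcup_exit`` is retained for bout duration only.
* Times are serialized with 3-decimal (millisecond) precision; logs built on
  a millisecond grid round-trip bit-exactly through CSV.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import pandas as pd
import yaml

__all__ = [
    "EVENT_TYPES",
    "PRESS_TYPES",
    "Event",
    "SessionLog",
    "FormatError",
    "ValidationError",
    "read_events",
    "write_events",
    "validate_log",
]

PRESS_TYPES = ("press_left", "press_right")

#: Deterministic rank used to break ties between events at the same time.
_TIE_ORDER = {
    "cs_onset": -1,
    "press_left": 0,
    "press_right": 0,
    "pellet_delivery": 1,
    "dispenser_cue": 2,
    "foodcup_entry": 3,
    "foodcup_exit": 4,
    "cs_offset": 5,
    "session_end": 6,
}

EVENT_TYPES = frozenset(_TIE_ORDER)

SESSION_TYPES = frozenset(
    {
        "magazine",
        "instrumental",
        "pavlovian",
        "extinction",
        "pit_test",
        "feedback_test",
        "devaluation_test",
    }
)

_COLUMNS = ["subject_id", "session_id", "session_type", "time_s", "event_type", "arg"]


class FormatError(ValueError):
    """Raised when an event-log file does not match the canonical schema."""


class ValidationError(ValueError):
    """Raised when a log violates a structural invariant."""


@dataclass(frozen=True, order=False)
class Event:
    """A single timestamped chamber event.

    Parameters
    ----------
    time_s
        Seconds from session start (non-negative).
    event_type
        One of :data:`EVENT_TYPES`.
    arg
        Optional label: cue identity (``"CS+"``/``"CS-"``) for CS events,
        lever value tag (``"valued"``/``"devalued"``) for presses in
        devaluation tests. Empty string when unused.
    """

    time_s: float
    event_type: str
    arg: str = ""

    def __post_init__(self) -> None:
        if self.event_type not in EVENT_TYPES:
            raise ValidationError(f"unknown event_type {self.event_type!r}")
        if not (self.time_s >= 0) or math.isnan(self.time_s):
            raise ValidationError(f"negative or NaN time {self.time_s!r}")

    @property
    def sort_key(self) -> tuple[float, int]:
        return (self.time_s, _TIE_ORDER[self.event_type])


@dataclass
class SessionLog:
    """A complete behavioral session: metadata plus a sorted event stream."""

    subject_id: str
    session_id: str
    session_type: str
    duration_s: float
    events: list[Event] = field(default_factory=list)
    condition_tags: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.session_type not in SESSION_TYPES:
            raise ValidationError(f"unknown session_type {self.session_type!r}")

    def sorted(self) -> "SessionLog":
        """Return a copy with events in canonical (time, tie-rank) order."""
        return replace(self, events=sorted(self.events, key=lambda e: e.sort_key))

    def times(self, *event_types: str, arg: str | None = None) -> list[float]:
        """Times of events matching any of ``event_types`` (and ``arg`` if given)."""
        return [
            e.time_s
            for e in self.events
            if e.event_type in event_types and (arg is None or e.arg == arg)
        ]

    @property
    def press_times(self) -> list[float]:
        return self.times(*PRESS_TYPES)

    @property
    def entry_times(self) -> list[float]:
        return self.times("foodcup_entry")


# ---------------------------------------------------------------------------
# Validation


def validate_log(log: SessionLog) -> SessionLog:
    """Check every structural invariant of a session log.

    Verifies sort order, time bounds, CS-window nesting, food-cup
    entry/exit alternation, and session_end placement. Returns the log
    unchanged if valid; raises :class:`ValidationError` otherwise.
    """
    keys = [e.sort_key for e in log.events]
    if keys != sorted(keys):
        raise ValidationError(f"{log.session_id}: events not in canonical order")

    open_cs: str | None = None
    cup_occupied = False
    n_end = 0
    for e in log.events:
        if e.time_s > log.duration_s + 1e-9:
            raise ValidationError(
                f"{log.session_id}: event at {e.time_s} after duration {log.duration_s}"
            )
        if e.event_type == "cs_onset":
            if not e.arg:
                raise ValidationError(f"{log.session_id}: cs_onset without cue identity")
            if open_cs is not None:
                raise ValidationError(
                    f"{log.session_id}: overlapping CS windows at t={e.time_s}"
                )
            open_cs = e.arg
        elif e.event_type == "cs_offset":
            if open_cs is None:
                raise ValidationError(
                    f"{log.session_id}: cs_offset with no prior cs_onset at t={e.time_s}"
                )
            if e.arg and e.arg != open_cs:
                raise ValidationError(
                    f"{log.session_id}: cs_offset cue {e.arg!r} != open {open_cs!r}"
                )
            open_cs = None
        elif e.event_type == "foodcup_entry":
            if cup_occupied:
                raise ValidationError(
                    f"{log.session_id}: foodcup_entry at t={e.time_s} without prior exit"
                )
            cup_occupied = True
        elif e.event_type == "foodcup_exit":
            if not cup_occupied:
                raise ValidationError(
                    f"{log.session_id}: foodcup_exit at t={e.time_s} without entry"
                )
            cup_occupied = False
        elif e.event_type == "session_end":
            n_end += 1
            if n_end > 1:
                raise ValidationError(f"{log.session_id}: multiple session_end events")
            if abs(e.time_s - log.duration_s) > 1e-9:
                raise ValidationError(
                    f"{log.session_id}: session_end at {e.time_s} != duration "
                    f"{log.duration_s}"
                )
    if open_cs is not None:
        raise ValidationError(f"{log.session_id}: unterminated CS window ({open_cs})")
    return log


# ---------------------------------------------------------------------------
# CSV I/O


def read_events(path) -> list[SessionLog]:
    """Read a tidy event-log CSV into one :class:`SessionLog` per session.

    The file must carry the canonical columns ``subject_id, session_id,
    session_type, time_s, event_type, arg``. Rows may be in any order;
    events are returned sorted with the canonical tie order. Duration is
    taken from the ``session_end`` event when present, else the last event
    time.
    """
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in _COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(f"missing column(s): {', '.join(missing)}")

    logs: list[SessionLog] = []
    for (subject_id, session_id), grp in frame.groupby(
        ["subject_id", "session_id"], sort=True
    ):
        session_types = grp["session_type"].unique()
        if len(session_types) != 1:
            raise FormatError(
                f"session {session_id!r} has conflicting session_type values"
            )
        events = []
        for row in grp.itertuples():
            try:
                t = float(row.time_s)
            except ValueError:
                raise FormatError(f"row {row.Index + 2}: non-numeric time_s")
            if t < 0:
                raise ValidationError(f"row {row.Index + 2}: negative time_s")
            if row.event_type not in EVENT_TYPES:
                raise ValidationError(
                    f"row {row.Index + 2}: unknown event_type {row.event_type!r}"
                )
            events.append(Event(t, row.event_type, row.arg))
        events.sort(key=lambda e: e.sort_key)
        end_times = [e.time_s for e in events if e.event_type == "session_end"]
        duration = end_times[0] if end_times else (events[-1].time_s if events else 0.0)
        logs.append(
            SessionLog(
                subject_id=str(subject_id),
                session_id=str(session_id),
                session_type=str(session_types[0]),
                duration_s=duration,
                events=events,
            )
        )
    return logs


def write_events(logs: list[SessionLog], path) -> None:
    """Write session logs to the canonical CSV layout.

    Times are rendered with fixed 3-decimal precision, so output is
    bit-stable for fixed input and logs on a millisecond grid satisfy
    ``read_events(write_events(logs)) == logs``.
    """
    rows = []
    for log in logs:
        for e in sorted(log.events, key=lambda ev: ev.sort_key):
            rows.append(
                (
                    log.subject_id,
                    log.session_id,
                    log.session_type,
                    f"{e.time_s:.3f}",
                    e.event_type,
                    e.arg,
                )
            )
    pd.DataFrame(rows, columns=_COLUMNS).to_csv(path, index=False)


def read_condition_tags(path) -> dict[str, dict[str, str]]:
    """Read the optional YAML sidecar mapping session_id -> condition tags."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return {str(k): {str(a): str(b) for a, b in (v or {}).items()} for k, v in raw.items()}


def write_condition_tags(logs: list[SessionLog], path) -> None:
    """Write each session's condition tags to a YAML sidecar."""
    payload = {log.session_id: dict(log.condition_tags) for log in logs}
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=True)


def attach_condition_tags(logs: list[SessionLog], tags: dict[str, dict[str, str]]) -> None:
    for log in logs:
        if log.session_id in tags:
            log.condition_tags.update(tags[log.session_id])
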