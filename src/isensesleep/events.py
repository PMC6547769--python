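"""Screen-event records, interaction sessions, and log file I/O.

A phone logger emits three kinds of screen events: ``SCREEN_ON`` (the user
pressed the power button), ``PRESENT`` (the device was unlocked and ready
for app interaction) and ``SCREEN_OFF``.  One *interaction session* is a
consecutive ON→OFF pair; everything downstream (sleep-gap detection,
scoring) operates on sessions, never on raw events.

Timestamps are stored timezone-aware and ordered on the absolute (UTC)
line; time-of-day logic elsewhere in the package uses the wall-clock time
carried by each timestamp's own offset, because "10 pm" is a local-time
concept.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from datetime import datetime
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "ScreenEventKind",
    "ScreenEventRecord",
    "ScreenSession",
    "PairingReport",
    "read_event_log",
    "write_event_log",
    "pair_sessions",
]


class ScreenEventKind(str, Enum):
    SCREEN_ON = "SCREEN_ON"
    SCREEN_OFF = "SCREEN_OFF"
    PRESENT = "PRESENT"


@dataclass(frozen=True, order=True)
class ScreenEventRecord:
    """One raw logged screen event."""

    timestamp: datetime
    kind: ScreenEventKind

    def __post_init__(self) -> None:
        if self.timestamp.tzinfo is None or self.timestamp.tzinfo.utcoffset(self.timestamp) is None:
            raise ValueError(f"event timestamp must be timezone-aware: {self.timestamp!r}")
        if not isinstance(self.kind, ScreenEventKind):
            object.__setattr__(self, "kind", ScreenEventKind(self.kind))


@dataclass(frozen=True)
class ScreenSession:
    """A paired ON→OFF interaction interval.

    ``unlocked`` is True when a PRESENT event occurred between the ON and
    the OFF (the phone was actually unlocked, not merely lit).
    """

    on_time: datetime
    off_time: datetime
    unlocked: bool = False

    def __post_init__(self) -> None:
        if not self.on_time < self.off_time:
            raise ValueError("session requires on_time < off_time")

    @property
    def duration_min(self) -> float:
        return (self.off_time - self.on_time).total_seconds() / 60.0


@dataclass
class PairingReport:
    """Counts of malformed subsequences repaired while pairing events."""

    reopened_on: int = 0        # SCREEN_ON superseded by a later SCREEN_ON
    leading_off: int = 0        # SCREEN_OFF with no prior SCREEN_ON
    trailing_on: int = 0        # unmatched SCREEN_ON at end of stream
    zero_length: int = 0        # ON and OFF at the identical timestamp
    orphan_present: int = 0     # PRESENT outside any open session

    @property
    def total(self) -> int:
        return (self.reopened_on + self.leading_off + self.trailing_on
                + self.zero_length + self.orphan_present)


_CSV_HEADER = ["timestamp", "kind"]


def _parse_record(ts_str: str, kind_str: str, lineno: int) -> ScreenEventRecord:
    try:
        ts = datetime.fromisoformat(ts_str.strip())
    except ValueError as exc:
        raise ValueError(f"line {lineno}: unparseable timestamp {ts_str!r}") from exc
    if ts.tzinfo is None:
        raise ValueError(f"line {lineno}: timestamp {ts_str!r} lacks a UTC offset")
    try:
        kind = ScreenEventKind(kind_str.strip())
    except ValueError as exc:
        raise ValueError(f"line {lineno}: unknown event kind {kind_str!r}") from exc
    return ScreenEventRecord(ts, kind)


def read_event_log(path: str | Path, dialect: str | None = None) -> list[ScreenEventRecord]:
    """Read an event log, returning records sorted by timestamp, de-duplicated.

    Parameters
    ----------
    path
        CSV (header ``timestamp,kind``) or JSON-lines file.
    dialect
        ``"csv"`` or ``"jsonl"``; inferred from the file suffix when None.

    Exact duplicates (identical timestamp and kind) are dropped; ordering is
    a stable ascending sort on the absolute timestamp.
    """
    path = Path(path)
    if dialect is None:
        dialect = "jsonl" if path.suffix.lower() in {".jsonl", ".ndjson", ".json"} else "csv"
    if dialect not in {"csv", "jsonl"}:
        raise ValueError(f"unknown dialect {dialect!r}")

    records: list[ScreenEventRecord] = []
    with open(path, newline="") as fh:
        if dialect == "csv":
            reader = csv.reader(fh)
            for lineno, row in enumerate(reader, start=1):
                if not row or (lineno == 1 and [c.strip().lower() for c in row] == _CSV_HEADER):
                    continue
                if len(row) < 2:
                    raise ValueError(f"line {lineno}: expected 'timestamp,kind', got {row!r}")
                records.append(_parse_record(row[0], row[1], lineno))
        else:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line:
                    continue
                try:
                    obj = json.loads(line)
                except json.JSONDecodeError as exc:
                    raise ValueError(f"line {lineno}: invalid JSON") from exc
                if "timestamp" not in obj or "kind" not in obj:
                    raise ValueError(f"line {lineno}: missing 'timestamp' or 'kind'")
                records.append(_parse_record(str(obj["timestamp"]), str(obj["kind"]), lineno))

    records.sort(key=lambda r: r.timestamp)  # stable
    deduped: list[ScreenEventRecord] = []
    seen: set[tuple[datetime, ScreenEventKind]] = set()
    for rec in records:
        key = (rec.timestamp, rec.kind)
        if key not in seen:
            seen.add(key)
            deduped.append(rec)
    return deduped


def write_event_log(records: Iterable[ScreenEventRecord], path: str | Path,
                    dialect: str | None = None) -> None:
    """Write records in the canonical CSV or JSON-lines dialect."""
    path = Path(path)
    if dialect is None:
        dialect = "jsonl" if path.suffix.lower() in {".jsonl", ".ndjson", ".json"} else "csv"
    with open(path, "w", newline="") as fh:
        if dialect == "csv":
            writer = csv.writer(fh)
            writer.writerow(_CSV_HEADER)
            for rec in records:
                writer.writerow([rec.timestamp.isoformat(), rec.kind.value])
        elif dialect == "jsonl":
            for rec in records:
                fh.write(json.dumps({"timestamp": rec.timestamp.isoformat(),
                                     "kind": rec.kind.value}) + "\n")
        else:
            raise ValueError(f"unknown dialect {dialect!r}")


def pair_sessions(events: Sequence[ScreenEventRecord],
                  return_report: bool = False):
    """Pair SCREEN_ON/SCREEN_OFF events into interaction sessions.

    Repair rules for malformed subsequences (counted in the report, never
    raised):

    * ON followed by another ON without an OFF: the earlier ON is dropped
      (the later ON is closest to the terminating OFF; the choice only
      shifts session starts, never the OFF→ON gap boundaries used for
      sleep detection).
    * A leading OFF with no open session is dropped.
    * A trailing unmatched ON is dropped.
    * ON and OFF at the identical timestamp produce no session.
    * PRESENT events never open or close a session; inside one they set
      ``unlocked``.

    Returns the session list, or ``(sessions, PairingReport)`` when
    ``return_report`` is true.
    """
    report = PairingReport()
    sessions: list[ScreenSession] = []
    open_on: datetime | None = None
    unlocked = False
    for ev in events:
        if ev.kind is ScreenEventKind.SCREEN_ON:
            if open_on is not None:
                report.reopened_on += 1
            open_on = ev.timestamp
            unlocked = False
        elif ev.kind is ScreenEventKind.SCREEN_OFF:
            if open_on is None:
                report.leading_off += 1
            elif ev.timestamp == open_on:
                report.zero_length += 1
                open_on = None
            else:
                sessions.append(ScreenSession(open_on, ev.timestamp, unlocked))
                open_on = None
        else:  # PRESENT
            if open_on is None:
                report.orphan_present += 1
            else:
                unlocked = True
    if open_on is not None:
        report.trailing_on += 1
    if return_report:
        return sessions, report
    return sessions
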