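"""Timestamped procedure annotations: the event-log data model and CSV I/O.

An event log records one treatment procedure as a list of half-open intervals
``[start_s, end_s)`` in integer seconds from recording start, each labelled
with a phase or module of the process model.  Logs carry the declared method
(LLR/LLA/PA), treatment type, and the total recording length, which is
authoritative for idle-time accounting (the endoscope may be out of view,
so the last event need not reach the recording end).

File dialect: UTF-8 CSV with header
``procedure_id,method,treatment_type,level,entity,start_s,end_s,parallel,note``;
one metadata row with ``level=meta, entity=total_s`` carries the recording
length in its ``end_s`` column.  Notes are quoted by the CSV layer, so
delimiters inside notes round-trip.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

from .model import Method, ProcessModel, TREATMENT_TYPES

__all__ = [
    "Event",
    "EventLog",
    "ClinicalSpans",
    "StructuralIssue",
    "LogParseError",
    "LogInvariantError",
    "read_log",
    "write_log",
    "validate_structure",
    "derive_spans",
]

LOG_COLUMNS = (
    "procedure_id",
    "method",
    "treatment_type",
    "level",
    "entity",
    "start_s",
    "end_s",
    "parallel",
    "note",
)


class LogParseError(ValueError):
    """Malformed event-log text; carries the 1-based line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        super().__init__(f"line {line}: {message}" if line else message)


class LogInvariantError(ValueError):
    """An event log violating its invariants was handed to the writer."""


@dataclass(frozen=True)
class Event:
    """One annotated interval.  ``parallel`` marks activities that may overlap
    other phase events (e.g. imaging during preparation)."""

    event_id: int
    level: str  # "phase" | "module"
    entity: str
    start_s: int
    end_s: int
    parallel: bool = False
    note: Optional[str] = None

    @property
    def duration_s(self) -> int:
        return self.end_s - self.start_s

    def contains(self, other: "Event") -> bool:
        return self.start_s <= other.start_s and other.end_s <= self.end_s

    def overlaps(self, other: "Event") -> bool:
        # half-open intervals: sharing a boundary is not an overlap
        return self.start_s < other.end_s and other.start_s < self.end_s


def _sort_key(e: Event) -> tuple:
    # phases before the modules they contain at equal start
    return (e.start_s, 0 if e.level == "phase" else 1, e.event_id)


@dataclass
class EventLog:
    """One procedure's annotations plus metadata."""

    procedure_id: str
    method: Method
    treatment_type: str
    total_s: int
    events: list[Event] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.method = Method(self.method)
        self.events = sorted(self.events, key=_sort_key)

    def phase_events(self) -> list[Event]:
        return [e for e in self.events if e.level == "phase"]

    def module_events(self) -> list[Event]:
        return [e for e in self.events if e.level == "module"]

    def phase_sequence(self) -> list[str]:
        """Chronological phase labels (linearized by start time)."""
        return [e.entity for e in self.phase_events()]

    def with_events(self, events: Iterable[Event]) -> "EventLog":
        return replace(self, events=sorted(events, key=_sort_key))


@dataclass(frozen=True)
class ClinicalSpans:
    """Nested clinical spans, outermost to innermost; each may be absent.

    operation: the whole stay in the OR (the recording);
    intervention: from the first incision or first needle manipulation;
    surgery: from the first incision (absent for percutaneous procedures);
    treatment: the span of the physical resection/ablation acts.
    """

    operation: Optional[tuple[int, int]] = None
    intervention: Optional[tuple[int, int]] = None
    surgery: Optional[tuple[int, int]] = None
    treatment: Optional[tuple[int, int]] = None


@dataclass(frozen=True)
class StructuralIssue:
    kind: str  # unknown_entity | level_mismatch | orphan_module | overlap | out_of_range | interval
    event_id: Optional[int]
    message: str


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def _parse_bool(raw: str, line: int) -> bool:
    v = raw.strip().lower()
    if v in ("true", "1", "yes"):
        return True
    if v in ("false", "0", "no", ""):
        return False
    raise LogParseError(f"cannot parse boolean {raw!r}", line)


def _parse_int(raw: str, col: str, line: int) -> int:
    try:
        return int(raw.strip())
    except ValueError:
        raise LogParseError(f"cannot parse integer {col}={raw!r}", line) from None


def read_log(source: str) -> EventLog:
    """Parse event-log CSV text into an :class:`EventLog`.

    Unknown entity ids are accepted here (they are a conformance finding, so
    logs written against other model versions still load); malformed rows and
    reversed intervals raise :class:`LogParseError` with the line number.
    """
    reader = csv.reader(io.StringIO(source))
    rows = list(reader)
    if not rows:
        raise LogParseError("empty file", 1)
    header = [c.strip() for c in rows[0]]
    if header != list(LOG_COLUMNS):
        raise LogParseError(
            f"unexpected header {header!r}; expected {','.join(LOG_COLUMNS)}", 1
        )

    procedure_id = method = treatment_type = None
    total_s: Optional[int] = None
    events: list[Event] = []
    next_id = 1
    for lineno, row in enumerate(rows[1:], start=2):
        if not row or all(not c.strip() for c in row):
            continue
        if len(row) != len(LOG_COLUMNS):
            raise LogParseError(
                f"expected {len(LOG_COLUMNS)} fields, got {len(row)}", lineno
            )
        pid, meth, ttype, level, entity, s_raw, e_raw, par_raw, note = row
        if procedure_id is None:
            procedure_id, treatment_type = pid, ttype.strip()
            try:
                method = Method(meth.strip())
            except ValueError:
                raise LogParseError(f"unknown method {meth!r}", lineno) from None
        level = level.strip()
        if level == "meta":
            if entity.strip() != "total_s":
                raise LogParseError(f"unknown metadata key {entity!r}", lineno)
            total_s = _parse_int(e_raw, "end_s", lineno)
            continue
        if level not in ("phase", "module"):
            raise LogParseError(f"unknown level {level!r}", lineno)
        start_s = _parse_int(s_raw, "start_s", lineno)
        end_s = _parse_int(e_raw, "end_s", lineno)
        if start_s < 0:
            raise LogParseError(f"negative start_s {start_s}", lineno)
        if end_s < start_s:
            raise LogParseError(
                f"interval reversed: end_s {end_s} < start_s {start_s}", lineno
            )
        events.append(
            Event(
                event_id=next_id,
                level=level,
                entity=entity.strip(),
                start_s=start_s,
                end_s=end_s,
                parallel=_parse_bool(par_raw, lineno),
                note=note if note else None,
            )
        )
        next_id += 1

    if procedure_id is None:
        raise LogParseError("log contains no data rows", len(rows))
    if total_s is None:
        raise LogParseError("missing total_s metadata row", len(rows))
    return EventLog(
        procedure_id=procedure_id,
        method=method,
        treatment_type=treatment_type,
        total_s=total_s,
        events=events,
    )


def write_log(log: EventLog) -> str:
    """Serialize a log to the CSV dialect in canonical (chronological) order.

    Refuses logs whose per-event intervals are ill-formed (reversed, negative,
    or outside ``[0, total_s)``); nesting/overlap findings are the business of
    :func:`validate_structure` and do not block serialization for exchange.
    """
    for e in log.events:
        if e.end_s < e.start_s:
            raise LogInvariantError(
                f"event {e.event_id}: end_s {e.end_s} < start_s {e.start_s}"
            )
        if e.start_s < 0 or e.end_s > log.total_s:
            raise LogInvariantError(
                f"event {e.event_id}: interval [{e.start_s}, {e.end_s}) outside "
                f"[0, {log.total_s})"
            )
        if e.level not in ("phase", "module"):
            raise LogInvariantError(f"event {e.event_id}: unknown level {e.level!r}")

    buf = io.StringIO()
    w = csv.writer(buf, lineterminator="\n")
    w.writerow(LOG_COLUMNS)
    w.writerow(
        [log.procedure_id, log.method.value, log.treatment_type, "meta", "total_s",
         0, log.total_s, "false", ""]
    )
    for e in sorted(log.events, key=_sort_key):
        w.writerow(
            [log.procedure_id, log.method.value, log.treatment_type, e.level,
             e.entity, e.start_s, e.end_s, "true" if e.parallel else "false",
             e.note or ""]
        )
    return buf.getvalue()


# ---------------------------------------------------------------------------
# Structural validation
# ---------------------------------------------------------------------------


def _module_parent(entity: str) -> str:
    return entity.split(".", 1)[0]


def validate_structure(
    log: EventLog, model: Optional[ProcessModel] = None
) -> list[StructuralIssue]:
    """Structural findings for ``log``; empty iff the log is well formed.

    Checks: intervals within ``[0, total_s)``; entities known to ``model``
    (skipped when no model is given) at the declared level; every module
    event nested inside a phase event of its parent phase; non-parallel
    phase events pairwise non-overlapping.
    """
    issues: list[StructuralIssue] = []

    for e in log.events:
        if e.end_s < e.start_s:
            issues.append(
                StructuralIssue("interval", e.event_id,
                                f"end_s {e.end_s} < start_s {e.start_s}")
            )
        if e.start_s < 0 or e.end_s > log.total_s:
            issues.append(
                StructuralIssue("out_of_range", e.event_id,
                                f"[{e.start_s}, {e.end_s}) outside [0, {log.total_s})")
            )
        if model is not None:
            if e.level == "phase":
                if not model.has_phase(e.entity):
                    issues.append(
                        StructuralIssue("unknown_entity", e.event_id,
                                        f"unknown phase {e.entity!r}")
                    )
            else:
                if not model.has_module(e.entity):
                    issues.append(
                        StructuralIssue("unknown_entity", e.event_id,
                                        f"unknown module {e.entity!r}")
                    )

    phase_events = log.phase_events()
    for m in log.module_events():
        parent = (
            model.module(m.entity).parent_phase
            if model is not None and model.has_module(m.entity)
            else _module_parent(m.entity)
        )
        if not any(p.entity == parent and p.contains(m) for p in phase_events):
            issues.append(
                StructuralIssue(
                    "orphan_module", m.event_id,
                    f"module event {m.entity} [{m.start_s}, {m.end_s}) has no "
                    f"enclosing {parent} phase event",
                )
            )

    for i, a in enumerate(phase_events):
        for b in phase_events[i + 1:]:
            if b.start_s >= a.end_s:
                break  # sorted by start: no later event can overlap a
            if a.overlaps(b) and not (a.parallel or b.parallel):
                issues.append(
                    StructuralIssue(
                        "overlap", a.event_id,
                        f"non-parallel phase events {a.event_id} ({a.entity}) and "
                        f"{b.event_id} ({b.entity}) overlap",
                    )
                )
    return issues


# ---------------------------------------------------------------------------
# Clinical spans
# ---------------------------------------------------------------------------


def derive_spans(log: EventLog) -> ClinicalSpans:
    """Derive the nested clinical spans from a structurally valid log.

    operation covers the whole recording; intervention starts at the first
    incision (first P07 event) or, for percutaneous access, the first needle
    manipulation (first P09); surgery starts at the first P07 event only;
    treatment spans the union of the treatment-phase (P10) events.  Each inner
    span ends with the last phase-level event.  Spans whose triggering events
    are absent are ``None``.
    """
    phase_events = log.phase_events()
    operation = (0, log.total_s)
    if not phase_events:
        return ClinicalSpans(operation=operation)
    last_end = max(e.end_s for e in phase_events)

    def first_start(*entities: str) -> Optional[int]:
        starts = [e.start_s for e in phase_events if e.entity in entities]
        return min(starts) if starts else None

    surgery_start = first_start("P07")
    intervention_start = first_start("P07", "P09")
    p10 = [e for e in phase_events if e.entity == "P10"]
    treatment = (min(e.start_s for e in p10), max(e.end_s for e in p10)) if p10 else None

    return ClinicalSpans(
        operation=operation,
        intervention=(intervention_start, last_end) if intervention_start is not None else None,
        surgery=(surgery_start, last_end) if surgery_start is not None else None,
        treatment=treatment,
    )
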