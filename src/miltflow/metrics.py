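"""Quantitative verification and duration/occurrence analytics.

For one procedure, :func:`summarize` produces per-phase and per-module
duration sums and occurrence counts plus the global idle time — the shape of
a per-surgery results table.  Idle is the part of the recording covered by no
phase-level event (endoscope out of view, camera cleaning); intra-phase gaps
are attributed to the phase.  :func:`quantitative_verify` asserts the
conservation identity: phase durations plus idle equal the recording length.
:func:`aggregate` pools procedures into cohort fractions and per-procedure
means.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import pandas as pd

from .eventlog import EventLog, validate_structure
from .model import ProcessModel

__all__ = [
    "EntitySummary",
    "ProcedureSummary",
    "QuantitativeVerdict",
    "CohortSummary",
    "StructuralError",
    "summarize",
    "quantitative_verify",
    "aggregate",
    "summary_table",
]


class StructuralError(ValueError):
    """A structurally invalid log was handed to an analytics operation."""


@dataclass(frozen=True)
class EntitySummary:
    entity: str
    duration_s: int
    occurrence: int


@dataclass
class ProcedureSummary:
    procedure_id: str
    phase_rows: dict[str, EntitySummary]
    module_rows: dict[str, EntitySummary]
    idle_s: int
    total_s: int
    #: seconds counted twice in phase sums because of parallel-flagged overlap
    overlap_s: int = 0

    @property
    def phase_duration_total(self) -> int:
        return sum(r.duration_s for r in self.phase_rows.values())


@dataclass(frozen=True)
class QuantitativeVerdict:
    passed: bool
    discrepancy_s: int
    phase_overruns: dict[str, int]


@dataclass
class CohortSummary:
    n_procedures: int
    #: per-procedure mean duration per phase (seconds)
    mean_duration_s: dict[str, float]
    #: pooled fraction of total recording time per phase
    pooled_fraction: dict[str, float]
    mean_occurrence: dict[str, float]
    idle_fraction: float


def _union_length(intervals: list[tuple[int, int]]) -> int:
    total = 0
    end = None
    for s, e in sorted(intervals):
        if end is None or s > end:
            total += e - s
            end = e
        elif e > end:
            total += e - end
            end = e
    return total


def summarize(log: EventLog, model: Optional[ProcessModel] = None) -> ProcedureSummary:
    """Per-entity duration sums and occurrence counts at both levels.

    Occurrence counts events; zero-length events count as occurrences with
    zero duration.  When a ``model`` is given the output is censused against
    its full phase/module inventory, with explicit zero rows for entities
    that never occur (a published per-surgery table prints those too), and
    unknown entities are a hard error.  Raises :class:`StructuralError` on
    structurally invalid logs.
    """
    issues = validate_structure(log, model)
    if issues:
        raise StructuralError(issues[0].message)

    phase_rows: dict[str, EntitySummary] = {}
    module_rows: dict[str, EntitySummary] = {}
    if model is not None:
        phase_rows = {p.phase_id: EntitySummary(p.phase_id, 0, 0) for p in model.phases}
        module_rows = {m.module_id: EntitySummary(m.module_id, 0, 0) for m in model.modules}

    for e in log.events:
        rows = phase_rows if e.level == "phase" else module_rows
        prev = rows.get(e.entity, EntitySummary(e.entity, 0, 0))
        rows[e.entity] = EntitySummary(
            e.entity, prev.duration_s + e.duration_s, prev.occurrence + 1
        )

    phase_intervals = [(e.start_s, e.end_s) for e in log.phase_events()]
    covered = _union_length(phase_intervals)
    phase_sum = sum(r.duration_s for r in phase_rows.values())
    return ProcedureSummary(
        procedure_id=log.procedure_id,
        phase_rows=phase_rows,
        module_rows=module_rows,
        idle_s=log.total_s - covered,
        total_s=log.total_s,
        overlap_s=phase_sum - covered,
    )


def quantitative_verify(
    summary: ProcedureSummary, tolerance_s: int = 0
) -> QuantitativeVerdict:
    """Conservation check: phase durations (+ idle, − parallel overlap) must
    reproduce the recording length, and no phase's module sums may exceed the
    phase duration.  Default tolerance is zero seconds."""
    discrepancy = summary.total_s - (
        summary.phase_duration_total - summary.overlap_s + summary.idle_s
    )
    overruns: dict[str, int] = {}
    for phase_id, row in summary.phase_rows.items():
        msum = sum(
            r.duration_s
            for mid, r in summary.module_rows.items()
            if mid.split(".", 1)[0] == phase_id
        )
        if msum > row.duration_s:
            overruns[phase_id] = msum - row.duration_s
    passed = abs(discrepancy) <= tolerance_s and not overruns
    return QuantitativeVerdict(passed=passed, discrepancy_s=discrepancy,
                               phase_overruns=overruns)


def aggregate(summaries: Iterable[ProcedureSummary]) -> CohortSummary:
    """Pool procedure summaries into cohort statistics.

    Pooled fraction of phase p = Σ duration_p / Σ total; the mean duration and
    occurrence are per-procedure means (entities absent from a procedure count
    as zero).  Both are reported because "share of time in a phase" is
    ambiguous between the two conventions.
    """
    summaries = list(summaries)
    if not summaries:
        raise ValueError("aggregate() needs at least one procedure summary")

    entities = sorted({p for s in summaries for p in s.phase_rows})
    n = len(summaries)
    grand_total = sum(s.total_s for s in summaries)
    if grand_total <= 0:
        raise ValueError("cohort has zero total recording time")

    def row(s: ProcedureSummary, p: str) -> EntitySummary:
        return s.phase_rows.get(p, EntitySummary(p, 0, 0))

    mean_duration = {
        p: sum(row(s, p).duration_s for s in summaries) / n for p in entities
    }
    pooled = {
        p: sum(row(s, p).duration_s for s in summaries) / grand_total
        for p in entities
    }
    mean_occ = {
        p: sum(row(s, p).occurrence for s in summaries) / n for p in entities
    }
    idle_fraction = sum(s.idle_s for s in summaries) / grand_total
    return CohortSummary(
        n_procedures=n,
        mean_duration_s=mean_duration,
        pooled_fraction=pooled,
        mean_occurrence=mean_occ,
        idle_fraction=idle_fraction,
    )


def summary_table(
    summary: ProcedureSummary, model: Optional[ProcessModel] = None
) -> pd.DataFrame:
    """Tabular view of a procedure summary mirroring a per-surgery results
    table: one row per module nested under its phase, then Idle and Sum."""
    records = []
    phase_ids = list(summary.phase_rows)

    def name_of(entity: str, level: str) -> str:
        if model is None:
            return entity
        try:
            return (model.phase(entity) if level == "phase" else model.module(entity)).name
        except KeyError:
            return entity

    for pid in phase_ids:
        prow = summary.phase_rows[pid]
        mods = [m for m in summary.module_rows if m.split(".", 1)[0] == pid]
        if not mods:
            mods = [None]
        for mid in mods:
            mrow = summary.module_rows.get(mid) if mid else None
            records.append(
                {
                    "phase": pid,
                    "phase_name": name_of(pid, "phase"),
                    "phase_duration_s": prow.duration_s,
                    "phase_occurrence": prow.occurrence,
                    "module": mid or "",
                    "module_name": name_of(mid, "module") if mid else "",
                    "module_duration_s": mrow.duration_s if mrow else 0,
                    "module_occurrence": mrow.occurrence if mrow else 0,
                }
            )
    records.append(
        {"phase": "Idle", "phase_name": "Idle",
         "phase_duration_s": summary.idle_s, "phase_occurrence": "",
         "module": "", "module_name": "", "module_duration_s": "",
         "module_occurrence": ""}
    )
    records.append(
        {"phase": "Sum", "phase_name": "Sum",
         "phase_duration_s": summary.total_s, "phase_occurrence": "",
         "module": "", "module_name": "", "module_duration_s": "",
         "module_occurrence": ""}
    )
    return pd.DataFrame.from_records(records)
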