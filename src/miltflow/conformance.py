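"""Qualitative verification: does an observed log follow the process model?

The phase-level check walks the chronological phase sequence, treats anytime
phases (complications, miscellaneous) as wildcards — they are skipped and
counted, never used to bridge an otherwise illegal transition — and requires
every remaining consecutive pair either to repeat the same phase (continued
or revisited work in one phase is always legal) or to follow an execution
arrow applicable to the log's declared method.  The module-level check
enforces the model's within-phase precedence rules per phase instance.
Verdicts are boolean with itemized violations; there is no fitness scoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Union

from .eventlog import EventLog, StructuralIssue, validate_structure
from .model import Method, ProcessModel, TREATMENT_TYPES, allowed_next

__all__ = [
    "Violation",
    "ConformanceReport",
    "StructuralPreconditionError",
    "check_phase_sequence",
    "check_module_events",
    "verify",
]

#: Structural finding kinds that make sequence semantics ill-defined.
_BLOCKING = ("interval", "out_of_range", "orphan_module", "overlap")


class StructuralPreconditionError(ValueError):
    """Sequence checking was asked for a structurally invalid log."""


@dataclass(frozen=True)
class Violation:
    kind: str
    position: Union[int, tuple[int, int], None]
    message: str


@dataclass
class ConformanceReport:
    violations: list[Violation] = field(default_factory=list)
    checked_events: int = 0
    wildcard_insertions: int = 0

    @property
    def valid(self) -> bool:
        return not self.violations

    def merged(self, other: "ConformanceReport") -> "ConformanceReport":
        return ConformanceReport(
            violations=self.violations + other.violations,
            checked_events=max(self.checked_events, other.checked_events),
            wildcard_insertions=self.wildcard_insertions + other.wildcard_insertions,
        )

    def to_dict(self) -> dict:
        return {
            "valid": self.valid,
            "checked_events": self.checked_events,
            "wildcard_insertions": self.wildcard_insertions,
            "violations": [
                {"kind": v.kind, "position": v.position, "message": v.message}
                for v in self.violations
            ],
        }


def _precheck(log: EventLog, model: Optional[ProcessModel]) -> None:
    blockers = [
        i for i in validate_structure(log, model) if i.kind in _BLOCKING
    ]
    if blockers:
        raise StructuralPreconditionError(
            f"structurally invalid log: {blockers[0].message}"
        )


def _applicability_violation(
    model: ProcessModel, entity: str, method: Method, event_id: int
) -> Optional[Violation]:
    if not model.has_phase(entity):
        return Violation(
            "inapplicable_phase", event_id, f"unknown phase {entity!r}"
        )
    phase = model.phase(entity)
    if method not in phase.methods:
        if phase.ablation_only:
            return Violation(
                "ablation_only_in_resection", event_id,
                f"{entity} ({phase.name}) is ablation-only but the log declares "
                f"{method.value}",
            )
        return Violation(
            "inapplicable_phase", event_id,
            f"{entity} ({phase.name}) does not apply to {method.value}",
        )
    return None


def check_phase_sequence(log: EventLog, model: ProcessModel) -> ConformanceReport:
    """Check the chronological phase sequence against the model's arrows."""
    _precheck(log, model)
    method = Method(log.method)
    report = ConformanceReport()
    anytime = model.anytime_phases

    chain: list[tuple[int, str]] = []  # (event_id, entity) after wildcard removal
    for e in log.phase_events():
        report.checked_events += 1
        if e.entity in anytime:
            report.wildcard_insertions += 1
            v = _applicability_violation(model, e.entity, method, e.event_id)
            if v:
                report.violations.append(v)
            continue
        v = _applicability_violation(model, e.entity, method, e.event_id)
        if v:
            report.violations.append(v)
            if not model.has_phase(e.entity):
                continue  # unknown node cannot anchor a transition check
        chain.append((e.event_id, e.entity))

    for (id_a, a), (id_b, b) in zip(chain, chain[1:]):
        if a == b:
            continue  # phase continuation / repeat
        if b not in allowed_next(model, a, method):
            report.violations.append(
                Violation(
                    "illegal_transition", (id_a, id_b),
                    f"no execution path {a} -> {b} for {method.value}",
                )
            )
    return report


def check_module_events(log: EventLog, model: ProcessModel) -> ConformanceReport:
    """Check module membership and within-phase module ordering.

    A precedence rule (A before B) binds per phase instance and only when both
    modules occur there: B occurring without A is legal (e.g. leak closure
    without a registered leak test), B starting before the first A is not.
    """
    _precheck(log, model)
    report = ConformanceReport()
    phase_events = log.phase_events()

    # assign each module event to the phase event that contains it
    contents: dict[int, list] = {p.event_id: [] for p in phase_events}
    for m in log.module_events():
        report.checked_events += 1
        if not model.has_module(m.entity):
            report.violations.append(
                Violation("inapplicable_phase", m.event_id,
                          f"unknown module {m.entity!r}")
            )
            continue
        parent = model.module(m.entity).parent_phase
        host = next(
            (p for p in phase_events if p.contains(m)), None
        )
        if host is None:
            continue  # orphan: structural precheck only blocks parent-mismatch
        if host.entity != parent:
            report.violations.append(
                Violation(
                    "orphan_module", m.event_id,
                    f"module {m.entity} of phase {parent} sits inside a "
                    f"{host.entity} phase event",
                )
            )
            continue
        contents[host.event_id].append(m)

    for p in phase_events:
        inside = sorted(contents.get(p.event_id, []),
                        key=lambda e: (e.start_s, e.event_id))
        if not inside:
            continue
        first_start = {}
        for m in inside:
            first_start.setdefault(m.entity, m.start_s)
        for rule in model.precedence_of(p.entity):
            if rule.before in first_start and rule.after in first_start:
                if first_start[rule.after] < first_start[rule.before]:
                    report.violations.append(
                        Violation(
                            "illegal_module_order", p.event_id,
                            f"in {p.entity} instance {p.event_id}: "
                            f"{rule.after} starts before {rule.before}",
                        )
                    )
    return report


def verify(log: EventLog, model: ProcessModel) -> ConformanceReport:
    """Full qualitative verification: structure, phase sequence, module order.

    Never raises on log content: structural findings are folded into the
    report (unknown entities surface as ``inapplicable_phase``).  When
    structural blockers (overlaps, orphan modules, broken intervals) are
    present, sequence semantics are undefined and the sequence checks are
    skipped — the report is already invalid.
    """
    report = ConformanceReport()
    method = Method(log.method)

    if log.treatment_type and log.treatment_type not in TREATMENT_TYPES[method]:
        report.violations.append(
            Violation(
                "method_mismatch", None,
                f"treatment type {log.treatment_type!r} is not a "
                f"{method.value} type",
            )
        )

    structural = validate_structure(log, model)
    blocked = False
    for issue in structural:
        if issue.kind == "unknown_entity":
            continue  # resurfaces as inapplicable_phase in the detail checks
        blocked = blocked or issue.kind in _BLOCKING
        kind = issue.kind if issue.kind in ("orphan_module",) else issue.kind
        report.violations.append(Violation(kind, issue.event_id, issue.message))

    if blocked:
        # still surface unknown/inapplicable entities for a fuller picture
        for e in log.phase_events():
            v = _applicability_violation(model, e.entity, method, e.event_id)
            if v:
                report.violations.append(v)
        report.checked_events = len(log.events)
        return report

    report = report.merged(check_phase_sequence(log, model))
    report = report.merged(check_module_events(log, model))
    return report
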