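"""Hierarchical surgical process model for minimally invasive liver treatment (MILT).

The model has three granularity levels — procedure, phase, module — and
covers three treatment methods: laparoscopic liver resection (LLR),
laparoscopic liver ablation (LLA) and percutaneous ablation (PA).  A phase
groups modules that share a goal (e.g. "Destructive isolation"); a module is
a chain of actions with a specific goal (e.g. "Supply ducts division").

Phase-level control flow is a directed graph of classed transitions:
``common`` arrows apply to resection and ablation alike, ``ablation_only``
arrows only to LLA/PA, and ``data_transfer`` arrows carry information (images,
anamnesis) and never legitimize an execution step.  Two phases —
intra-operative complications (P11) and miscellaneous (P12) — are *anytime*
phases that may occur at any point of the operation.  Nodes carrying an
``imaging_possible`` marker admit interleaved intra-operative imaging (P05)
and re-planning (P06).

The packaged default model (:func:`default_model`) encodes the generic MILT
workflow: 13 phase indices (08a and 08b share index 08), 48 modules, and the
phase-level arrow set.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from enum import Enum
from importlib import resources
from typing import Iterable, Mapping

import yaml

__all__ = [
    "Method",
    "TREATMENT_TYPES",
    "ABLATION_METHODS",
    "GRANULARITY_LEVELS",
    "START",
    "END",
    "PhaseDef",
    "ModuleDef",
    "TransitionDef",
    "PrecedenceRule",
    "ProcessModel",
    "ModelSchemaError",
    "ModelIntegrityError",
    "load_model",
    "write_model",
    "default_model",
    "allowed_next",
    "validate_model",
]

# ---------------------------------------------------------------------------
# Enumerations and constants
# ---------------------------------------------------------------------------


class Method(str, Enum):
    """The three MILT methods covered by the model."""

    LLR = "LLR"  # laparoscopic liver resection
    LLA = "LLA"  # laparoscopic liver ablation
    PA = "PA"  # percutaneous ablation


#: LLA and PA destroy the lesion in place; LLR removes it.
ABLATION_METHODS = frozenset({Method.LLA, Method.PA})

#: Treatment types (techniques) per method.  PA shares LLA's ablation types.
TREATMENT_TYPES: Mapping[Method, frozenset[str]] = {
    Method.LLR: frozenset({"formal", "anatomical", "atypical"}),
    Method.LLA: frozenset({"RFA", "MWA", "IRE", "CA", "EI"}),
    Method.PA: frozenset({"RFA", "MWA", "IRE", "CA", "EI"}),
}

GRANULARITY_LEVELS = ("procedure", "phase", "module")

#: Virtual boundary nodes of the phase graph.
START = "START"
END = "END"

_PHASE_ID_RE = re.compile(r"^P(\d{2})([ab])?$")
_MODULE_ID_RE = re.compile(r"^(P\d{2}[ab]?)\.M(\d{2})$")

_ARROW_CLASSES = ("common", "ablation_only", "data_transfer")
_STAGES = ("pre_operative", "intra_operative")
_LEVELS = ("phase", "module")


class ModelSchemaError(ValueError):
    """A model definition does not match the schema (bad/unknown key or value)."""


class ModelIntegrityError(ValueError):
    """A model definition references undeclared nodes or breaks invariants."""


# ---------------------------------------------------------------------------
# Definition records
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PhaseDef:
    """One workflow phase.

    ``anytime`` marks the green phases (complications, miscellaneous) that may
    occur at any point of the operation; ``ablation_only`` marks the gray
    needle-manipulation phase that only LLA/PA use.
    """

    phase_id: str
    name: str
    methods: frozenset[Method]
    stage: str = "intra_operative"
    anytime: bool = False
    ablation_only: bool = False

    @property
    def index(self) -> int:
        """Numeric phase index; variants a/b share one index (P08a/P08b -> 8)."""
        m = _PHASE_ID_RE.match(self.phase_id)
        if not m:
            raise ValueError(f"malformed phase id {self.phase_id!r}")
        return int(m.group(1))


@dataclass(frozen=True)
class ModuleDef:
    """One module (highest granularity), nested under its parent phase."""

    module_id: str
    name: str
    parent_phase: str


@dataclass(frozen=True)
class TransitionDef:
    """A classed arrow between two nodes of the same granularity level."""

    source: str
    target: str
    level: str = "phase"
    arrow_class: str = "common"
    methods: frozenset[Method] = frozenset(Method)

    @property
    def is_execution(self) -> bool:
        """Data-transfer arrows carry information only, never a legal step."""
        return self.arrow_class != "data_transfer"


@dataclass(frozen=True)
class PrecedenceRule:
    """Within one instance of ``phase``, module ``before`` must precede ``after``.

    The rule binds only when both modules occur in that phase instance: the
    sample data contains e.g. leak closure without leak testing, which is
    legal — what is illegal is closing before testing when both happen.
    """

    phase: str
    before: str
    after: str


# ---------------------------------------------------------------------------
# ProcessModel container
# ---------------------------------------------------------------------------


@dataclass
class ProcessModel:
    """A hierarchical surgical process model (phases, modules, transitions)."""

    name: str
    version: str
    phases: list[PhaseDef] = field(default_factory=list)
    modules: list[ModuleDef] = field(default_factory=list)
    transitions: list[TransitionDef] = field(default_factory=list)
    module_precedence: list[PrecedenceRule] = field(default_factory=list)
    imaging_possible: frozenset[str] = frozenset()

    # -- lookups ------------------------------------------------------------

    def __post_init__(self) -> None:
        self._reindex()

    def _reindex(self) -> None:
        self._phases = {p.phase_id: p for p in self.phases}
        self._modules = {m.module_id: m for m in self.modules}

    def phase(self, phase_id: str) -> PhaseDef:
        try:
            return self._phases[phase_id]
        except KeyError:
            raise KeyError(f"unknown phase {phase_id!r}") from None

    def module(self, module_id: str) -> ModuleDef:
        try:
            return self._modules[module_id]
        except KeyError:
            raise KeyError(f"unknown module {module_id!r}") from None

    def has_phase(self, phase_id: str) -> bool:
        return phase_id in self._phases

    def has_module(self, module_id: str) -> bool:
        return module_id in self._modules

    def modules_of(self, phase_id: str) -> list[ModuleDef]:
        return [m for m in self.modules if m.parent_phase == phase_id]

    def precedence_of(self, phase_id: str) -> list[PrecedenceRule]:
        return [r for r in self.module_precedence if r.phase == phase_id]

    @property
    def phase_indices(self) -> frozenset[int]:
        """Distinct numeric phase indices (P08a/P08b count once)."""
        return frozenset(p.index for p in self.phases)

    @property
    def granularity_levels(self) -> tuple[str, ...]:
        return GRANULARITY_LEVELS

    @property
    def anytime_phases(self) -> frozenset[str]:
        return frozenset(p.phase_id for p in self.phases if p.anytime)

    def module_counts(self) -> dict[str, int]:
        counts = {p.phase_id: 0 for p in self.phases}
        for m in self.modules:
            counts[m.parent_phase] = counts.get(m.parent_phase, 0) + 1
        return counts

    def phases_for(self, method: Method) -> list[PhaseDef]:
        method = Method(method)
        return [p for p in self.phases if method in p.methods]


# ---------------------------------------------------------------------------
# Loading / writing
# ---------------------------------------------------------------------------

_TOP_KEYS = {
    "model_name",
    "version",
    "phases",
    "modules",
    "transitions",
    "module_precedence",
    "imaging_possible",
}
_PHASE_KEYS = {"phase_id", "name", "methods", "stage", "anytime", "ablation_only"}
_MODULE_KEYS = {"module_id", "name", "parent_phase"}
_TRANSITION_KEYS = {"source", "target", "level", "arrow_class", "methods"}
_PRECEDENCE_KEYS = {"phase", "before", "after"}


def _check_keys(entry: Mapping, allowed: set[str], required: set[str], what: str) -> None:
    if not isinstance(entry, Mapping):
        raise ModelSchemaError(f"{what}: expected a mapping, got {type(entry).__name__}")
    unknown = set(entry) - allowed
    if unknown:
        raise ModelSchemaError(f"{what}: unknown key {sorted(unknown)[0]!r}")
    missing = required - set(entry)
    if missing:
        raise ModelSchemaError(f"{what}: missing key {sorted(missing)[0]!r}")


def _parse_methods(raw, what: str) -> frozenset[Method]:
    if not isinstance(raw, list) or not raw:
        raise ModelSchemaError(f"{what}: 'methods' must be a non-empty list")
    out = set()
    for v in raw:
        try:
            out.add(Method(v))
        except ValueError:
            raise ModelSchemaError(f"{what}: unknown method {v!r}") from None
    return frozenset(out)


def load_model(definition_text: str) -> ProcessModel:
    """Parse a model definition (YAML/JSON dialect) into a :class:`ProcessModel`.

    Unknown keys are errors, not warnings, so the shipped model reproduces
    bit-exactly.  Raises :class:`ModelSchemaError` on malformed structure and
    :class:`ModelIntegrityError` on dangling references or invariant breaks.
    """
    try:
        doc = yaml.safe_load(definition_text)
    except yaml.YAMLError as exc:  # pragma: no cover - yaml's own message
        raise ModelSchemaError(f"unparseable model definition: {exc}") from exc
    if not isinstance(doc, Mapping):
        raise ModelSchemaError("model definition must be a mapping at top level")
    _check_keys(doc, _TOP_KEYS, {"model_name", "version", "phases"}, "model")

    phases: list[PhaseDef] = []
    for entry in doc.get("phases") or []:
        _check_keys(entry, _PHASE_KEYS, {"phase_id", "name", "methods"}, "phase")
        pid = str(entry["phase_id"])
        if not _PHASE_ID_RE.match(pid):
            raise ModelSchemaError(f"phase: malformed phase_id {pid!r}")
        stage = entry.get("stage", "intra_operative")
        if stage not in _STAGES:
            raise ModelSchemaError(f"phase {pid}: unknown stage {stage!r}")
        phases.append(
            PhaseDef(
                phase_id=pid,
                name=str(entry["name"]),
                methods=_parse_methods(entry["methods"], f"phase {pid}"),
                stage=stage,
                anytime=bool(entry.get("anytime", False)),
                ablation_only=bool(entry.get("ablation_only", False)),
            )
        )

    modules: list[ModuleDef] = []
    for entry in doc.get("modules") or []:
        _check_keys(entry, _MODULE_KEYS, {"module_id", "name", "parent_phase"}, "module")
        mid = str(entry["module_id"])
        if not _MODULE_ID_RE.match(mid):
            raise ModelSchemaError(f"module: malformed module_id {mid!r}")
        modules.append(
            ModuleDef(
                module_id=mid,
                name=str(entry["name"]),
                parent_phase=str(entry["parent_phase"]),
            )
        )

    transitions: list[TransitionDef] = []
    for entry in doc.get("transitions") or []:
        _check_keys(entry, _TRANSITION_KEYS, {"source", "target"}, "transition")
        level = entry.get("level", "phase")
        if level not in _LEVELS:
            raise ModelSchemaError(f"transition: unknown level {level!r}")
        arrow_class = entry.get("arrow_class", "common")
        if arrow_class not in _ARROW_CLASSES:
            raise ModelSchemaError(f"transition: unknown arrow_class {arrow_class!r}")
        methods = (
            _parse_methods(entry["methods"], "transition")
            if "methods" in entry
            else frozenset(Method)
        )
        transitions.append(
            TransitionDef(
                source=str(entry["source"]),
                target=str(entry["target"]),
                level=level,
                arrow_class=arrow_class,
                methods=methods,
            )
        )

    precedence: list[PrecedenceRule] = []
    for entry in doc.get("module_precedence") or []:
        _check_keys(entry, _PRECEDENCE_KEYS, _PRECEDENCE_KEYS, "module_precedence")
        precedence.append(
            PrecedenceRule(
                phase=str(entry["phase"]),
                before=str(entry["before"]),
                after=str(entry["after"]),
            )
        )

    imaging = doc.get("imaging_possible") or []
    if not isinstance(imaging, list):
        raise ModelSchemaError("imaging_possible must be a list of node ids")

    model = ProcessModel(
        name=str(doc["model_name"]),
        version=str(doc["version"]),
        phases=phases,
        modules=modules,
        transitions=transitions,
        module_precedence=precedence,
        imaging_possible=frozenset(str(x) for x in imaging),
    )
    issues = validate_model(model)
    if issues:
        raise ModelIntegrityError("; ".join(issues))
    return model


def write_model(model: ProcessModel) -> str:
    """Serialize a model back to the definition dialect (round-trips load_model)."""
    doc = {
        "model_name": model.name,
        "version": model.version,
        "phases": [
            {
                "phase_id": p.phase_id,
                "name": p.name,
                "methods": sorted(m.value for m in p.methods),
                "stage": p.stage,
                "anytime": p.anytime,
                "ablation_only": p.ablation_only,
            }
            for p in model.phases
        ],
        "modules": [
            {"module_id": m.module_id, "name": m.name, "parent_phase": m.parent_phase}
            for m in model.modules
        ],
        "transitions": [
            {
                "source": t.source,
                "target": t.target,
                "level": t.level,
                "arrow_class": t.arrow_class,
                "methods": sorted(m.value for m in t.methods),
            }
            for t in model.transitions
        ],
        "module_precedence": [
            {"phase": r.phase, "before": r.before, "after": r.after}
            for r in model.module_precedence
        ],
        "imaging_possible": sorted(model.imaging_possible),
    }
    return yaml.safe_dump(doc, sort_keys=False, allow_unicode=True)


_DEFAULT_MODEL: ProcessModel | None = None


def default_model() -> ProcessModel:
    """Return the packaged generic MILT process model (fresh copy per call)."""
    global _DEFAULT_MODEL
    if _DEFAULT_MODEL is None:
        text = resources.files("miltflow.data").joinpath("milt_model.yaml").read_text("utf-8")
        _DEFAULT_MODEL = load_model(text)
    m = _DEFAULT_MODEL
    # shallow copies keep the cached instance immutable against caller edits
    return replace(
        m,
        phases=list(m.phases),
        modules=list(m.modules),
        transitions=list(m.transitions),
        module_precedence=list(m.module_precedence),
    )


# ---------------------------------------------------------------------------
# Queries
# ---------------------------------------------------------------------------


def allowed_next(model: ProcessModel, node: str, method: Method | str) -> set[str]:
    """Phase-level successors of ``node`` legal for ``method``.

    Union of (a) targets of execution transitions (everything but
    data-transfer arrows) whose method set contains ``method``, (b) imaging
    interleaving induced by ``imaging_possible`` markers — a marked node may
    step to P05/P06 and back — and (c) all anytime phases applicable to the
    method, which may occur after any node.
    """
    method = Method(method)
    if node not in (START, END) and not model.has_phase(node):
        raise KeyError(f"unknown phase {node!r}")

    out: set[str] = set()
    for t in model.transitions:
        if t.level != "phase" or not t.is_execution:
            continue
        if t.source == node and method in t.methods:
            out.add(t.target)

    applicable = {p.phase_id for p in model.phases_for(method)}
    imaging_nodes = {"P05", "P06"} & applicable
    if node in model.imaging_possible:
        out |= imaging_nodes
    if node in imaging_nodes:
        out |= model.imaging_possible & applicable

    out |= {p for p in model.anytime_phases if p in applicable}
    return out


def validate_model(model: ProcessModel) -> list[str]:
    """All invariant violations of ``model``; empty iff well-formed.

    Checks id uniqueness and well-formedness, referential closure of
    transitions/precedence/markers, and method-set consistency of
    ablation-only elements.
    """
    issues: list[str] = []
    seen_p: set[str] = set()
    for p in model.phases:
        if p.phase_id in seen_p:
            issues.append(f"duplicate phase id {p.phase_id}")
        seen_p.add(p.phase_id)
        if not _PHASE_ID_RE.match(p.phase_id):
            issues.append(f"malformed phase id {p.phase_id!r}")
        if not p.methods:
            issues.append(f"phase {p.phase_id} has empty method set")
        if p.anytime and p.ablation_only:
            issues.append(f"phase {p.phase_id} is both anytime and ablation_only")
        if p.ablation_only and not p.methods <= ABLATION_METHODS:
            issues.append(
                f"ablation-only phase {p.phase_id} lists non-ablation method"
            )

    seen_m: set[str] = set()
    for m in model.modules:
        if m.module_id in seen_m:
            issues.append(f"duplicate module id {m.module_id}")
        seen_m.add(m.module_id)
        mm = _MODULE_ID_RE.match(m.module_id)
        if not mm:
            issues.append(f"malformed module id {m.module_id!r}")
        elif mm.group(1) != m.parent_phase:
            issues.append(
                f"module {m.module_id} id prefix disagrees with parent {m.parent_phase}"
            )
        if m.parent_phase not in seen_p:
            issues.append(f"module {m.module_id} references unknown phase {m.parent_phase}")

    def node_ok(node: str, level: str) -> bool:
        if node in (START, END):
            return True
        return model.has_phase(node) if level == "phase" else model.has_module(node)

    for t in model.transitions:
        for endpoint in (t.source, t.target):
            if not node_ok(endpoint, t.level):
                issues.append(f"transition references unknown {t.level} {endpoint!r}")
        if t.arrow_class == "ablation_only" and not t.methods <= ABLATION_METHODS:
            issues.append(
                f"ablation-only transition {t.source}->{t.target} lists non-ablation method"
            )

    for r in model.module_precedence:
        if not model.has_phase(r.phase):
            issues.append(f"precedence rule references unknown phase {r.phase!r}")
        for mid in (r.before, r.after):
            if not model.has_module(mid):
                issues.append(f"precedence rule references unknown module {mid!r}")
            elif model.module(mid).parent_phase != r.phase:
                issues.append(f"precedence module {mid} not in phase {r.phase}")

    for node in sorted(model.imaging_possible):
        if not (model.has_phase(node) or model.has_module(node)):
            issues.append(f"imaging_possible references unknown node {node!r}")

    return issues
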