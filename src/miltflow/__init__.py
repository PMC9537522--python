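"""miltflow: generic surgical process model for minimally invasive liver
treatments — event logs, conformance checking, duration analytics and
conforming-log simulation."""

from importlib import resources

from .model import (
    Method,
    TREATMENT_TYPES,
    ABLATION_METHODS,
    GRANULARITY_LEVELS,
    START,
    END,
    PhaseDef,
    ModuleDef,
    TransitionDef,
    PrecedenceRule,
    ProcessModel,
    ModelSchemaError,
    ModelIntegrityError,
    load_model,
    write_model,
    default_model,
    allowed_next,
    validate_model,
)
from .eventlog import (
    Event,
    EventLog,
    ClinicalSpans,
    StructuralIssue,
    LogParseError,
    LogInvariantError,
    read_log,
    write_log,
    validate_structure,
    derive_spans,
)
from .conformance import (
    Violation,
    ConformanceReport,
    StructuralPreconditionError,
    check_phase_sequence,
    check_module_events,
    verify,
)
from .metrics import (
    EntitySummary,
    ProcedureSummary,
    QuantitativeVerdict,
    CohortSummary,
    StructuralError,
    summarize,
    quantitative_verify,
    aggregate,
    summary_table,
)
from .simulate import (
    DwellSpec,
    SimulationConfig,
    ConfigError,
    default_dwell,
    load_config,
    simulate_log,
    simulate_cohort,
)

__version__ = "0.1.0"


def sample_surgery_log() -> EventLog:
    """The packaged sample surgery: a parenchyma-sparing laparoscopic liver
    resection annotated at phase and module level (4203 s recording)."""
    text = resources.files("miltflow.data").joinpath("sample_surgery.csv").read_text("utf-8")
    return read_log(text)
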