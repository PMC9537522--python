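# Methods

## The process model

`miltflow` models a minimally invasive liver treatment as a walk through a
directed graph of workflow **phases**, each of which contains **modules**
(the highest-granularity actions). Three abstraction levels are
distinguished — procedure, phase, module — and three treatment methods:
laparoscopic liver resection (LLR), laparoscopic liver ablation (LLA) and
percutaneous ablation (PA). Robot-assisted resection and post-operative
care are out of scope.

The shipped generic model has 13 numeric phase indices. `P08a` (destructive
isolation) and `P08b` (non-destructive isolation) are distinct nodes sharing
index 08, so phase-count queries report 13; `P08a` and `P07` (operative
field access) apply only to the laparoscopic methods, `P09` (needle
manipulation) only to the ablation methods. `P11` (complications) and `P12`
(miscellaneous) are *anytime* phases: they may occur at any point of the
operation and carry no explicit arrows.

Three design points of the default graph were genuinely open and are
resolved as model **data**, not checker logic, so users can override them by
editing the YAML definition:

- **Phase-level arrow set.** The shipped table encodes the pre-operative
  chain `P01→P02→P03→P04`, the intra-operative flow
  `P04→P05↔P06`, `P06→P07` (laparoscopic) or `P06→P09` (percutaneous),
  `P07→P08a/P08b`, `P08a↔P08b`, `P08a/P08b→P10`, the ablation arrows
  `P08b→P09→P10`, the revisit arrows `P10→{P08a, P08b, P09, P10}`, and
  `P10→P13→END`, plus data-transfer arrows (`P01/P02→P03`, `P03→P06`,
  `P05→P06`) that never legitimize an execution step. Logs may begin at OR
  entry (`START→P04`) because endoscopic recordings do not capture the
  pre-operative phases.
- **Imaging interleaving.** Intra-operative imaging can in principle happen
  at any moment, but it is deliberately modelled with explicit dependencies
  rather than as an anytime phase, because sequential/parallel structure
  around imaging is exactly what downstream analyses need. Nodes carrying an
  `imaging_possible` marker (`P04`, `P07`, `P08a`, `P08b`, `P09`, `P10`,
  `P13` by default) induce execution arrows `n↔P05` and `n↔P06`: the team
  may pause there to image and re-plan, then resume. This also supplies the
  mid-procedure re-planning route `P10→P06`.
- **Module order.** Within a phase, modules may occur in any order and any
  number of times, except explicitly stated chains, encoded as precedence
  pairs: supply-duct isolation before temporary/permanent occlusion and
  permanent occlusion before division (`P08a`), leak testing before leak
  closure and trocar removal before incision closing (`P13`). A precedence
  pair is violated only when **both** modules occur in the same phase
  instance and the first `after` event starts before the first `before`
  event — the packaged sample surgery registers leak closure with no leak
  test, which is legal.

Model definitions are strict: unknown keys are schema errors and dangling
node references are integrity errors, so the shipped model loads
bit-reproducibly. A JSON-Schema document
(`src/miltflow/data/milt_model.schema.json`) is published for third-party
validation.

## Event logs

Events are half-open intervals `[start_s, end_s)` in integer seconds, so
adjacent events share a boundary without overlapping, and zero-length events
are representable (they count as occurrences with zero duration — a
published per-surgery table distinguishes momentary marks from non-events).
Structural validity requires every module event to nest inside a phase event
of its parent phase and non-parallel phase events to be pairwise disjoint;
only events carrying the explicit `parallel` flag may overlap. The log's
declared `total_s` is authoritative for idle accounting: idle is the part of
the recording covered by no phase event (endoscope out of view), and
intra-phase gaps are attributed to the phase. Unknown entity ids are
deliberately *not* parse errors — they surface during conformance checking,
so logs exchange cleanly across model versions.

The four nested clinical spans are derived rather than annotated: operation
is the whole recording; intervention starts at the first incision (`P07`) or
first needle manipulation (`P09`); surgery starts at the first `P07` only
(absent for percutaneous procedures); treatment spans the `P10` events.

## Conformance checking

The phase check linearizes phase events by start time, removes anytime-phase
events (counting them as wildcard insertions — they can never *bridge* an
otherwise illegal transition), and then requires each remaining pair to be a
repeat or an execution arrow applicable to the declared method. Repeats
(`a = a`) are always legal because phases genuinely recur (destructive
isolation occurs twice in the sample surgery); *revisits* to earlier phases
need an explicit back-arrow. Verdicts are boolean with itemized violations;
no token-replay fitness or alignment cost is computed. A log carries one
declared method: converted or aborted procedures should be split by the
user before checking.

`verify()` folds structural findings, the phase-sequence check and the
module-precedence check into one report. When structural blockers (overlaps
of non-parallel events, orphan modules, broken intervals) are present the
sequence semantics are undefined and the sequence checks are skipped.

## Quantitative verification and aggregation

`summarize` produces integer duration sums and occurrence counts per entity
at both levels, censused against the model's full inventory when a model is
supplied (zero rows are printed, as in published tables). The conservation
check `quantitative_verify` passes iff
`|total − (Σ phase durations − parallel overlap + idle)| ≤ tolerance`
(default tolerance 0 s) and no phase's module sums exceed the phase
duration. For cohorts, the *pooled fraction* of a phase is
Σ duration / Σ total over all procedures, while *mean duration* and *mean
occurrence* are per-procedure means; both conventions are reported because
"share of time in a phase" is ambiguous between them.

## Simulator

The generator is a seeded semi-Markov walk: forward arrows are chosen
uniformly; backward arrows (revisits, the imaging/planning loop) fire with
per-arrow probabilities (`default_repeat` for unlisted ones, default 0).
Each visited phase is tiled by one occurrence of each of its modules in a
precedence-respecting random order, with the phase's dwell time split across
them by a Dirichlet draw. Dwell distributions are per phase: constant,
lognormal (default, `dispersion` = log-scale sigma 0.5) or gamma
(`dispersion` = coefficient of variation); lognormal/gamma draws are
parameterised to have exactly the configured mean. The default means are a
documented, overridable preset anchored on the packaged sample surgery where
it provides a value (P05 82 s, P06 26 s, P07 89 s, P08a 2534 s, P10 647 s,
P11 140 s, P13 528 s) and on round figures elsewhere (e.g. P04 900 s); the
preset is a convenience for testing, not an estimate of clinical reality.
Anytime interruptions arrive as a Poisson process (`anytime_rate` per hour)
and *pause* the current phase event, splitting it and its module tiling at
the interruption instant, so phase events stay disjoint and each split piece
counts as an occurrence. By default simulation starts at OR entry (`P04`),
mimicking endoscopic recordings; `include_preoperative` prepends
`P01→P02→P03`.

One random stream per config seed is consumed in documented order — path,
then per-phase module order and dwell, then idle gaps, then interruptions —
so output is byte-identical for identical (model, config), and a cohort's
first log coincides with a single simulation at the same seed.

## What the synthetic data does and does not show

Simulated logs exercise every structural feature the checker and metrics
rely on: method-dependent routing, phase revisits, anytime interruptions
mid-phase, module precedence, idle gaps, and exact tiling of phases by
modules. They do **not** emulate annotation noise (boundary jitter, missed
or mislabelled events), parallel-flagged overlapping activities, correlated
dwell times, or method conversion mid-procedure — so green simulator-based
tests demonstrate the pipeline's correctness on clean conforming data, not
robustness to real annotation artefacts.

The packaged sample-surgery fixture reproduces a published per-surgery
table's per-entity duration sums and occurrence counts exactly (phase sums
82/26/89/2534/647/140/528 s, idle 157 s, total 4203 s). That table prints
aggregates only, so the fixture's individual event boundaries are a
documented convention chosen to nest correctly and conform to the default
model; every analysis in this package depends only on the sums and counts.
One occurrence digit in the source table (the complications row) is
typographically ambiguous; the fixture uses one occurrence, and no computed
quantity depends on that choice.

## Numerical choices and edge cases

- All event arithmetic is integer seconds; no floating-point durations.
- Half-open intervals: `[a, b)` and `[b, c)` are disjoint; zero-length
  events overlap nothing and nest by endpoint inclusion.
- Precedence comparisons use first start times; equal starts do not violate
  a rule (parallel registration).
- Duration splitting uses floor-plus-top-up so module durations always sum
  exactly to the phase dwell; non-constant dwell draws are clamped to ≥ 1 s.
- `aggregate` rejects empty collections and zero total recording time.
- Problem sizes in the test suite (1000 simulated logs for soundness, 500
  procedures for dwell recovery, 1000 random sequences for the
  enumeration cross-check) complete in a few seconds and give 3-standard-
  error and exhaustive-membership resolution respectively.

## Known limitations

- The default module-level constraint set contains only the orderings the
  phase descriptions state; the full module-level arrow layout of the
  original diagram is richer and can be supplied as a custom model file.
- The conformance verdict is unweighted: one violation invalidates a log,
  with no notion of severity or fitness.
- Cohort statistics are descriptive; no inter-cohort hypothesis testing is
  provided.
- The simulator draws dwell times independently across phases and
  occurrences; real procedures show strong dependence (e.g. lesion count
  drives both isolation and treatment time).
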