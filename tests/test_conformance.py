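"""Qualitative verification: phase sequences, module order, full verify()."""

import dataclasses
import itertools

import numpy as np
import pytest

import miltflow as mf
from miltflow.model import Method, PhaseDef, TransitionDef
from conftest import make_phase_log

ALL = frozenset(Method)


class TestPhaseSequence:
    def test_nominal_resection_path_is_valid(self, model):
        log = make_phase_log(["P04", "P05", "P06", "P07", "P08a", "P10", "P13"])
        report = mf.check_phase_sequence(log, model)
        assert report.valid
        assert report.checked_events == 7

    def test_needle_manipulation_rejected_for_resection(self, model):
        log = make_phase_log(["P04", "P05", "P06", "P09", "P10", "P13"])
        report = mf.check_phase_sequence(log, model)
        assert not report.valid
        assert any(v.kind == "ablation_only_in_resection" for v in report.violations)

    def test_operative_field_access_rejected_for_percutaneous(self, model):
        log = make_phase_log(["P04", "P05", "P06", "P07"], method="PA",
                             treatment_type="RFA")
        report = mf.check_phase_sequence(log, model)
        assert any(v.kind == "inapplicable_phase" for v in report.violations)

    def test_anytime_insertion_counts_wildcards_and_keeps_validity(self, model):
        base = ["P04", "P05", "P06", "P07", "P08a", "P10", "P13"]
        for pos in range(len(base) + 1):
            seq = base[:pos] + ["P11"] + base[pos:]
            report = mf.check_phase_sequence(make_phase_log(seq), model)
            assert report.valid
            assert report.wildcard_insertions == 1

    def test_wildcard_does_not_bridge_illegal_transition(self, model):
        # P13 -> P04 is illegal with or without a complication in between
        log = make_phase_log(["P13", "P11", "P04"])
        report = mf.check_phase_sequence(log, model)
        assert any(v.kind == "illegal_transition" for v in report.violations)

    def test_empty_sequence_is_vacuously_valid(self, model):
        log = mf.EventLog("X", "LLR", "atypical", 10, [])
        report = mf.check_phase_sequence(log, model)
        assert report.valid and report.checked_events == 0

    def test_phase_repeat_is_always_legal(self, model):
        log = make_phase_log(["P08a", "P08a", "P08a", "P10", "P10"])
        assert mf.check_phase_sequence(log, model).valid

    def test_structurally_invalid_log_raises_precondition(self, model):
        log = mf.EventLog(
            "X", "LLR", "atypical", 100,
            [mf.Event(1, "phase", "P05", 0, 10), mf.Event(2, "phase", "P06", 5, 15)],
        )
        with pytest.raises(mf.StructuralPreconditionError):
            mf.check_phase_sequence(log, model)

    def test_adding_a_transition_never_invalidates(self, model):
        """Monotonicity: a richer arrow set accepts a superset of logs."""
        log = make_phase_log(["P04", "P05", "P06", "P07", "P08a", "P10", "P13"])
        assert mf.check_phase_sequence(log, model).valid
        richer = dataclasses.replace(
            model,
            transitions=model.transitions
            + [TransitionDef("P13", "P04", methods=ALL)],
        )
        assert mf.check_phase_sequence(log, richer).valid
        # and a previously illegal pair becomes legal only in the richer model
        back = make_phase_log(["P13", "P04"])
        assert not mf.check_phase_sequence(back, model).valid
        assert mf.check_phase_sequence(back, richer).valid


def _log_with_modules(phase_spans, module_spans, method="LLR", tt="atypical"):
    events = []
    eid = 1
    for entity, s, e in phase_spans:
        events.append(mf.Event(eid, "phase", entity, s, e))
        eid += 1
    for entity, s, e in module_spans:
        events.append(mf.Event(eid, "module", entity, s, e))
        eid += 1
    total = max(e for _, _, e in phase_spans)
    return mf.EventLog("X", method, tt, total, events)


class TestModuleEvents:
    def test_division_before_occlusion_is_illegal(self, model):
        log = _log_with_modules(
            [("P08a", 0, 100)],
            [("P08a.M06", 0, 40), ("P08a.M05", 40, 100)],
        )
        report = mf.check_module_events(log, model)
        assert any(v.kind == "illegal_module_order" for v in report.violations)

    def test_leak_testing_then_closure_is_valid(self, model):
        log = _log_with_modules(
            [("P13", 0, 100)],
            [("P13.M05", 0, 30), ("P13.M06", 30, 100)],
        )
        assert mf.check_module_events(log, model).valid

    def test_closure_without_testing_is_valid(self, model):
        # the precedence rule binds only when both modules occur
        log = _log_with_modules([("P13", 0, 100)], [("P13.M06", 0, 100)])
        assert mf.check_module_events(log, model).valid

    def test_unconstrained_modules_in_any_order(self, model):
        for order in itertools.permutations(["P10.M01", "P10.M02", "P10.M03"]):
            spans = [(m, i * 10, (i + 1) * 10) for i, m in enumerate(order)]
            log = _log_with_modules([("P10", 0, 30)], spans)
            assert mf.check_module_events(log, model).valid

    def test_module_inside_wrong_phase_event(self, model):
        # structurally an orphan: surfaced via verify(), not the sequence check
        log = _log_with_modules([("P10", 0, 100)], [("P08a.M01", 0, 50)])
        report = mf.verify(log, model)
        assert any(v.kind == "orphan_module" for v in report.violations)


class TestVerify:
    def test_sample_surgery_verifies_valid(self, sample_log, model):
        report = mf.verify(sample_log, model)
        assert report.valid
        assert report.wildcard_insertions == 1  # one complications event

    def test_unknown_entity_surfaces_as_inapplicable_phase(self, model):
        log = make_phase_log(["P04", "P99"])
        report = mf.verify(log, model)
        assert any(
            v.kind == "inapplicable_phase" and "P99" in v.message
            for v in report.violations
        )

    def test_treatment_type_method_mismatch(self, model):
        log = make_phase_log(["P04", "P05"], method="LLR", treatment_type="RFA")
        report = mf.verify(log, model)
        assert any(v.kind == "method_mismatch" for v in report.violations)

    def test_simulated_logs_verify_valid(self, model):
        for seed in range(20):
            cfg = mf.SimulationConfig(method="LLA", treatment_type="MWA",
                                      seed=seed, anytime_rate=2.0,
                                      default_repeat=0.2)
            assert mf.verify(mf.simulate_log(model, cfg), model).valid


# ---------------------------------------------------------------------------
# Independent oracle: exhaustive path enumeration on small random models
# ---------------------------------------------------------------------------


def random_small_model(rng, n_phases):
    phases = [
        PhaseDef(f"P{i + 1:02d}", f"phase {i + 1}", ALL,
                 anytime=bool(rng.random() < 0.2))
        for i in range(n_phases)
    ]
    ids = [p.phase_id for p in phases]
    transitions = [
        TransitionDef(a, b, methods=ALL)
        for a in ids
        for b in ids
        if a != b and rng.random() < 0.3
    ]
    return mf.ProcessModel(name="rand", version="1", phases=phases,
                           transitions=transitions)


def enumerate_allowed_sequences(m, method, max_len):
    """All legal non-anytime phase sequences up to max_len, grown by DFS
    directly over the raw transition table (independent of allowed_next)."""
    core = [p.phase_id for p in m.phases if not p.anytime]
    step = {
        p: {p}
        | {
            t.target
            for t in m.transitions
            if t.source == p and t.is_execution and method in t.methods
            and t.target in core
        }
        for p in core
    }
    allowed = set()
    frontier = [(p,) for p in core]
    allowed.update(frontier)
    for _ in range(max_len - 1):
        nxt = [seq + (t,) for seq in frontier for t in sorted(step[seq[-1]])]
        allowed.update(nxt)
        frontier = nxt
    return allowed


def test_phase_check_agrees_with_exhaustive_enumeration():
    """On random models with <= 8 phases, the pairwise sequence check and
    brute-force enumeration of all allowed paths give identical verdicts."""
    rng = np.random.default_rng(2024)
    method = Method.LLR
    checked = 0
    for _ in range(12):
        n = int(rng.integers(3, 7))
        m = random_small_model(rng, n)
        core = [p.phase_id for p in m.phases if not p.anytime]
        if not core:
            continue
        max_len = 5
        allowed = enumerate_allowed_sequences(m, method, max_len)
        for _ in range(30):
            length = int(rng.integers(1, max_len + 1))
            seq = [core[int(rng.integers(len(core)))] for _ in range(length)]
            log = make_phase_log(seq)
            verdict = mf.check_phase_sequence(log, m).valid
            assert verdict == (tuple(seq) in allowed), (seq, m.transitions)
            checked += 1
    assert checked >= 300
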