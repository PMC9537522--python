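"""Duration/occurrence summaries, conservation and cohort aggregation."""

import collections
import dataclasses

import pytest

import miltflow as mf
from conftest import make_phase_log


class TestSummarize:
    def test_sample_surgery_phase_durations(self, sample_log, model):
        s = mf.summarize(sample_log, model)
        expected = {"P05": 82, "P06": 26, "P07": 89, "P08a": 2534,
                    "P10": 647, "P11": 140, "P13": 528}
        for pid, dur in expected.items():
            assert s.phase_rows[pid].duration_s == dur
        assert s.idle_s == 157
        assert s.total_s == 4203
        assert s.phase_duration_total + s.idle_s == 4203

    def test_sample_surgery_module_sums_equal_phase_durations(self, sample_log, model):
        s = mf.summarize(sample_log, model)
        assert [s.module_rows[f"P08a.M0{i}"].duration_s for i in range(1, 7)] == \
            [90, 518, 842, 0, 267, 817]
        assert sum([90, 518, 842, 0, 267, 817]) == s.phase_rows["P08a"].duration_s
        assert (s.module_rows["P10.M01"].duration_s,
                s.module_rows["P10.M02"].duration_s) == (171, 476)

    def test_zero_occurrence_entities_censused_against_model(self, sample_log, model):
        s = mf.summarize(sample_log, model)
        assert s.module_rows["P08a.M04"] == mf.EntitySummary("P08a.M04", 0, 0)
        assert s.phase_rows["P09"] == mf.EntitySummary("P09", 0, 0)
        assert len(s.module_rows) == len(model.modules)

    def test_single_event(self):
        log = mf.EventLog("X", "LLR", "atypical", 100,
                          [mf.Event(1, "phase", "P05", 0, 10)])
        s = mf.summarize(log)
        assert s.phase_rows["P05"] == mf.EntitySummary("P05", 10, 1)
        assert s.idle_s == 90

    def test_structurally_invalid_log_rejected(self, model):
        log = mf.EventLog(
            "X", "LLR", "atypical", 100,
            [mf.Event(1, "phase", "P05", 0, 10), mf.Event(2, "phase", "P06", 5, 15)],
        )
        with pytest.raises(mf.StructuralError):
            mf.summarize(log, model)

    def test_occurrence_matches_brute_force_recount(self, sample_log, model):
        s = mf.summarize(sample_log, model)
        counter = collections.Counter(
            (e.level, e.entity) for e in sample_log.events
        )
        for pid, row in s.phase_rows.items():
            assert row.occurrence == counter.get(("phase", pid), 0)
        for mid, row in s.module_rows.items():
            assert row.occurrence == counter.get(("module", mid), 0)

    def test_conservation_on_simulated_logs(self, model):
        for seed in range(10):
            cfg = mf.SimulationConfig(method="LLR", treatment_type="formal",
                                      seed=seed, anytime_rate=3.0,
                                      idle_gap=mf.DwellSpec("constant", 30, 0))
            s = mf.summarize(mf.simulate_log(model, cfg))
            assert s.phase_duration_total + s.idle_s == s.total_s

    def test_additivity_of_disjoint_concatenation(self, model):
        a = make_phase_log(["P04", "P05", "P06"], dur=50, gap=10, total_s=200)
        shifted = [
            dataclasses.replace(e, start_s=e.start_s + 200, end_s=e.end_s + 200)
            for e in make_phase_log(["P07", "P08a"], dur=40, gap=5).events
        ]
        b_total = 100
        combined = mf.EventLog("X", "LLR", "atypical", 200 + b_total,
                               a.events + shifted)
        sa = mf.summarize(a)
        sb = mf.summarize(mf.EventLog("X", "LLR", "atypical", b_total,
                                      make_phase_log(["P07", "P08a"], dur=40, gap=5).events))
        sc = mf.summarize(combined)
        for pid in set(sa.phase_rows) | set(sb.phase_rows):
            assert sc.phase_rows[pid].duration_s == (
                sa.phase_rows.get(pid, mf.EntitySummary(pid, 0, 0)).duration_s
                + sb.phase_rows.get(pid, mf.EntitySummary(pid, 0, 0)).duration_s
            )
        assert sc.idle_s == sa.idle_s + sb.idle_s


class TestQuantitativeVerify:
    def test_sample_surgery_passes_at_zero_tolerance(self, sample_log, model):
        assert mf.quantitative_verify(mf.summarize(sample_log, model), 0).passed

    def test_truncated_declaration_fails_then_passes_at_tolerance(self):
        summary = mf.ProcedureSummary(
            procedure_id="X",
            phase_rows={"P05": mf.EntitySummary("P05", 80, 1)},
            module_rows={},
            idle_s=10,
            total_s=100,
        )
        verdict = mf.quantitative_verify(summary, 0)
        assert not verdict.passed and verdict.discrepancy_s == 10
        assert mf.quantitative_verify(summary, 10).passed

    def test_module_overrun_fails(self):
        summary = mf.ProcedureSummary(
            procedure_id="X",
            phase_rows={"P05": mf.EntitySummary("P05", 50, 1)},
            module_rows={"P05.M02": mf.EntitySummary("P05.M02", 60, 1)},
            idle_s=50,
            total_s=100,
        )
        verdict = mf.quantitative_verify(summary, 0)
        assert not verdict.passed
        assert verdict.phase_overruns == {"P05": 10}


class TestAggregate:
    def test_single_procedure_pooled_fraction(self, sample_log, model):
        cohort = mf.aggregate([mf.summarize(sample_log, model)])
        assert cohort.pooled_fraction["P10"] == pytest.approx(647 / 4203)
        assert cohort.n_procedures == 1

    def test_scale_invariance_for_identical_procedures(self, sample_log, model):
        s = mf.summarize(sample_log, model)
        one, two = mf.aggregate([s]), mf.aggregate([s, s])
        assert two.pooled_fraction == one.pooled_fraction
        assert two.mean_duration_s == one.mean_duration_s

    def test_idle_log_dilutes_treatment_fraction(self, sample_log, model):
        s = mf.summarize(sample_log, model)
        idle = mf.summarize(mf.EventLog("I", "LLR", "atypical", 1000, []))
        assert mf.aggregate([s, idle]).pooled_fraction["P10"] < \
            mf.aggregate([s]).pooled_fraction["P10"]

    def test_fractions_normalize(self, model):
        logs = [
            mf.simulate_log(model, mf.SimulationConfig(
                method="LLA", treatment_type="CA", seed=seed,
                idle_gap=mf.DwellSpec("constant", 20, 0)))
            for seed in range(5)
        ]
        cohort = mf.aggregate([mf.summarize(l) for l in logs])
        total = sum(cohort.pooled_fraction.values()) + cohort.idle_fraction
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_empty_collection_rejected(self):
        with pytest.raises(ValueError):
            mf.aggregate([])


class TestSummaryTable:
    def test_table_has_idle_and_sum_rows(self, sample_log, model):
        df = mf.summary_table(mf.summarize(sample_log, model), model)
        assert list(df["phase"])[-2:] == ["Idle", "Sum"]
        sum_row = df[df["phase"] == "Sum"].iloc[0]
        assert sum_row["phase_duration_s"] == 4203
        p08a = df[df["module"] == "P08a.M03"].iloc[0]
        assert p08a["module_duration_s"] == 842
        assert p08a["module_occurrence"] == 21
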