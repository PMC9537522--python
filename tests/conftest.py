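import pytest

import miltflow as mf


@pytest.fixture(scope="session")
def model():
    return mf.default_model()


@pytest.fixture(scope="session")
def sample_log():
    return mf.sample_surgery_log()


def make_phase_log(
    entities,
    method="LLR",
    treatment_type="atypical",
    dur=10,
    gap=0,
    total_s=None,
):
    """Build a phase-level log from a label sequence with uniform durations."""
    events, t = [], 0
    for i, entity in enumerate(entities):
        events.append(mf.Event(i + 1, "phase", entity, t, t + dur))
        t += dur + gap
    return mf.EventLog(
        procedure_id="TEST",
        method=method,
        treatment_type=treatment_type,
        total_s=total_s if total_s is not None else max(t, 1),
        events=events,
    )
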