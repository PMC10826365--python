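import numpy as np
import pytest

from heatlimits.synthdata import TraceSpec, generate_trace
from heatlimits.trials import RampSchedule


@pytest.fixture
def pcrit_schedule():
    """Representative humid-limb ramp: fixed T_db 40 °C, P_a from 21 mmHg."""
    return RampSchedule(mode="P_crit", fixed_value=40.0, start_value=21.0)


@pytest.fixture
def noise_free_record(pcrit_schedule):
    """Noise-free trial with true critical P_a = 29 mmHg (inflection at 70 min)."""
    spec = TraceSpec(schedule=pcrit_schedule, true_critical=29.0, noise_sd=0.0)
    return generate_trace(spec, trial_id="clean", subject_id="S1")


def make_noisy_record(schedule, seed, *, noise_sd=0.05, ar1=0.8, **kw):
    spec = TraceSpec(schedule=schedule, true_critical=29.0,
                     noise_sd=noise_sd, ar1=ar1, seed=seed, **kw)
    return generate_trace(spec, trial_id=f"noisy-{seed}", subject_id="S1")


@pytest.fixture
def noisy_record_factory():
    return make_noisy_record
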