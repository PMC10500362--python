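import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from wardews import (
    CohortAnalysis,
    CohortConfig,
    Parameter,
    PatientRecord,
    ScoreBandTable,
    VitalChannel,
    generate_cohort,
)

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def table() -> ScoreBandTable:
    return ScoreBandTable.default()


def make_channel(param, values, pid="P1", start=0):
    """Minute-sampled channel from a plain list of values."""
    values = np.asarray(values, dtype=float)
    return VitalChannel(
        patient_id=pid,
        parameter=Parameter(param),
        times=np.arange(start, start + values.size),
        values=values,
    )


def make_patient(channel_values, end_min, pid="P1", nurse=()):
    """Patient whose channels repeat per-hour parameter values minute by minute.

    ``channel_values``: mapping parameter -> list of per-hour values (each
    held constant for 60 minutes), or parameter -> (times, values) arrays.
    """
    channels = {}
    for param, spec in channel_values.items():
        param = Parameter(param)
        if isinstance(spec, tuple):
            times, values = spec
            ch = VitalChannel(
                patient_id=pid,
                parameter=param,
                times=np.asarray(times, dtype=np.int64),
                values=np.asarray(values, dtype=float),
            )
        else:
            values = np.repeat(np.asarray(spec, dtype=float), 60)
            ch = make_channel(param, values, pid=pid)
        channels[param] = ch
    return PatientRecord(
        patient_id=pid,
        recording_end_min=end_min,
        channels=channels,
        nurse_observations=list(nurse),
    )


@pytest.fixture(scope="session")
def small_cohort():
    """A small but fully featured synthetic cohort shared across tests."""
    cfg = CohortConfig(
        seed=42,
        n_event_patients=3,
        n_control_patients=5,
        recording_hours_range=(96, 120),
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def small_analysis(small_cohort):
    return CohortAnalysis.from_cohort(small_cohort)
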