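import numpy as np
import pytest

from pulsemorph import (
    Channel,
    GatingConfig,
    MeasurementMeta,
    ParticleRecord,
    PulseShape,
    SimParams,
    simulate_run,
)


def make_pulse(samples, channel=Channel.FWS, um_per_sample=1.0, saturation=1e4):
    return PulseShape(channel, np.asarray(samples, float), um_per_sample, saturation)


def make_particle(fws, sws, fl_green=None, um_per_sample=1.0, saturation=1e4, pid="p0"):
    pulses = {
        Channel.FWS: make_pulse(fws, Channel.FWS, um_per_sample, saturation),
        Channel.SWS: make_pulse(sws, Channel.SWS, um_per_sample, saturation),
    }
    if fl_green is not None:
        pulses[Channel.FL_GREEN] = make_pulse(
            fl_green, Channel.FL_GREEN, um_per_sample, saturation
        )
    return ParticleRecord(pid, pulses)


@pytest.fixture(scope="session")
def default_config():
    return GatingConfig()


@pytest.fixture(scope="session")
def small_run():
    """A mixed simulated run shared across tests (session-scoped, read-only)."""
    params = SimParams(n=400, seed=11)
    records, truth, meta = simulate_run(params)
    return params, records, truth, meta


@pytest.fixture
def meta():
    return MeasurementMeta(pump_speed=15.0, duration=80.0, dilution_factor=1000.0)
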