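import numpy as np
import pytest

from divertsim.arrivals import ArrivalRecord, ArrivalStream
from divertsim.config import default_experiment, resolve_network
from divertsim.los import LosModel
from divertsim.network import Subspecialty, build_network

TRAUMA = Subspecialty.TRAUMA_SURGERY


def trauma_pair_config(cap_a=2, cap_b=5):
    return {
        "hospitals": [
            {"id": "A", "x": 0.0, "y": 0.0, "units": {"trauma_surgery": cap_a}},
            {"id": "B", "x": 10.0, "y": 0.0, "units": {"trauma_surgery": cap_b}},
        ]
    }


@pytest.fixture
def trauma_pair():
    """Two trauma units A (capacity 2) and B (capacity 5); A's closest peer is B."""
    return build_network(trauma_pair_config())


@pytest.fixture(scope="session")
def resolved_default():
    """The built-in synthetic experiment with capacities resolved by pretest."""
    exp = default_experiment()
    return exp, resolve_network(exp)


def make_stream(times, unit="A:trauma_surgery", horizon=None, subspecialty=TRAUMA):
    recs = tuple(
        ArrivalRecord(patient_id=i + 1, time=float(t), subspecialty=subspecialty, assigned_unit=unit)
        for i, t in enumerate(times)
    )
    if horizon is None:
        horizon = (max(times) + 1000.0) if len(times) else 100.0
    return ArrivalStream(records=recs, horizon=horizon)


def poisson_stream(rate, horizon, unit, rng, subspecialty=TRAUMA):
    t, times = 0.0, []
    while True:
        t += rng.exponential(1.0 / rate)
        if t >= horizon:
            break
        times.append(t)
    return make_stream(times, unit=unit, horizon=horizon, subspecialty=subspecialty)


class SequenceLos:
    """LOS stub returning a fixed sequence of durations in admission order."""

    def __init__(self, durations):
        self._seq = list(durations)

    def sample(self, subspecialty, rng):
        return self._seq.pop(0)

    def mean(self, subspecialty):
        raise NotImplementedError
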