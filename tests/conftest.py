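"""Shared fixtures: seeded spike-train generators used across the suite."""

from __future__ import annotations

import numpy as np
import pytest

from spikeinfer.spike_data import SpikeTrain, SpikeTrainSet, quantize_times


def poisson_train(
    rate: float,
    duration: float,
    seed: int,
    neuron_id: str = "n0",
    quantize: bool = True,
) -> SpikeTrain:
    """Homogeneous Poisson spike train on [0, duration)."""
    rng = np.random.default_rng(seed)
    n = rng.poisson(rate * duration)
    times = np.sort(rng.uniform(0.0, duration, size=n))
    if quantize:
        times = quantize_times(times)
    times = times[times < duration]
    return SpikeTrain(spike_times=times, duration=duration, neuron_id=neuron_id)


def regular_train(
    period: float, duration: float, neuron_id: str = "n0", offset: float = 0.0
) -> SpikeTrain:
    times = np.arange(offset, duration, period)
    return SpikeTrain(
        spike_times=quantize_times(times), duration=duration, neuron_id=neuron_id
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def poisson_set() -> SpikeTrainSet:
    trains = tuple(
        poisson_train(1.0, 500.0, seed=100 + k, neuron_id=f"n{k}") for k in range(3)
    )
    return SpikeTrainSet(trains=trains, condition="CON", metadata={"origin": "test"})


@pytest.fixture
def make_poisson_train():
    return poisson_train


@pytest.fixture
def make_regular_train():
    return regular_train
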