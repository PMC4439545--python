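"""Seeded fixture generators for tests and recovery experiments.

Two generators produce paired control/drug recordings whose generating
parameters obey the commonality structure (shared g_c for the PIX pairing,
shared g_i for the CBX pairing), with optional per-segment jitter of scale
``sigma_true`` around the neuron-level values:

* ``renewal``  - fast gamma-renewal trains whose rate decreases with g_i
  and whose pairwise spike-time jitter decreases with g_c; used by unit
  tests that need a forward model in seconds.
* ``surrogate`` - the lattice network simulator; slower, used by the
  end-to-end recovery experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np

from ._utils import derive_seed
from .spike_data import SpikeTrain, SpikeTrainSet, quantize_times
from .surrogate_sim import SimConfig, simulate_network

# renewal-family response surfaces: rate falls with g_i, jitter with g_c
_BASE_RATE = 2.0  # Hz at g_i = 0
_RATE_SLOPE = 1.2  # rate = base / (1 + slope * g_i)
_BASE_JITTER = 0.06  # s at g_c = 0
_JITTER_SLOPE = 2.5  # jitter = base / (1 + slope * g_c)
_GAMMA_SHAPE = 2.0
_P_KEEP = 0.9
_INDEP_FRAC = 0.1


def renewal_rate(g_i: float) -> float:
    """Mean mother-process rate (Hz) implied by g_i."""
    return _BASE_RATE / (1.0 + _RATE_SLOPE * g_i)


def renewal_jitter(g_c: float) -> float:
    """Per-neuron spike-time jitter SD (s) implied by g_c."""
    return _BASE_JITTER / (1.0 + _JITTER_SLOPE * g_c)


def _gamma_renewal_times(
    rate: float, duration: float, rng: np.random.Generator, shape: float = _GAMMA_SHAPE
) -> np.ndarray:
    """Gamma-renewal spike times on [0, duration)."""
    if rate <= 0:
        return np.empty(0)
    n_max = max(16, int(duration * rate * 3 + 20))
    isis = rng.gamma(shape, 1.0 / (shape * rate), size=n_max)
    times = np.cumsum(isis) - rng.uniform(0, 1.0 / rate)  # random start phase
    return times[(times >= 0) & (times < duration)]


def renewal_recording(
    g_i: float,
    g_c: float,
    duration: float,
    seed: int,
    n_neurons: int = 3,
    condition: str = "SIM",
) -> SpikeTrainSet:
    """Correlated gamma-renewal recording parameterized by (g_i, g_c).

    All neurons derive from one mother train (rate set by g_i); each keeps
    90% of the mother spikes, jitters them with an SD set by g_c, and adds
    a small independent Poisson component.
    """
    rng = np.random.default_rng(seed)
    rate = renewal_rate(g_i)
    jitter = renewal_jitter(g_c)
    mother = _gamma_renewal_times(rate, duration, rng)
    trains = []
    for k in range(n_neurons):
        keep = mother[rng.uniform(size=mother.size) < _P_KEEP]
        times = keep + rng.normal(0.0, jitter, size=keep.size)
        n_indep = rng.poisson(_INDEP_FRAC * rate * duration)
        times = np.concatenate([times, rng.uniform(0, duration, size=n_indep)])
        times = quantize_times(times[(times >= 0) & (times < duration)])
        trains.append(
            SpikeTrain(spike_times=times, duration=duration, neuron_id=f"n{k}")
        )
    return SpikeTrainSet(
        trains=tuple(trains),
        condition=condition,
        metadata={"g_i": g_i, "g_c": g_c, "seed": seed},
    )


@dataclass(frozen=True)
class FixtureSpec:
    """Specification of one paired-condition synthetic neuron."""

    gi_con: float
    gc_con: float
    gi_pha: float
    gc_pha: float
    pha_label: str = "PIX"
    generator: str = "renewal"  # or "surrogate"
    sigma_true: float = 0.0
    n_neurons: int = 3
    duration: float = 500.0
    seg_len: float = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pha_label not in ("PIX", "CBX"):
            raise ValueError("pha_label must be PIX or CBX")
        if self.generator not in ("renewal", "surrogate"):
            raise ValueError("generator must be 'renewal' or 'surrogate'")
        if self.pha_label == "PIX" and self.gc_con != self.gc_pha:
            raise ValueError("PIX pairing requires gc_con == gc_pha")
        if self.pha_label == "CBX" and self.gi_con != self.gi_pha:
            raise ValueError("CBX pairing requires gi_con == gi_pha")
        if self.sigma_true < 0:
            raise ValueError("sigma_true must be >= 0")


@dataclass(frozen=True)
class FixtureResult:
    """Generated pair of recordings plus the generating truth record."""

    con: SpikeTrainSet
    pha: SpikeTrainSet
    truth: dict


def _segment_params(
    g: tuple[float, float], sigma: float, n_seg: int, rng: np.random.Generator
) -> list[tuple[float, float]]:
    """Neuron-level parameters jittered per segment (clipped at 0)."""
    if sigma == 0:
        return [g] * n_seg
    out = []
    for _ in range(n_seg):
        gi = max(0.0, g[0] + rng.normal(0.0, sigma))
        gc = max(0.0, g[1] + rng.normal(0.0, sigma))
        out.append((gi, gc))
    return out


def _build_recording(
    params: list[tuple[float, float]],
    spec: FixtureSpec,
    condition: str,
    seed: int,
) -> SpikeTrainSet:
    """Concatenate per-segment generated spike trains into one recording."""
    seg_len = spec.seg_len
    constant = all(p == params[0] for p in params)
    if spec.generator == "surrogate":
        cfg = SimConfig(n_neurons=max(spec.n_neurons, 9), noise_seed=seed,
                        duration=spec.duration if constant else seg_len)
        if constant:
            sts = simulate_network(*params[0], cfg)
            trains = sts.trains[: spec.n_neurons]
        else:
            pieces = []
            for t, p in enumerate(params):
                cfg_t = replace(cfg, noise_seed=derive_seed(seed, t))
                pieces.append(simulate_network(*p, cfg_t))
            trains = []
            for k in range(spec.n_neurons):
                times = np.concatenate(
                    [p.trains[k].spike_times + t * seg_len for t, p in enumerate(pieces)]
                )
                trains.append(
                    SpikeTrain(
                        spike_times=quantize_times(times),
                        duration=spec.duration,
                        neuron_id=f"n{k}",
                    )
                )
    else:
        pieces = [
            renewal_recording(
                *p, seg_len, derive_seed(seed, t), n_neurons=spec.n_neurons
            )
            for t, p in enumerate(params)
        ]
        trains = []
        for k in range(spec.n_neurons):
            times = np.concatenate(
                [p.trains[k].spike_times + t * seg_len for t, p in enumerate(pieces)]
            )
            trains.append(
                SpikeTrain(
                    spike_times=quantize_times(times),
                    duration=spec.duration,
                    neuron_id=f"n{k}",
                )
            )
    return SpikeTrainSet(
        trains=tuple(trains), condition=condition, metadata={"fixture_seed": seed}
    )


def generate_fixture(spec: FixtureSpec) -> FixtureResult:
    """Generate a paired CON/drug fixture with a scoreable truth record."""
    n_seg = int(spec.duration // spec.seg_len)
    rng = np.random.default_rng(derive_seed(spec.seed, 0xF1))
    params_con = _segment_params((spec.gi_con, spec.gc_con), spec.sigma_true, n_seg, rng)
    params_pha = _segment_params((spec.gi_pha, spec.gc_pha), spec.sigma_true, n_seg, rng)
    con = _build_recording(params_con, spec, "CON", derive_seed(spec.seed, 1))
    pha = _build_recording(params_pha, spec, spec.pha_label, derive_seed(spec.seed, 2))
    truth = {
        "gi_con": spec.gi_con,
        "gc_con": spec.gc_con,
        "gi_pha": spec.gi_pha,
        "gc_pha": spec.gc_pha,
        "pha_label": spec.pha_label,
        "sigma_true": spec.sigma_true,
        "segment_params_con": params_con,
        "segment_params_pha": params_pha,
    }
    return FixtureResult(con=con, pha=pha, truth=truth)
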