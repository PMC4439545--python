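"""Spike-segment feature vectors and non-stationarity metrics.

One segment of a 3-neuron recording is summarised by 68 features::

    FR (1) | LV (1) | ACG1..20 | CCG1..20 | MD1..25 | SD (1)

Per-neuron features (FR, LV, ACG) are averaged over the three neurons;
pairwise features (CCG, MD, SD) over the three unordered pairs, with the
direction-dependent CCG and MD evaluated in both directions and averaged
within each pair.  Features that are undefined on a near-silent segment are
reported as NaN sentinels; callers flag such rows and keep them out of model
fitting.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
from scipy import stats

from .spike_data import Segment, SpikeTrain, restrict

#: Correlogram binning: 20 delay bins of 50 ms spanning 0-1000 ms.
CORR_BIN = 0.05
CORR_MAX_DELAY = 1.0
N_CORR_BINS = 20

#: Minimal-distance histogram bins on [0, 1].
N_MD_BINS = 25

#: Total feature count and block names.
N_FEATURES = 1 + 1 + N_CORR_BINS + N_CORR_BINS + N_MD_BINS + 1

FEATURE_NAMES: tuple[str, ...] = (
    ("FR", "LV")
    + tuple(f"ACG{i}" for i in range(1, N_CORR_BINS + 1))
    + tuple(f"CCG{i}" for i in range(1, N_CORR_BINS + 1))
    + tuple(f"MD{i}" for i in range(1, N_MD_BINS + 1))
    + ("SD",)
)


@dataclass(frozen=True)
class FeatureVector:
    """The 68-component descriptor of one spike segment."""

    fr: float
    lv: float
    acg: np.ndarray
    ccg: np.ndarray
    md: np.ndarray
    sd: float

    def __post_init__(self) -> None:
        for name, arr, n in (
            ("acg", self.acg, N_CORR_BINS),
            ("ccg", self.ccg, N_CORR_BINS),
            ("md", self.md, N_MD_BINS),
        ):
            a = np.asarray(arr, dtype=float)
            if a.shape != (n,):
                raise ValueError(f"{name} must have shape ({n},), got {a.shape}")
            object.__setattr__(self, name, a)

    def to_array(self) -> np.ndarray:
        """Flatten to the canonical 68-vector."""
        return np.concatenate(
            [[self.fr, self.lv], self.acg, self.ccg, self.md, [self.sd]]
        )

    @property
    def valid(self) -> bool:
        """True when no component carries the NaN sentinel."""
        return bool(np.all(np.isfinite(self.to_array())))


def firing_rate(tr: SpikeTrain, seg: Segment | None = None) -> float:
    """Mean firing rate over the segment: spike count per second."""
    if seg is None:
        return tr.n_spikes / tr.duration
    return restrict(tr, seg).size / seg.length


def local_variation(isis: Sequence[float] | np.ndarray) -> float:
    """Local variation of an ordered ISI sequence.

    ``LV = mean over consecutive pairs of 3 (T_{r+1} - T_r)^2 / (T_{r+1} + T_r)^2``;
    0 for perfectly regular trains, ~1 for Poisson, bounded below 3.
    Returns NaN when fewer than 2 ISIs are available.
    """
    t = np.asarray(isis, dtype=float)
    if t.size < 2:
        return float("nan")
    if np.any(t <= 0):
        raise ValueError("ISIs must be positive")
    a, b = t[:-1], t[1:]
    return float(np.mean(3.0 * (b - a) ** 2 / (b + a) ** 2))


def _forward_lag_counts(
    ref: np.ndarray, other: np.ndarray, bin_w: float, max_delay: float
) -> np.ndarray:
    """Counts of ordered pairs with lag (t_ref - t_other) in [k*w, (k+1)*w).

    Includes zero-lag pairs (t_ref == t_other).  Times are snapped to the
    0.1 ms storage lattice and binned in integer ticks, so lags that fall
    exactly on a bin edge are assigned deterministically.
    """
    from .spike_data import TIME_RESOLUTION

    n_bins = int(round(max_delay / bin_w))
    if ref.size == 0 or other.size == 0:
        return np.zeros(n_bins)
    ref_t = np.round(ref / TIME_RESOLUTION).astype(np.int64)
    other_t = np.round(other / TIME_RESOLUTION).astype(np.int64)
    bin_t = int(round(bin_w / TIME_RESOLUTION))
    edges = bin_t * np.arange(n_bins + 1, dtype=np.int64)
    # lag in [e_k, e_{k+1})  <=>  t_other in (t_ref - e_{k+1}, t_ref - e_k]
    pos = np.searchsorted(other_t, ref_t[:, None] - edges[None, :], side="right")
    return (-np.diff(pos, axis=1)).sum(axis=0).astype(float)


def autocorrelogram(
    tr: SpikeTrain,
    seg: Segment | None = None,
    bin_w: float = CORR_BIN,
    max_delay: float = CORR_MAX_DELAY,
    normalize: bool = True,
) -> np.ndarray:
    """Autocorrelogram over 20 delay bins; zero-lag self-pairs excluded.

    Counts ordered spike pairs of the segment with positive lag in each bin;
    with ``normalize`` (default) counts are divided by the segment spike
    count so that segments of different rates are comparable.
    """
    spikes = restrict(tr, seg)
    counts = _forward_lag_counts(spikes, spikes, bin_w, max_delay)
    if spikes.size:
        counts[0] -= spikes.size  # remove the lag-0 self pairs
        if normalize:
            counts = counts / spikes.size
    return counts


def crosscorrelogram(
    tr_i: SpikeTrain,
    tr_j: SpikeTrain,
    seg: Segment | None = None,
    bin_w: float = CORR_BIN,
    max_delay: float = CORR_MAX_DELAY,
    normalize: bool = True,
) -> np.ndarray:
    """Crosscorrelogram over 20 delay bins; zero-lag pairs included.

    Bin ``k`` counts pairs where a spike of ``tr_j`` precedes a spike of
    ``tr_i`` by a lag in [k*50 ms, (k+1)*50 ms); normalized by the spike
    count of the reference train ``tr_i``.
    """
    a = restrict(tr_i, seg)
    b = restrict(tr_j, seg)
    counts = _forward_lag_counts(a, b, bin_w, max_delay)
    if normalize and a.size:
        counts = counts / a.size
    return counts


def minimal_distance_histogram(
    tr_i: SpikeTrain,
    tr_j: SpikeTrain,
    seg: Segment | None = None,
    n_bins: int = N_MD_BINS,
) -> np.ndarray:
    """Histogram of per-spike minimal-distance scores between two trains.

    For each spike l of train i, ``s_l = 1 - exp(-2 * min_m |t_l - t_m| / mean_isi_j)``
    lies in [0, 1); for independent random trains the scores are uniform.
    The histogram uses ``n_bins`` equal bins on [0, 1] and is normalized to
    sum to 1.  Returns NaN sentinels when either train is too sparse for the
    statistic (no spikes in i, fewer than 2 spikes in j).
    """
    a = restrict(tr_i, seg)
    b = restrict(tr_j, seg)
    if a.size == 0 or b.size < 2:
        return np.full(n_bins, np.nan)
    mean_isi = float(np.mean(np.diff(b)))
    if mean_isi <= 0:
        return np.full(n_bins, np.nan)
    pos = np.searchsorted(b, a)
    d_right = np.where(pos < b.size, b[np.minimum(pos, b.size - 1)] - a, np.inf)
    d_left = np.where(pos > 0, a - b[np.maximum(pos - 1, 0)], np.inf)
    dmin = np.minimum(np.abs(d_left), np.abs(d_right))
    s = 1.0 - np.exp(-2.0 * dmin / mean_isi)
    hist, _ = np.histogram(s, bins=n_bins, range=(0.0, 1.0))
    return hist / hist.sum()


def _nearest_distance(x: np.ndarray, train: np.ndarray) -> np.ndarray:
    """Distance from each point of x to the nearest spike of train."""
    pos = np.searchsorted(train, x)
    d_right = np.where(pos < train.size, train[np.minimum(pos, train.size - 1)] - x, np.inf)
    d_left = np.where(pos > 0, x - train[np.maximum(pos - 1, 0)], np.inf)
    return np.minimum(np.abs(d_left), np.abs(d_right))


def spike_distance(
    tr_i: SpikeTrain, tr_j: SpikeTrain, seg: Segment | None = None
) -> float:
    """Adaptive, parameter-free spike-train dissimilarity in [0, 1].

    Time-average of the piecewise-linear instantaneous profile S(t) built
    from the distances between corner spikes of one train and their nearest
    counterparts in the other, weighted by the local inter-spike intervals.
    Exactly 0 for identical trains; symmetric.  Auxiliary spikes at the
    segment edges handle boundary intervals.  Returns NaN when either train
    is empty on the segment.
    """
    if seg is None:
        seg = Segment(0.0, tr_i.duration, index=0)
    a = restrict(tr_i, seg)
    b = restrict(tr_j, seg)
    if a.size == 0 or b.size == 0:
        return float("nan")
    t0, t1 = seg.t_start, seg.t_end
    aa = np.unique(np.concatenate(([t0], a, [t1])))
    bb = np.unique(np.concatenate(([t0], b, [t1])))
    events = np.union1d(aa, bb)
    mids = 0.5 * (events[:-1] + events[1:])
    widths = np.diff(events)

    def _profile_terms(train: np.ndarray, other: np.ndarray):
        idx = np.searchsorted(train, mids, side="right") - 1
        t_p = train[idx]
        t_f = train[idx + 1]
        x_isi = t_f - t_p
        x_p = mids - t_p
        x_f = t_f - mids
        d_p = _nearest_distance(t_p, other)
        d_f = _nearest_distance(t_f, other)
        s = (d_p * x_f + d_f * x_p) / x_isi
        return s, x_isi

    s1, isi1 = _profile_terms(aa, bb)
    s2, isi2 = _profile_terms(bb, aa)
    mean_isi = 0.5 * (isi1 + isi2)
    profile = (s1 * isi2 + s2 * isi1) / (2.0 * mean_isi**2)
    return float(np.sum(profile * widths) / (t1 - t0))


def ks_distance_to_poisson(isis: Sequence[float] | np.ndarray) -> float:
    """KS distance between the empirical ISI CDF and a matched-mean exponential."""
    t = np.asarray(isis, dtype=float)
    if t.size < 2:
        raise ValueError("need at least 2 ISIs")
    scale = float(np.mean(t))
    return float(stats.kstest(t, stats.expon(scale=scale).cdf).statistic)


def firing_rate_sd(tr: SpikeTrain, window: float) -> float:
    """Standard deviation of windowed firing-rate estimates over the recording."""
    if not window > 0:
        raise ValueError("window must be > 0")
    n = int(np.floor(tr.duration / window + 1e-9))
    if n < 1:
        raise ValueError("window exceeds recording duration")
    edges = window * np.arange(n + 1)
    counts = np.diff(np.searchsorted(tr.spike_times, edges, side="left"))
    return float(np.std(counts / window))


def _segment_isis(tr: SpikeTrain, seg: Segment | None) -> np.ndarray:
    return np.diff(restrict(tr, seg))


def compute_feature_vector(
    trains: Sequence[SpikeTrain],
    seg: Segment | None = None,
    normalize_correlograms: bool = True,
) -> FeatureVector:
    """Assemble the 68-component feature vector of one 3-neuron segment.

    Per-neuron blocks are averaged over the three neurons, pairwise blocks
    over the three unordered pairs (both directions averaged for CCG and MD).
    Any undefined sub-feature propagates as a NaN sentinel.
    """
    if len(trains) != 3:
        raise ValueError(f"expected exactly 3 trains, got {len(trains)}")
    fr = float(np.mean([firing_rate(tr, seg) for tr in trains]))
    lv = float(np.mean([local_variation(_segment_isis(tr, seg)) for tr in trains]))
    acg = np.mean(
        [autocorrelogram(tr, seg, normalize=normalize_correlograms) for tr in trains],
        axis=0,
    )
    pairs = list(combinations(range(3), 2))
    ccg = np.mean(
        [
            0.5
            * (
                crosscorrelogram(trains[i], trains[j], seg, normalize=normalize_correlograms)
                + crosscorrelogram(trains[j], trains[i], seg, normalize=normalize_correlograms)
            )
            for i, j in pairs
        ],
        axis=0,
    )
    md = np.mean(
        [
            0.5
            * (
                minimal_distance_histogram(trains[i], trains[j], seg)
                + minimal_distance_histogram(trains[j], trains[i], seg)
            )
            for i, j in pairs
        ],
        axis=0,
    )
    sd = float(np.mean([spike_distance(trains[i], trains[j], seg) for i, j in pairs]))
    return FeatureVector(fr=fr, lv=lv, acg=acg, ccg=ccg, md=md, sd=sd)
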