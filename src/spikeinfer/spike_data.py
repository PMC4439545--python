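"""Spike-train data types, readers/writers, segmentation, and binning.

File format: CSV with commented header lines declaring recording duration,
condition and the neuron ids (so that silent neurons survive a round trip),
followed by ``neuron_id,time_s`` rows::

    # duration_s=500.0000
    # condition=CON
    # neurons=n0,n1,n2
    neuron_id,time_s
    n0,0.1234

Spike times are stored at a fixed resolution of 0.1 ms; the read/write round
trip is the identity for any set whose times lie on that lattice.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from ._utils import check_positive

#: Storage/comparison time resolution in seconds (0.1 ms).
TIME_RESOLUTION = 1e-4

#: Decimal places implied by TIME_RESOLUTION, used for text formatting.
_TIME_DECIMALS = 4

#: Allowed condition labels.
CONDITIONS = ("CON", "PIX", "CBX", "SIM")


def quantize_times(times: np.ndarray) -> np.ndarray:
    """Snap spike times to the storage lattice and drop duplicates."""
    q = np.round(np.asarray(times, dtype=float), _TIME_DECIMALS)
    return np.unique(q)


@dataclass(frozen=True)
class SpikeTrain:
    """Ordered spike times of one neuron over a recording of fixed duration."""

    spike_times: np.ndarray
    duration: float
    neuron_id: str = ""

    def __post_init__(self) -> None:
        times = np.asarray(self.spike_times, dtype=float)
        object.__setattr__(self, "spike_times", times)
        check_positive(self.duration, "duration")
        if times.ndim != 1:
            raise ValueError("spike_times must be one-dimensional")
        if times.size:
            if times.min() < 0 or times.max() > self.duration:
                raise ValueError(
                    f"spike times of neuron {self.neuron_id!r} fall outside "
                    f"[0, {self.duration}]"
                )
            if np.any(np.diff(times) <= 0):
                raise ValueError(
                    f"spike times of neuron {self.neuron_id!r} are not "
                    "strictly increasing"
                )

    @property
    def n_spikes(self) -> int:
        return int(self.spike_times.size)

    def isis(self) -> np.ndarray:
        """Inter-spike intervals, in seconds."""
        return np.diff(self.spike_times)

    def in_window(self, t0: float, t1: float) -> np.ndarray:
        """Spike times falling in the half-open window [t0, t1)."""
        lo, hi = np.searchsorted(self.spike_times, [t0, t1], side="left")
        return self.spike_times[lo:hi]


@dataclass(frozen=True)
class SpikeTrainSet:
    """A multi-neuron recording: trains sharing one duration and condition."""

    trains: tuple[SpikeTrain, ...]
    condition: str = "SIM"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "trains", tuple(self.trains))
        if not self.trains:
            raise ValueError("SpikeTrainSet needs at least one train")
        durations = {tr.duration for tr in self.trains}
        if len(durations) != 1:
            raise ValueError(f"trains have differing durations: {durations}")
        if self.condition not in CONDITIONS:
            raise ValueError(
                f"condition must be one of {CONDITIONS}, got {self.condition!r}"
            )

    @property
    def duration(self) -> float:
        return self.trains[0].duration

    @property
    def n_neurons(self) -> int:
        return len(self.trains)

    @property
    def n_spikes(self) -> int:
        return sum(tr.n_spikes for tr in self.trains)


@dataclass(frozen=True)
class Segment:
    """One contiguous time segment [t_start, t_end) of a recording."""

    t_start: float
    t_end: float
    index: int = 0

    def __post_init__(self) -> None:
        if not self.t_end > self.t_start:
            raise ValueError("segment must have t_end > t_start")

    @property
    def length(self) -> float:
        return self.t_end - self.t_start


@dataclass(frozen=True)
class BinnedSpikes:
    """Integer spike counts on a regular binning of a time window."""

    counts: np.ndarray
    bin_width: float
    t_start: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "counts", np.asarray(self.counts, dtype=int))
        check_positive(self.bin_width, "bin_width")

    @property
    def n_bins(self) -> int:
        return int(self.counts.size)


def segment_recording(s: SpikeTrainSet, seg_len: float = 50.0) -> list[Segment]:
    """Divide a recording into contiguous, non-overlapping segments.

    A duration that is not an integer multiple of ``seg_len`` is tail
    truncated with a warning.
    """
    check_positive(seg_len, "seg_len")
    if seg_len > s.duration:
        raise ValueError(
            f"seg_len {seg_len} exceeds recording duration {s.duration}"
        )
    ratio = s.duration / seg_len
    n = int(np.floor(ratio + 1e-9))
    leftover = s.duration - n * seg_len
    if leftover > 1e-9:
        warnings.warn(
            f"duration {s.duration} is not a multiple of seg_len {seg_len}; "
            f"truncating trailing {leftover:g} s",
            stacklevel=2,
        )
    return [Segment(k * seg_len, (k + 1) * seg_len, index=k) for k in range(n)]


def bin_spikes(
    tr: SpikeTrain, window: tuple[float, float], bin_width: float
) -> BinnedSpikes:
    """Count spikes on half-open bins [t0 + k*w, t0 + (k+1)*w) covering window."""
    t0, t1 = window
    check_positive(bin_width, "bin_width")
    if not t1 > t0:
        raise ValueError("window must satisfy t1 > t0")
    n_bins = int(np.ceil((t1 - t0) / bin_width - 1e-12))
    edges = t0 + bin_width * np.arange(n_bins + 1)
    spikes = tr.in_window(t0, t1)
    counts = np.diff(np.searchsorted(spikes, edges, side="left"))
    return BinnedSpikes(counts=counts, bin_width=bin_width, t_start=t0)


def write_spike_trains(s: SpikeTrainSet, path: str | Path) -> None:
    """Write a recording to the package spike-CSV format (deterministic)."""
    path = Path(path)
    lines = [
        f"# duration_s={s.duration:.{_TIME_DECIMALS}f}",
        f"# condition={s.condition}",
        "# neurons=" + ",".join(tr.neuron_id for tr in s.trains),
    ]
    for key, val in sorted(s.metadata.items()):
        lines.append(f"# meta:{key}={val}")
    lines.append("neuron_id,time_s")
    for tr in s.trains:
        for t in tr.spike_times:
            lines.append(f"{tr.neuron_id},{t:.{_TIME_DECIMALS}f}")
    path.write_text("\n".join(lines) + "\n")


def read_spike_trains(path: str | Path) -> SpikeTrainSet:
    """Read a recording written by :func:`write_spike_trains`.

    Raises a ``ValueError`` naming the offending line for malformed rows and
    for spike times exceeding the declared duration.
    """
    path = Path(path)
    duration: float | None = None
    condition = "SIM"
    neuron_order: list[str] = []
    metadata: dict = {}
    spikes: dict[str, list[float]] = {}

    with path.open(newline="") as fh:
        header_seen = False
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if "=" not in body:
                    raise ValueError(f"{path}:{lineno}: malformed header line {line!r}")
                key, _, val = body.partition("=")
                key = key.strip()
                if key == "duration_s":
                    duration = float(val)
                elif key == "condition":
                    condition = val.strip()
                elif key == "neurons":
                    neuron_order = [v for v in val.split(",") if v]
                    for nid in neuron_order:
                        spikes.setdefault(nid, [])
                elif key.startswith("meta:"):
                    metadata[key[5:]] = val
                continue
            if not header_seen and line.lower().startswith("neuron_id"):
                header_seen = True
                continue
            parts = next(csv.reader([line]))
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: malformed row {line!r}")
            nid, tstr = parts
            try:
                t = float(tstr)
            except ValueError as exc:
                raise ValueError(
                    f"{path}:{lineno}: unparsable spike time {tstr!r}"
                ) from exc
            if duration is not None and t > duration:
                raise ValueError(
                    f"{path}:{lineno}: spike time {t} exceeds duration {duration}"
                )
            if nid not in spikes:
                neuron_order.append(nid)
                spikes[nid] = []
            spikes[nid].append(t)

    if duration is None:
        raise ValueError(f"{path}: missing '# duration_s=' header")
    trains = tuple(
        SpikeTrain(
            spike_times=np.sort(np.asarray(spikes[nid], dtype=float)),
            duration=duration,
            neuron_id=nid,
        )
        for nid in neuron_order
    )
    return SpikeTrainSet(trains=trains, condition=condition, metadata=metadata)


def restrict(tr: SpikeTrain, seg: Segment | None) -> np.ndarray:
    """Spike times of ``tr`` inside ``seg`` (whole recording if seg is None)."""
    if seg is None:
        return tr.spike_times
    return tr.in_window(seg.t_start, seg.t_end)
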