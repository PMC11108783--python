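"""Spike-cluster seizure segmentation.

Two rules govern segmentation, applied in this order:

1. *Inclusion*: a spike cluster whose consecutive interspike intervals are
   all below ``max_isi`` (default 1 s) is a seizure candidate.
2. *Termination*: a seizure is not considered ended until the spiking rate
   falls below one spike per ``end_gap`` (default 2 s); trailing spikes
   whose gaps stay below ``end_gap`` — even when at or above ``max_isi`` —
   extend the seizure, and the seizure ends at the last spike followed by a
   gap of at least ``end_gap``.

The two rules can disagree for trailing ISIs in ``[max_isi, end_gap)``;
the termination rule wins there by design.  Boundary conventions, stated
once and used everywhere: gap comparisons use ``<`` for inclusion and
``>=`` for termination; ``min_spikes`` applies to the core cluster (the
run of sub-``max_isi`` ISIs), and trailing spikes absorbed by the
termination rule count toward ``n_spikes`` but cannot seed a cluster.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class ClusterParams:
    """Segmentation parameters (seconds / counts)."""

    max_isi: float = 1.0
    min_spikes: int = 3
    end_gap: float = 2.0
    intercluster_interval: float | None = None  # defaults to end_gap

    def __post_init__(self) -> None:
        if self.max_isi <= 0:
            raise ValueError("max_isi must be > 0")
        if self.end_gap < self.max_isi:
            raise ValueError("end_gap must be >= max_isi")
        if self.min_spikes < 2:
            raise ValueError("min_spikes must be >= 2")
        if self.intercluster_interval is None:
            self.intercluster_interval = self.end_gap

    @property
    def ici(self) -> float:
        return float(self.intercluster_interval)


@dataclass
class SeizureEvent:
    """A segmented seizure: onset at the first spike, end per the 2 s rule."""

    onset: float
    end: float
    spike_times: np.ndarray
    trigger_time: float | None = None
    duration_from_trigger: float | None = None
    flags: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.spike_times = np.asarray(self.spike_times, float)

    @property
    def n_spikes(self) -> int:
        return int(self.spike_times.size)


def cluster_spikes(spike_times, params: ClusterParams | None = None) -> list[SeizureEvent]:
    """Greedy single-pass segmentation of a sorted spike train.

    A cluster grows while the next ISI is below ``max_isi`` (core), then
    extends through trailing spikes while gaps stay below ``end_gap``
    (termination rule).  Cores smaller than ``min_spikes`` are discarded
    (their spikes are interictal).  Events closer than
    ``intercluster_interval`` are merged.  Input must be sorted and unique.
    """
    if params is None:
        params = ClusterParams()
    t = np.asarray(spike_times, float)
    if t.size and (np.any(np.diff(t) < 0) or np.unique(t).size != t.size):
        raise ValueError("spike times must be sorted and unique")

    events: list[SeizureEvent] = []
    n = t.size
    i = 0
    while i < n:
        if i + 1 < n and t[i + 1] - t[i] < params.max_isi:
            j = i
            while j + 1 < n and t[j + 1] - t[j] < params.max_isi:
                j += 1
            if j - i + 1 >= params.min_spikes:
                # termination rule: absorb trailing spikes (including further
                # clusters) while gaps stay below end_gap
                k = j
                while k + 1 < n and t[k + 1] - t[k] < params.end_gap:
                    k += 1
                events.append(SeizureEvent(t[i], t[k], t[i : k + 1]))
                i = k + 1
            else:
                # an interictal pair, not a seizure; it must not swallow a
                # cluster that may start within end_gap
                i = j + 1
        else:
            i += 1

    if params.ici > params.end_gap and len(events) > 1:
        merged = [events[0]]
        for ev in events[1:]:
            prev = merged[-1]
            if ev.onset - prev.end < params.ici:
                merged[-1] = SeizureEvent(
                    prev.onset, ev.end,
                    np.concatenate([prev.spike_times, ev.spike_times]),
                )
            else:
                merged.append(ev)
        events = merged
    return events


def seizure_end(cluster: SeizureEvent, params: ClusterParams | None = None) -> float:
    """End time of a cluster under the rate-based termination rule.

    The end is the time of the last spike that is followed by a gap of at
    least ``end_gap`` within the cluster's own spikes — i.e. the cluster's
    final spike when its internal gaps all stay below ``end_gap`` (the case
    ``cluster_spikes`` produces by construction).
    """
    if params is None:
        params = ClusterParams()
    t = cluster.spike_times
    if t.size == 0:
        raise ValueError("empty cluster")
    gaps = np.diff(t)
    big = np.flatnonzero(gaps >= params.end_gap)
    return float(t[big[0]]) if big.size else float(t[-1])


def duration_from_trigger(seizure: SeizureEvent, trigger_time: float) -> float:
    """Seizure duration measured from the closed-loop trigger to the end.

    The trigger must fall within ``[onset, end]``; the trigger and the
    resulting duration are attached to the event.
    """
    if not (seizure.onset <= trigger_time <= seizure.end):
        raise ValueError(
            f"trigger {trigger_time:.3f} s outside seizure "
            f"[{seizure.onset:.3f}, {seizure.end:.3f}]"
        )
    seizure.trigger_time = float(trigger_time)
    seizure.duration_from_trigger = float(seizure.end - trigger_time)
    return seizure.duration_from_trigger


def segment(spike_times, params: ClusterParams | None = None) -> list[SeizureEvent]:
    """Alias for :func:`cluster_spikes` (the full segmentation pass)."""
    return cluster_spikes(spike_times, params)


def match_seizures_to_truth(
    events: list[SeizureEvent],
    truth_intervals: list[tuple[float, float]],
    tolerance: float = 2.0,
) -> list[int | None]:
    """For each segmented event, index of the overlapping truth interval.

    An event matches the truth seizure whose padded interval contains its
    onset; unmatched events map to None.
    """
    out: list[int | None] = []
    for ev in events:
        hit = None
        for k, (a, b) in enumerate(truth_intervals):
            if a - tolerance <= ev.onset < b + tolerance:
                hit = k
                break
        out.append(hit)
    return out
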