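"""Independent brute-force oracles used to validate the implementation.

These deliberately use different algorithms (episode splitting + scanning,
Python eval, naive per-event loops) from the package code they check.
"""
from __future__ import annotations

import re

import numpy as np


def brute_force_segment(times, max_isi=1.0, min_spikes=3, end_gap=2.0):
    """O(n^2)-style reference segmenter.

    Split the train into episodes at gaps >= end_gap (the termination
    rule); within an episode, a seizure starts at the first spike that
    begins a run of at least ``min_spikes`` spikes with consecutive ISIs
    below ``max_isi`` and runs to the episode's last spike.  Returns
    (onset, end, spikes) tuples.
    """
    t = np.asarray(times, float)
    if t.size == 0:
        return []
    episodes = []
    start = 0
    for k in range(t.size - 1):
        if t[k + 1] - t[k] >= end_gap:
            episodes.append(t[start : k + 1])
            start = k + 1
    episodes.append(t[start:])

    events = []
    for ep in episodes:
        onset_idx = None
        for i in range(len(ep) - (min_spikes - 1)):
            if all(ep[j + 1] - ep[j] < max_isi for j in range(i, i + min_spikes - 1)):
                onset_idx = i
                break
        if onset_idx is not None:
            events.append((ep[onset_idx], ep[-1], ep[onset_idx:]))
    return events


def eval_rule_by_eval(expression: str, flags: dict) -> bool:
    """Oracle Boolean evaluation: lower AND/OR/NOT and use Python eval."""
    py = re.sub(
        r"\b(AND|OR|NOT)\b", lambda m: m.group(1).lower(), expression,
        flags=re.IGNORECASE,
    )
    return bool(eval(py, {"__builtins__": {}}, dict(flags)))  # noqa: S307


def naive_peri_event(values, frame_times, event_times, bins):
    """Naive per-event nearest-frame averaging for one cell."""
    acc = np.zeros(len(bins))
    cnt = np.zeros(len(bins))
    dt = np.median(np.diff(frame_times))
    for t in event_times:
        for bi, b in enumerate(bins):
            target = t + b
            k = int(np.argmin(np.abs(frame_times - target)))
            if abs(frame_times[k] - target) <= dt / 2 + 1e-12:
                acc[bi] += values[k]
                cnt[bi] += 1
    with np.errstate(invalid="ignore"):
        return np.where(cnt > 0, acc / np.maximum(cnt, 1), np.nan)
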