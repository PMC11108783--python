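"""Shared primitives: the Recording container and robust statistics.

Time convention used throughout the package: seconds from recording start,
intervals half-open ``[start, end)``, sample indices 0-based, so sample *i*
of a channel lives at ``t0 + i / sampling_rate``.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: MAD -> SD consistency constant for a Gaussian.
MAD_SCALE = 1.4826


def robust_sd(x: np.ndarray) -> float:
    """Robust spread estimate: 1.4826 x median absolute deviation.

    Preferred over the plain standard deviation for thresholding because
    epileptiform events are large and sparse: they would inflate an SD-based
    threshold on exactly the records that contain the most events.
    """
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        return 0.0
    return MAD_SCALE * float(np.median(np.abs(x - np.median(x))))


@dataclass
class Recording:
    """Uniformly sampled signal(s): one row per channel.

    Parameters
    ----------
    samples : ndarray, shape (n_channels, n_samples)
        Signal in arbitrary (but consistent) units.
    sampling_rate : float
        Samples per second, > 0.
    channel_labels : list of str
        One label per channel.
    t0 : float
        Time of sample 0 in seconds (default 0).
    """

    samples: np.ndarray
    sampling_rate: float
    channel_labels: list[str] = field(default_factory=list)
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=np.float64))
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be > 0")
        if not self.channel_labels:
            self.channel_labels = [f"ch{i}" for i in range(self.samples.shape[0])]
        if len(self.channel_labels) != self.samples.shape[0]:
            raise ValueError("one label per channel required")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate

    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.sampling_rate

    def channel(self, key: int | str) -> np.ndarray:
        if isinstance(key, str):
            key = self.channel_labels.index(key)
        return self.samples[key]

    def copy(self) -> "Recording":
        return Recording(
            self.samples.copy(),
            self.sampling_rate,
            list(self.channel_labels),
            self.t0,
        )

    def time_to_index(self, t: float) -> int:
        return int(round((t - self.t0) * self.sampling_rate))
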