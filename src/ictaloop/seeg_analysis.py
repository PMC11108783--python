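"""Human sEEG stage: per-seizure onset-pattern classification and tallies.

Two mesial temporal recording sites are compared per seizure: the fasciola
cinereum (FC) in the posterior-medial hippocampal tail, and the amygdala /
anterior hippocampus (AH).  When clear ictal onsets in the two regions are
separated by 50 ms or more, a differential onset is described and the
seizure is labeled as spreading from the earlier region; separations under
50 ms are simultaneous.  Exactly 50 ms counts as differential (the rule is
"50 ms or more").  Onset times are inputs — expert-marked on clinical
recordings or generator truth on synthetic cases; automated human
ictal-onset marking is out of scope.  An 80-250 Hz band marker flags
windows with elevated high-frequency activity.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

from .core import Recording, robust_sd
from .spikedet import design_bandpass

DIFFERENTIAL_ONSET_THRESHOLD = 0.050  # seconds

PATTERNS = (
    "FC_independent",
    "simultaneous_FC_AH",
    "spread_AH_to_FC",
    "spread_FC_to_AH",
    "AH_without_FC",
    "FC_without_AH",  # accepted alias of FC_independent on input
    "neither",
)


@dataclass
class ChannelOnset:
    """Onset record for one channel in one seizure (None = not involved)."""

    seizure: int
    channel: str
    region: str
    onset_time: float | None = None

    @property
    def involved(self) -> bool:
        return self.onset_time is not None and not (
            isinstance(self.onset_time, float) and math.isnan(self.onset_time)
        )


@dataclass
class InvolvementTally:
    """Seizure-involvement count for one region."""

    n_involved: int
    n_total: int

    @property
    def fraction(self) -> float:
        return 100.0 * self.n_involved / self.n_total

    @property
    def percent(self) -> int:
        """Nearest-integer percent (rounding happens only at reporting)."""
        return int(round(self.fraction))


def classify_onset(
    fc: ChannelOnset,
    ah: ChannelOnset,
    threshold: float = DIFFERENTIAL_ONSET_THRESHOLD,
) -> str:
    """Label one seizure's FC/AH onset pattern under the 50 ms rule.

    Both absent -> ``neither``; FC only -> ``FC_independent``; AH only ->
    ``AH_without_FC``; both present -> ``simultaneous_FC_AH`` when
    |dt| < threshold, else spread from the earlier region (|dt| exactly at
    the threshold is differential).
    """
    if fc.seizure != ah.seizure:
        raise ValueError("onset records refer to different seizures")
    if not fc.involved and not ah.involved:
        return "neither"
    if fc.involved and not ah.involved:
        return "FC_independent"
    if ah.involved and not fc.involved:
        return "AH_without_FC"
    dt = fc.onset_time - ah.onset_time  # > 0: AH leads
    if abs(dt) < threshold:
        return "simultaneous_FC_AH"
    return "spread_AH_to_FC" if dt > 0 else "spread_FC_to_AH"


def classify_case(
    onset_table: pd.DataFrame,
    fc_region: str = "FC",
    ah_region: str = "AH",
    threshold: float = DIFFERENTIAL_ONSET_THRESHOLD,
) -> pd.Series:
    """Per-seizure onset patterns from a (seizure, region, onset_time) table.

    When a region has several channels, its onset is the earliest involved
    channel's onset.  Returns a Series indexed by seizure id.
    """
    out = {}
    for s, sub in onset_table.groupby("seizure"):
        def region_onset(region: str) -> float | None:
            vals = sub.loc[sub["region"] == region, "onset_time"].dropna()
            return float(vals.min()) if not vals.empty else None

        fc = ChannelOnset(int(s), fc_region, fc_region, region_onset(fc_region))
        ah = ChannelOnset(int(s), ah_region, ah_region, region_onset(ah_region))
        out[int(s)] = classify_onset(fc, ah, threshold)
    return pd.Series(out, name="pattern").sort_index()


def involvement_fraction(onset_table: pd.DataFrame, region: str) -> InvolvementTally:
    """Fraction of seizures with an onset recorded for a region."""
    sub = onset_table[onset_table["region"] == region]
    if sub.empty:
        raise ValueError(f"no channels for region {region!r}")
    per_seizure = sub.groupby("seizure")["onset_time"].apply(
        lambda v: v.notna().any()
    )
    n_total = int(per_seizure.size)
    if n_total < 1:
        raise ValueError("need at least one seizure")
    return InvolvementTally(int(per_seizure.sum()), n_total)


def pattern_tally(patterns: pd.Series) -> pd.Series:
    """Counts per onset pattern; sums to the number of seizures."""
    return patterns.value_counts().reindex(
        [p for p in PATTERNS if p != "FC_without_AH"], fill_value=0
    )


def hfo_band_marker(
    recording: Recording,
    channel: int | str = 0,
    band: tuple[float, float] = (80.0, 250.0),
    window: float = 0.2,
    threshold: float = 5.0,
) -> pd.DataFrame:
    """Flag windows with elevated 80-250 Hz activity.

    Band-passes the channel, takes the magnitude of the analytic signal
    (envelope), and flags non-overlapping windows whose mean envelope
    exceeds ``threshold`` x the envelope's robust SD.  Requires the
    sampling rate to exceed twice the band's upper edge (satisfied by the
    1,000 Hz clinical rate).
    """
    fs = recording.sampling_rate
    if fs <= 2 * band[1]:
        raise ValueError("sampling rate must exceed twice the band's upper edge")
    x = recording.channel(channel)
    sos = design_bandpass(band, 4, fs)
    bb = sps.sosfiltfilt(sos, x)
    env = np.abs(sps.hilbert(bb))
    w = max(int(round(window * fs)), 1)
    n_win = x.size // w
    means = env[: n_win * w].reshape(n_win, w).mean(axis=1)
    level = threshold * robust_sd(env)
    return pd.DataFrame(
        {
            "start": np.arange(n_win) * w / fs,
            "end": (np.arange(n_win) + 1) * w / fs,
            "mean_envelope": means,
            "flagged": means > level,
        }
    )


def seizure_frequency_reduction(rate_before: float, rate_after: float) -> float:
    """Percent reduction in seizure frequency, 100 x (1 - after/before)."""
    if rate_before <= 0:
        raise ValueError("rate_before must be > 0")
    return 100.0 * (1.0 - rate_after / rate_before)


def onsets_from_table(onset_table: pd.DataFrame) -> list[ChannelOnset]:
    """Convert a tidy onset table to ChannelOnset records."""
    return [
        ChannelOnset(
            int(r.seizure), str(r.channel), str(r.region),
            None if pd.isna(r.onset_time) else float(r.onset_time),
        )
        for r in onset_table.itertuples()
    ]
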