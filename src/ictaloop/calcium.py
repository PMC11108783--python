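"""Calcium-trace analysis: ROI extraction, dF/F, peri-event alignment.

Implements the imaging-side analysis chain: mask-averaged trace extraction
from a movie, rolling-percentile dF/F, per-cell max-normalization,
event-aligned averaging on a common relative-time grid (the peri-event
heat-map object, with the event set as time 0), and the activity-spiking
correlation with its across-cell summary.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class RoiMask:
    """A labeled region of interest: a set of (row, col) pixels."""

    label: int
    rows: np.ndarray
    cols: np.ndarray

    def __post_init__(self) -> None:
        self.rows = np.asarray(self.rows, int)
        self.cols = np.asarray(self.cols, int)
        if self.rows.size == 0:
            raise ValueError("empty ROI mask")
        if self.rows.size != self.cols.size:
            raise ValueError("rows/cols length mismatch")


def masks_from_label_image(label_image: np.ndarray) -> list[RoiMask]:
    """ROI masks from a labeled image (0 = background)."""
    labels = np.unique(label_image)
    labels = labels[labels > 0]
    out = []
    for lab in labels:
        r, c = np.nonzero(label_image == lab)
        out.append(RoiMask(int(lab), r, c))
    return out


def extract_traces(movie: np.ndarray, masks: list[RoiMask]) -> np.ndarray:
    """Mask-averaged raw traces: mean of the included pixels per frame.

    ``movie`` has shape (frames, rows, cols); the result has shape
    (n_masks, frames).  Extraction is linear in the movie.
    """
    movie = np.asarray(movie)
    if movie.ndim != 3:
        raise ValueError("movie must be frames x rows x cols")
    n_frames, n_rows, n_cols = movie.shape
    traces = np.empty((len(masks), n_frames))
    for i, m in enumerate(masks):
        if m.rows.min() < 0 or m.rows.max() >= n_rows or m.cols.max() >= n_cols:
            raise ValueError(f"mask {m.label} exceeds frame bounds")
        traces[i] = movie[:, m.rows, m.cols].mean(axis=1)
    return traces


@dataclass
class DffTrace:
    """dF/F trace for one cell, with its baseline."""

    values: np.ndarray
    frame_times: np.ndarray
    baseline: np.ndarray
    cell: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        self.frame_times = np.asarray(self.frame_times, float)
        if np.any(np.diff(self.frame_times) <= 0):
            raise ValueError("frame_times must be strictly increasing")


def compute_dff(
    raw: np.ndarray,
    frame_times: np.ndarray,
    baseline_window: float = 30.0,
    baseline_percentile: float = 8.0,
    cell: int = 0,
) -> DffTrace:
    """dF/F with a rolling-percentile baseline.

    The baseline F0 is the ``baseline_percentile``-th percentile of the raw
    trace over a centered ``baseline_window`` (seconds); windows shrink at
    the edges.  dF/F = (F - F0) / F0.  Nonpositive baselines are rejected:
    the raw trace must carry a positive offset (the synthetic generator
    uses a resting fluorescence of 1).
    """
    raw = np.asarray(raw, float)
    frame_times = np.asarray(frame_times, float)
    if raw.size != frame_times.size:
        raise ValueError("trace/frame_times length mismatch")
    dt = float(np.median(np.diff(frame_times))) if raw.size > 1 else 1.0
    win = max(int(round(baseline_window / dt)), 1)
    if raw.size < win:
        win = raw.size
    f0 = (
        pd.Series(raw)
        .rolling(window=win, center=True, min_periods=1)
        .quantile(baseline_percentile / 100.0)
        .to_numpy()
    )
    if np.any(f0 <= 0):
        raise ValueError(
            "nonpositive baseline; dF/F requires a positive resting fluorescence"
        )
    return DffTrace((raw - f0) / f0, frame_times, f0, cell)


def compute_dff_matrix(raw: np.ndarray, frame_times: np.ndarray,
                       **kwargs) -> list[DffTrace]:
    return [
        compute_dff(raw[i], frame_times, cell=i, **kwargs)
        for i in range(raw.shape[0])
    ]


def normalize_to_max(dff: DffTrace) -> DffTrace | None:
    """Divide by the cell's maximum so the new maximum is exactly 1.

    Idempotent; cells with a nonpositive maximum are dropped (None) with a
    warning.  Order of time points is preserved (monotone transform).
    """
    m = float(np.max(dff.values))
    if m <= 0:
        logger.warning("cell %d has nonpositive maximum; dropped", dff.cell)
        return None
    return DffTrace(dff.values / m, dff.frame_times, dff.baseline, dff.cell)


@dataclass
class PeriEventMatrix:
    """Event-aligned, event-averaged (max-normalized) dF/F per cell.

    ``values`` is cells x time-bins; ``bin_centers`` are seconds relative
    to the event (0 = event); ``n_events`` counts usable events per bin
    (events clipped by the recording edge contribute only to in-range bins).
    """

    values: np.ndarray
    bin_centers: np.ndarray
    event_kind: str = "event"
    n_events: np.ndarray = field(default_factory=lambda: np.array([]))
    cell_ids: np.ndarray = field(default_factory=lambda: np.array([]))

    def column_mean(self) -> np.ndarray:
        return np.nanmean(self.values, axis=0)

    def sort_rows_by_peak(self) -> "PeriEventMatrix":
        order = np.argsort(np.nanargmax(self.values, axis=1))
        return PeriEventMatrix(
            self.values[order], self.bin_centers, self.event_kind,
            self.n_events, self.cell_ids[order] if self.cell_ids.size else self.cell_ids,
        )


def align_to_events(
    dffs: list[DffTrace],
    event_times,
    window: tuple[float, float] = (5.0, 5.0),
    bin_width: float | None = None,
    event_kind: str = "event",
    normalize: bool = True,
) -> PeriEventMatrix:
    """Average (max-normalized) dF/F across events on a relative-time grid.

    ``window`` is (pre, post) in seconds; bins are centered on multiples of
    ``bin_width`` (default: one frame period) from -pre to +post, with the
    event at bin 0.  Each bin takes the nearest frame to its center
    (bit-reproducible assignment); events whose window exceeds the
    recording are clipped and the per-bin event count tracked.  Rejects
    when no event is usable.
    """
    event_times = np.atleast_1d(np.asarray(event_times, float))
    if not dffs:
        raise ValueError("no traces supplied")
    ft = dffs[0].frame_times
    dt = float(np.median(np.diff(ft)))
    if bin_width is None:
        bin_width = dt
    pre, post = window
    bins = np.arange(-round(pre / bin_width), round(post / bin_width) + 1) * bin_width

    usable = [t for t in event_times if ft[0] - pre <= t <= ft[-1] + post]
    if not usable:
        raise ValueError("no usable events within the recording")

    mats = []
    for dff in dffs:
        v = dff.values
        if normalize:
            norm = normalize_to_max(dff)
            if norm is None:
                continue
            v = norm.values
        acc = np.zeros(bins.size)
        cnt = np.zeros(bins.size)
        for t in usable:
            targets = t + bins
            idx = np.round((targets - ft[0]) / dt).astype(int)
            ok = (idx >= 0) & (idx < ft.size)
            acc[ok] += v[idx[ok]]
            cnt[ok] += 1
        with np.errstate(invalid="ignore"):
            mats.append(np.where(cnt > 0, acc / np.maximum(cnt, 1), np.nan))
    values = np.vstack(mats)
    cnt_all = np.zeros(bins.size)
    for t in usable:
        idx = np.round((t + bins - ft[0]) / dt).astype(int)
        cnt_all += ((idx >= 0) & (idx < ft.size)).astype(float)
    return PeriEventMatrix(
        values, bins, event_kind, cnt_all,
        np.asarray([d.cell for d in dffs]),
    )


def binned_spike_rate(spike_times, frame_times, rate_bin: float | None = None) -> np.ndarray:
    """Spike rate binned at ``rate_bin`` and interpolated to frame times."""
    spike_times = np.asarray(spike_times, float)
    frame_times = np.asarray(frame_times, float)
    dt = float(np.median(np.diff(frame_times)))
    if rate_bin is None:
        rate_bin = dt
    edges = np.arange(frame_times[0], frame_times[-1] + rate_bin, rate_bin)
    counts, _ = np.histogram(spike_times, edges)
    centers = edges[:-1] + rate_bin / 2.0
    rate = counts / rate_bin
    return np.interp(frame_times, centers, rate)


def activity_spiking_correlation(
    dffs: list[DffTrace],
    spike_times,
    rate_bin: float | None = None,
) -> dict:
    """Per-cell product-moment correlation of dF/F with the spike rate.

    The spike rate is binned (default: one frame period) and linearly
    interpolated to frame times; cells with zero variance on either side
    are excluded with a log message.  Returns per-cell r plus the
    across-cell mean and s.e.m.
    """
    if not dffs:
        raise ValueError("no traces supplied")
    rate = binned_spike_rate(spike_times, dffs[0].frame_times, rate_bin)
    rs = []
    excluded = []
    for dff in dffs:
        v = dff.values
        if np.std(v) == 0 or np.std(rate) == 0:
            excluded.append(dff.cell)
            continue
        rs.append(float(np.corrcoef(v, rate)[0, 1]))
    if excluded:
        logger.info("excluded zero-variance cells: %s", excluded)
    rs = np.asarray(rs)
    n = rs.size
    return {
        "r": rs,
        "mean": float(rs.mean()) if n else np.nan,
        "sem": float(rs.std(ddof=1) / np.sqrt(n)) if n > 1 else np.nan,
        "n_cells": n,
        "excluded": excluded,
    }
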