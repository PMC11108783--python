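"""Synthetic session generator with known ground truth.

Emulates the experimental substrates of the closed-loop study:

* mouse hippocampal LFP at 500 Hz containing background noise, isolated
  interictal spikes, and seizures realized as clusters of spikes whose
  interspike intervals are below 1 s by construction;
* a light-on truncation effect on seizure duration (the optogenetic
  intervention model);
* calcium-indicator traces at 15.49 frames per second coupled to the LFP
  events, optionally rendered as a movie with ROI masks;
* multi-channel 1,000 Hz sEEG cases with per-channel ictal onset latencies.

Every generator is deterministic given ``GenConfig.seed``.  Sub-generators
draw from independent streams spawned from the single top-level seed
(`numpy.random.SeedSequence.spawn` with a fixed stream table), so e.g.
adding calcium cells never perturbs the LFP noise.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core import Recording

logger = logging.getLogger(__name__)

# Fixed spawn order of the independent random streams.
_STREAMS = {
    "lfp_noise": 0,
    "interictal": 1,
    "seizures": 2,
    "calcium": 3,
    "movie": 4,
    "seeg": 5,
}


def stream_rng(seed: int, stream: str) -> np.random.Generator:
    """Independent random stream derived from the top-level seed."""
    children = np.random.SeedSequence(seed).spawn(len(_STREAMS))
    return np.random.default_rng(children[_STREAMS[stream]])


@dataclass
class CalciumConfig:
    """Calcium-indicator model parameters.

    ``frame_rate`` defaults to the two-photon acquisition rate of 15.49
    frames per second.  The indicator kernel is a difference of
    exponentials with ``rise_tau`` < ``decay_tau`` (fast-indicator-like
    kinetics); ``spike_amplitude`` is the transient peak per interictal
    spike and ``seizure_gain`` the sustained plateau during a seizure, both
    in dF/F-like units on a resting baseline of 1.
    """

    frame_rate: float = 15.49
    rise_tau: float = 0.05
    decay_tau: float = 0.6
    spike_amplitude: float = 0.5
    seizure_gain: float = 1.0
    noise_sigma: float = 0.02

    def __post_init__(self) -> None:
        if self.decay_tau <= self.rise_tau:
            raise ValueError("decay_tau must exceed rise_tau")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be > 0")


@dataclass
class GenConfig:
    """Free parameters of the synthetic session generator.

    Defaults describe a 10 min mouse LFP session sampled at 500 Hz with
    Gaussian background noise of unit robust SD, biphasic epileptiform
    spikes of 40 ms width and 8x-noise amplitude (SNR 8), sparse isolated
    interictal spikes, and seizures built from spike clusters whose
    interspike intervals stay below the 1 s inclusion criterion.
    """

    sampling_rate: float = 500.0
    duration: float = 600.0
    # noise model
    gaussian_sigma: float = 1.0
    pink_sigma: float = 0.0
    pink_exponent: float = 1.0
    # spike waveform (biphasic transient)
    spike_width: float = 0.040
    spike_amplitude: float = 8.0
    # event rates
    interictal_rate: float = 0.1
    interictal_min_gap: float = 2.0
    seizure_rate: float = 0.01
    # seizure structure
    seizure_duration_log_mean: float = 2.0  # ~7.4 s median
    seizure_duration_log_sd: float = 0.4
    seizure_min_duration: float = 2.0
    seizure_min_gap: float = 40.0
    within_isi_mean: float = 0.30
    within_isi_sd: float = 0.10
    truncation_factor: float = 1.0
    calcium: CalciumConfig = field(default_factory=CalciumConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be > 0")
        if not (0.0 < self.truncation_factor <= 1.0):
            raise ValueError("truncation_factor must lie in (0, 1]")
        if self.interictal_rate < 0 or self.seizure_rate < 0:
            raise ValueError("rates must be >= 0")
        if not (self.within_isi_mean < 1.0):
            raise ValueError(
                "within-seizure ISI mean must be < 1 s so generated seizures "
                "satisfy the spike-cluster inclusion criterion"
            )
        if self.interictal_rate > 0 and self.interictal_rate >= 1.0 / self.interictal_min_gap:
            raise ValueError(
                "interictal_rate must stay below 1/interictal_min_gap: "
                "interictal spikes are isolated by definition"
            )
        if isinstance(self.calcium, dict):
            self.calcium = CalciumConfig(**self.calcium)


@dataclass
class GroundTruth:
    """Generator-emitted truth against which every stage is validated."""

    interictal_spike_times: np.ndarray
    seizure_intervals: list[tuple[float, float]]
    per_seizure_spike_times: list[np.ndarray]
    light_intervals: list[tuple[float, float]] = field(default_factory=list)
    applied_truncation_factor: float = 1.0
    duration: float = 0.0
    flags: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.interictal_spike_times = np.asarray(self.interictal_spike_times, float)
        for a, b in self.seizure_intervals:
            if not (0.0 <= a < b <= self.duration or self.duration == 0.0):
                raise ValueError("seizure intervals must lie in [0, duration)")
        prev_end = -math.inf
        for a, b in self.seizure_intervals:
            if a < prev_end:
                raise ValueError("seizure intervals must be sorted, non-overlapping")
            prev_end = b

    @property
    def n_seizures(self) -> int:
        return len(self.seizure_intervals)

    def all_spike_times(self) -> np.ndarray:
        parts = [self.interictal_spike_times] + [
            np.asarray(s) for s in self.per_seizure_spike_times
        ]
        return np.sort(np.concatenate(parts)) if parts else np.array([])

    def copy(self) -> "GroundTruth":
        return GroundTruth(
            self.interictal_spike_times.copy(),
            [tuple(iv) for iv in self.seizure_intervals],
            [np.asarray(s).copy() for s in self.per_seizure_spike_times],
            [tuple(iv) for iv in self.light_intervals],
            self.applied_truncation_factor,
            self.duration,
            dict(self.flags),
        )


def spike_waveform(
    width: float, amplitude: float, sampling_rate: float
) -> tuple[np.ndarray, int]:
    """Parameterized biphasic epileptiform transient.

    A sharp negative deflection (Gaussian, sd = width/4) followed by a
    slower positive rebound.  Returns ``(waveform, peak_index)`` where
    ``peak_index`` is the sample of the negative extremum; the extremum
    magnitude equals ``amplitude`` exactly.
    """
    t = np.arange(-1.5 * width, 2.5 * width, 1.0 / sampling_rate)
    neg = np.exp(-0.5 * (t / (width / 4.0)) ** 2)
    pos = 0.45 * np.exp(-0.5 * ((t - 0.9 * width) / (width / 1.6)) ** 2)
    w = pos - neg
    w = w * (amplitude / np.max(np.abs(w)))
    return w, int(np.argmin(w))


def _add_waveform(samples: np.ndarray, fs: float, t: float, wave: np.ndarray,
                  peak: int, sign: float = 1.0) -> None:
    """Add (or with sign=-1 remove) a waveform so its peak lands at time t."""
    start = int(round(t * fs)) - peak
    lo = max(start, 0)
    hi = min(start + wave.size, samples.size)
    if hi > lo:
        samples[lo:hi] += sign * wave[lo - start : hi - start]


def _background_noise(cfg: GenConfig, n: int, rng: np.random.Generator) -> np.ndarray:
    noise = rng.normal(0.0, cfg.gaussian_sigma, n)
    if cfg.pink_sigma > 0:
        # 1/f^a component shaped in the frequency domain
        white = rng.normal(0.0, 1.0, n)
        f = np.fft.rfftfreq(n, d=1.0 / cfg.sampling_rate)
        shape = np.ones_like(f)
        shape[1:] = f[1:] ** (-cfg.pink_exponent / 2.0)
        shape[0] = 0.0
        pink = np.fft.irfft(np.fft.rfft(white) * shape, n)
        pink *= cfg.pink_sigma / max(pink.std(), 1e-12)
        noise += pink
    return noise


def _draw_seizures(cfg: GenConfig, rng: np.random.Generator,
                   margin: float) -> list[tuple[float, float]]:
    """Sequential seizure placement: exponential inter-onset gaps at
    ``seizure_rate`` with a minimum clear gap after each offset."""
    intervals: list[tuple[float, float]] = []
    if cfg.seizure_rate <= 0:
        return intervals
    t = margin
    while True:
        gap = rng.exponential(1.0 / cfg.seizure_rate)
        onset = t + max(gap, cfg.seizure_min_gap if intervals else 0.0)
        dur = float(
            np.clip(
                rng.lognormal(cfg.seizure_duration_log_mean, cfg.seizure_duration_log_sd),
                cfg.seizure_min_duration,
                None,
            )
        )
        if onset + dur > cfg.duration - margin:
            break
        intervals.append((onset, onset + dur))
        t = onset + dur
    return intervals


def _seizure_spikes(onset: float, offset: float, cfg: GenConfig,
                    rng: np.random.Generator) -> np.ndarray:
    """Spike train spanning the seizure interval exactly.

    The first discharge sits at the onset and the last at the offset, so
    the interval is defined by its own discharges and a segmenter that
    measures the end at the last spike agrees with the truth interval.
    """
    times = [onset]
    t = onset
    while True:
        isi = float(np.clip(rng.normal(cfg.within_isi_mean, cfg.within_isi_sd),
                            0.05, 0.85))
        t += isi
        if t >= offset:
            break
        times.append(t)
    # terminal discharge at the offset; keep a clear gap before it
    while times and offset - times[-1] < 0.1:
        times.pop()
    times.append(offset)
    return np.asarray(times)


def generate_lfp(config: GenConfig) -> tuple[Recording, GroundTruth]:
    """Generate a single-channel LFP session with ground truth.

    Background noise plus additively inserted biphasic spike waveforms at
    homogeneous-Poisson interictal times and in clusters during seizure
    intervals.  Nonpositive rates simply yield empty event lists; a
    duration too short to hold a seizure yields an empty seizure list with
    ``truth.flags['no_seizure_room'] = True``.
    """
    fs = config.sampling_rate
    n = int(round(config.duration * fs))
    margin = max(3.0 * config.spike_width, 0.5)

    noise = _background_noise(config, n, stream_rng(config.seed, "lfp_noise"))

    sz_rng = stream_rng(config.seed, "seizures")
    seizure_intervals = _draw_seizures(config, sz_rng, margin)
    per_seizure = [
        _seizure_spikes(a, b, config, sz_rng) for a, b in seizure_intervals
    ]

    ii_rng = stream_rng(config.seed, "interictal")
    lo, hi = margin, config.duration - margin
    if config.interictal_rate > 0 and hi > lo:
        # dead-time renewal process at the requested mean rate: interictal
        # spikes are isolated transients by definition, so consecutive ones
        # are kept at least interictal_min_gap apart — otherwise the truth
        # itself would contain clusters satisfying the seizure rule
        mean_extra = 1.0 / config.interictal_rate - config.interictal_min_gap
        t = lo + ii_rng.exponential(1.0 / config.interictal_rate)
        cand = []
        while t < hi:
            cand.append(t)
            t += config.interictal_min_gap + ii_rng.exponential(mean_extra)
        cand = np.asarray(cand)
        # and clear of seizures
        keep = np.ones(cand.size, bool)
        for a, b in seizure_intervals:
            keep &= ~((cand >= a - 2.0) & (cand < b + 2.0))
        interictal = cand[keep]
    else:
        interictal = np.array([])

    samples = noise
    wave, peak = spike_waveform(config.spike_width, config.spike_amplitude, fs)
    for t in interictal:
        _add_waveform(samples, fs, t, wave, peak)
    for spikes in per_seizure:
        for t in spikes:
            _add_waveform(samples, fs, t, wave, peak)

    flags = {}
    if config.seizure_rate > 0 and not seizure_intervals:
        flags["no_seizure_room"] = True

    rec = Recording(samples[None, :], fs, ["lfp"])
    truth = GroundTruth(
        interictal_spike_times=interictal,
        seizure_intervals=seizure_intervals,
        per_seizure_spike_times=per_seizure,
        applied_truncation_factor=config.truncation_factor,
        duration=config.duration,
        flags=flags,
    )
    return rec, truth


def apply_intervention(
    recording: Recording,
    truth: GroundTruth,
    trigger_times,
    config: GenConfig,
    truncation_factor: float | None = None,
) -> tuple[Recording, GroundTruth]:
    """Model light-on truncation of triggered seizures.

    For each trigger that falls inside a truth seizure, the post-trigger
    duration is multiplied by the truncation factor: the new offset is
    ``trigger + factor * (offset - trigger)``.  Spikes beyond the new
    offset are deleted from the truth and their waveforms subtracted from
    the signal; a light interval ``[trigger, new_offset)`` is recorded.
    Triggers outside every seizure are ignored with a log warning.
    Factors above 1 (lengthening) are not modeled and are rejected.
    """
    factor = config.truncation_factor if truncation_factor is None else truncation_factor
    if not (0.0 < factor <= 1.0):
        raise ValueError("truncation_factor must lie in (0, 1]; lengthening not modeled")

    rec = recording.copy()
    out = truth.copy()
    out.applied_truncation_factor = factor
    wave, peak = spike_waveform(config.spike_width, config.spike_amplitude,
                                rec.sampling_rate)
    treated: set[int] = set()
    for trig in np.sort(np.atleast_1d(np.asarray(trigger_times, float))):
        hit = None
        for k, (a, b) in enumerate(out.seizure_intervals):
            if a <= trig < b:
                hit = k
                break
        if hit is None:
            logger.warning("trigger at %.3f s falls outside every seizure; ignored", trig)
            continue
        if hit in treated:
            continue
        treated.add(hit)
        a, b = out.seizure_intervals[hit]
        new_off = trig + factor * (b - trig)
        spikes = np.asarray(out.per_seizure_spike_times[hit])
        removed = spikes[spikes > new_off]
        for t in removed:
            _add_waveform(rec.samples[0], rec.sampling_rate, t, wave, peak, sign=-1.0)
        kept = spikes[spikes <= new_off]
        if removed.size:
            # the truncated seizure still ends with a terminal discharge at
            # its new offset, mirroring the generator's span convention
            while kept.size and new_off - kept[-1] < 0.1:
                _add_waveform(rec.samples[0], rec.sampling_rate, kept[-1],
                              wave, peak, sign=-1.0)
                kept = kept[:-1]
            _add_waveform(rec.samples[0], rec.sampling_rate, new_off, wave, peak)
            kept = np.r_[kept, new_off]
        out.per_seizure_spike_times[hit] = kept
        out.seizure_intervals[hit] = (a, new_off)
        out.light_intervals.append((float(trig), float(new_off)))
    return rec, out


# ---------------------------------------------------------------------------
# calcium


def calcium_kernel(cfg: CalciumConfig) -> np.ndarray:
    """Difference-of-exponentials indicator kernel, peak-normalized to 1."""
    dt = 1.0 / cfg.frame_rate
    t = np.arange(0.0, 8.0 * cfg.decay_tau, dt)
    h = np.exp(-t / cfg.decay_tau) - np.exp(-t / cfg.rise_tau)
    peak = h.max()
    if peak <= 0:
        raise ValueError("degenerate calcium kernel")
    return h / peak


def generate_calcium(
    truth: GroundTruth, n_cells: int, config: GenConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Synthesize raw-fluorescence traces coupled to the LFP events.

    Each cell's latent activity receives an impulse of height
    ``spike_amplitude x gain_cell`` at every interictal spike and a
    sustained elevation ``seizure_gain x gain_cell`` during each seizure
    interval, both shaped by the indicator kernel (impulse response
    peak-normalized; the sustained drive reaches its plateau with the same
    kinetics).  The resting fluorescence baseline is 1, so dF/F is well
    defined.  Returns ``(traces, frame_times)`` with traces of shape
    ``(n_cells, n_frames)``.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    ca = config.calcium
    dt = 1.0 / ca.frame_rate
    n_frames = int(round(truth.duration * ca.frame_rate))
    frame_times = np.arange(n_frames) * dt

    h = calcium_kernel(ca)
    h_box = h / h.sum()  # unit steady-state response for sustained drive

    impulses = np.zeros(n_frames)
    for t in truth.interictal_spike_times:
        k = int(round(t * ca.frame_rate))
        if 0 <= k < n_frames:
            impulses[k] += 1.0
    box = np.zeros(n_frames)
    for a, b in truth.seizure_intervals:
        box[(frame_times >= a) & (frame_times < b)] = 1.0

    spike_resp = np.convolve(impulses, h)[:n_frames]
    seiz_resp = np.convolve(box, h_box)[:n_frames]

    rng = stream_rng(config.seed, "calcium")
    # per-cell gains on an independent stream so the LFP is untouched
    gains = rng.lognormal(0.0, 0.25, n_cells)
    latent = (
        gains[:, None]
        * (ca.spike_amplitude * spike_resp + ca.seizure_gain * seiz_resp)[None, :]
    )
    traces = 1.0 + latent
    if ca.noise_sigma > 0:
        traces = traces + rng.normal(0.0, ca.noise_sigma, traces.shape)
    return traces, frame_times


def render_movie(
    traces: np.ndarray,
    frame_shape: tuple[int, int] = (48, 48),
    radius: int = 3,
    pixel_noise: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Render traces as a movie of disk-shaped cells plus a labeled mask.

    Cells are laid out on a lattice; every pixel of cell *i*'s disk carries
    the trace value (plus optional pixel noise), so mask-averaged
    extraction recovers the traces exactly in the noise-free case.
    Returns ``(movie, label_image)`` with movie shape
    ``(n_frames, rows, cols)`` and a uint16 label image (0 = background,
    cell i -> label i+1).
    """
    n_cells, n_frames = traces.shape
    rows, cols = frame_shape
    pitch = 2 * radius + 3
    per_row = max((cols - 2) // pitch, 1)
    if n_cells > per_row * max((rows - 2) // pitch, 1):
        raise ValueError("frame too small for requested cell count")

    labels = np.zeros(frame_shape, np.uint16)
    yy, xx = np.mgrid[0:rows, 0:cols]
    centers = []
    for i in range(n_cells):
        r = 1 + radius + (i // per_row) * pitch
        c = 1 + radius + (i % per_row) * pitch
        centers.append((r, c))
        disk = (yy - r) ** 2 + (xx - c) ** 2 <= radius**2
        labels[disk] = i + 1

    movie = np.zeros((n_frames, rows, cols), np.float64)
    for i in range(n_cells):
        mask = labels == i + 1
        movie[:, mask] = traces[i][:, None]
    if pixel_noise > 0:
        rng = stream_rng(seed, "movie")
        movie = movie + rng.normal(0.0, pixel_noise, movie.shape)
    return movie, labels


# ---------------------------------------------------------------------------
# sEEG


@dataclass
class RegionOnsetRule:
    """Per-region involvement probability and onset-latency distribution."""

    p_involved: float = 1.0
    latency_mean: float = 0.0
    latency_sd: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_involved <= 1.0):
            raise ValueError("p_involved must lie in [0, 1]")


def generate_seeg_case(
    n_seizures: int,
    channel_plan: list[tuple[str, str]],
    onset_rule: dict[str, RegionOnsetRule],
    config: GenConfig,
    ictal_duration: float = 5.0,
) -> tuple[Recording, pd.DataFrame]:
    """Generate a multi-channel sEEG case with a per-channel onset table.

    ``channel_plan`` lists ``(channel_label, region)`` pairs (e.g. FC, AH,
    neocortex); ``onset_rule`` maps each region to its involvement
    probability and onset-latency distribution relative to the seizure's
    base time.  Each involved channel receives an ictal discharge (spike
    cluster) starting at its drawn onset.  The returned table (columns
    seizure, channel, region, onset_time; NaN when not involved) is the
    ground truth for onset classification.
    """
    if len(channel_plan) < 2:
        raise ValueError("at least 2 channels required")
    if not channel_plan:
        raise ValueError("empty channel plan")
    for _, region in channel_plan:
        if region not in onset_rule:
            raise ValueError(f"no onset rule for region {region!r}")

    fs = config.sampling_rate
    n = int(round(config.duration * fs))
    rng = stream_rng(config.seed, "seeg")

    margin = 2.0
    span = config.duration - 2 * margin - ictal_duration
    if n_seizures > 0 and span <= 0:
        raise ValueError("duration too short for the requested seizures")
    base_times = margin + (np.arange(n_seizures) + 0.5) * span / max(n_seizures, 1)

    wave, peak = spike_waveform(config.spike_width, config.spike_amplitude, fs)
    samples = np.empty((len(channel_plan), n))
    for c in range(len(channel_plan)):
        samples[c] = _background_noise(config, n, rng)

    rows = []
    for s, t0 in enumerate(base_times):
        for c, (label, region) in enumerate(channel_plan):
            rule = onset_rule[region]
            involved = rng.uniform() < rule.p_involved
            onset = math.nan
            if involved:
                onset = t0 + max(rng.normal(rule.latency_mean, rule.latency_sd), 0.0)
                t = onset
                while t < onset + ictal_duration:
                    _add_waveform(samples[c], fs, t, wave, peak)
                    t += float(np.clip(rng.normal(0.25, 0.05), 0.05, 0.9))
            rows.append(
                {"seizure": s, "channel": label, "region": region,
                 "onset_time": onset}
            )

    rec = Recording(samples, fs, [lab for lab, _ in channel_plan])
    return rec, pd.DataFrame(rows)


def with_seed(config: GenConfig, seed: int) -> GenConfig:
    """Copy of the config with a different seed (convenience for sweeps)."""
    return replace(config, seed=int(seed))
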