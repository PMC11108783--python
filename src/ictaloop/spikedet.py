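"""Offline epileptiform-spike detection.

Per-criterion operators — band-pass filtering, robust-SD amplitude
threshold, full-width-at-half-maximum measurement, normalized template
matching, artifact rejection — each populate a named boolean flag on every
candidate event, and a user-specified Boolean rule over those flags decides
acceptance.  Criterion values are experimenter inputs; the defaults below
are documented starting points, not claims about any particular dataset.

Thresholds are expressed in multiples of the robust SD (1.4826 x MAD) of
the filtered trace, so detection is invariant to signal scaling and a
seizure-dense record does not inflate its own threshold.
"""
from __future__ import annotations

import ast
import re
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

from .core import Recording, robust_sd
from .synthgen import spike_waveform


@dataclass
class SpikeCriteria:
    """Detection criterion values (experimenter inputs).

    ``threshold`` is in robust-SD multiples of the filtered trace;
    ``polarity`` selects which excursions count ('neg', 'pos' or 'both').
    ``template``/``template_fs`` hold the matched waveform; candidates are
    scored by normalized cross-correlation against it.
    """

    band: tuple[float, float] = (5.0, 40.0)
    filter_order: int = 4
    threshold: float = 5.0
    polarity: str = "neg"
    width_bounds: tuple[float, float] = (0.010, 0.080)
    template: np.ndarray | None = None
    template_fs: float = 500.0
    template_min_score: float = 0.6
    refractory: float = 0.100

    def __post_init__(self) -> None:
        lo, hi = self.band
        if not (0 < lo < hi):
            raise ValueError("band must satisfy 0 < low < high")
        if self.width_bounds[0] >= self.width_bounds[1]:
            raise ValueError("width_bounds must satisfy min < max")
        if self.refractory < 0:
            raise ValueError("refractory must be >= 0")
        if self.polarity not in ("neg", "pos", "both"):
            raise ValueError("polarity must be 'neg', 'pos' or 'both'")


def default_criteria(sampling_rate: float = 500.0,
                     spike_width: float = 0.040) -> SpikeCriteria:
    """Default criteria with a matched biphasic template at unit amplitude."""
    wave, _ = spike_waveform(spike_width, 1.0, sampling_rate)
    return SpikeCriteria(template=wave, template_fs=sampling_rate)


@dataclass
class ArtifactCriteria:
    """Artifact veto: saturation and broadband-power exceedance."""

    saturation_level: float = np.inf
    broadband_band: tuple[float, float] = (60.0, 240.0)
    broadband_threshold: float = np.inf
    veto_pad: float = 0.25

    def __post_init__(self) -> None:
        if self.veto_pad < 0:
            raise ValueError("veto_pad must be >= 0")


@dataclass
class SpikeEvent:
    """A detected (or candidate) epileptiform spike."""

    time: float
    amplitude: float = 0.0
    width: float = 0.0
    template_score: float = 0.0
    flags: dict[str, bool] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# filtering


def design_bandpass(band: tuple[float, float], order: int,
                    sampling_rate: float) -> np.ndarray:
    nyq = sampling_rate / 2.0
    if band[1] >= nyq:
        raise ValueError("band edge must be below Nyquist")
    return signal.butter(order, band, btype="bandpass", fs=sampling_rate,
                         output="sos")


def bandpass_filter(recording: Recording, band: tuple[float, float] = (5.0, 40.0),
                    order: int = 4) -> Recording:
    """Zero-phase (forward-backward) band-pass of each channel."""
    sos = design_bandpass(band, order, recording.sampling_rate)
    out = recording.copy()
    for c in range(out.n_channels):
        out.samples[c] = signal.sosfiltfilt(sos, out.samples[c])
    return out


# ---------------------------------------------------------------------------
# candidates


def _excursion_runs(x: np.ndarray, thr: float, polarity: str) -> list[tuple[int, int]]:
    if polarity == "neg":
        mask = x < -thr
    elif polarity == "pos":
        mask = x > thr
    else:
        mask = np.abs(x) > thr
    if not mask.any():
        return []
    d = np.diff(mask.astype(np.int8))
    starts = np.flatnonzero(d == 1) + 1
    ends = np.flatnonzero(d == -1) + 1
    if mask[0]:
        starts = np.r_[0, starts]
    if mask[-1]:
        ends = np.r_[ends, mask.size]
    return list(zip(starts, ends))


def detect_threshold_crossings(
    filtered: Recording | np.ndarray,
    threshold: float = 5.0,
    polarity: str = "neg",
    refractory: float = 0.100,
    sampling_rate: float | None = None,
) -> list[SpikeEvent]:
    """Candidate events from robust-SD threshold excursions.

    Each supra-threshold excursion of the filtered single-channel trace
    yields one candidate at its extremum.  Candidates closer than the
    refractory period to the previously accepted candidate are suppressed
    (the earlier one wins; exact ties resolved by larger amplitude).
    A zero-variance trace yields an empty list.
    """
    if isinstance(filtered, Recording):
        if filtered.n_channels != 1:
            raise ValueError("single-channel input required")
        x, fs = filtered.samples[0], filtered.sampling_rate
    else:
        if sampling_rate is None:
            raise ValueError("sampling_rate required for array input")
        x, fs = np.asarray(filtered, float), sampling_rate

    sd = robust_sd(x)
    if sd == 0.0:
        return []
    thr = threshold * sd

    events: list[SpikeEvent] = []
    last_t = -np.inf
    for a, b in _excursion_runs(x, thr, polarity):
        seg = x[a:b]
        k = a + int(np.argmax(np.abs(seg)))
        t = k / fs
        if t - last_t < refractory:
            continue
        events.append(SpikeEvent(time=t, amplitude=abs(x[k])))
        last_t = t
    return events


def measure_spike(
    x: np.ndarray,
    sampling_rate: float,
    candidate_time: float,
    window: float = 0.100,
    polarity: str = "neg",
) -> tuple[float, float]:
    """Amplitude and full width at half maximum around a candidate.

    Amplitude is the extremum magnitude within the window (clipped at the
    recording edges); width is the duration the excursion stays beyond half
    of its extremum.  A flat window reports (0, 0).
    """
    half = int(round(window * sampling_rate / 2.0))
    c = int(round(candidate_time * sampling_rate))
    lo, hi = max(c - half, 0), min(c + half + 1, x.size)
    seg = x[lo:hi]
    if seg.size == 0 or np.ptp(seg) == 0.0:
        return 0.0, 0.0
    if polarity == "pos":
        k = int(np.argmax(seg))
        ext = seg[k]
    elif polarity == "neg":
        k = int(np.argmin(seg))
        ext = seg[k]
    else:
        k = int(np.argmax(np.abs(seg)))
        ext = seg[k]
    if ext == 0.0:
        return 0.0, 0.0
    halfmax = ext / 2.0
    beyond = seg >= halfmax if ext > 0 else seg <= halfmax
    left = k
    while left > 0 and beyond[left - 1]:
        left -= 1
    right = k
    while right < seg.size - 1 and beyond[right + 1]:
        right += 1
    width = (right - left + 1) / sampling_rate
    return abs(float(ext)), float(width)


def template_match(
    x: np.ndarray,
    sampling_rate: float,
    candidate_time: float,
    template: np.ndarray,
    template_fs: float | None = None,
    jitter: float = 0.005,
) -> float:
    """Normalized cross-correlation of the candidate window with a template.

    Both sides are made zero-mean and unit-norm; the score is maximized
    over +-jitter around the candidate, so small alignment errors do not
    penalize a genuine match.  Zero-variance windows score 0.
    """
    template = np.asarray(template, float)
    if template_fs is not None and template_fs != sampling_rate:
        n_new = max(int(round(template.size * sampling_rate / template_fs)), 2)
        template = np.interp(
            np.linspace(0, template.size - 1, n_new),
            np.arange(template.size), template,
        )
    if template.size >= x.size:
        raise ValueError("template must be shorter than the recording")
    tmpl = template - template.mean()
    tnorm = np.linalg.norm(tmpl)
    if tnorm == 0:
        return 0.0
    tmpl /= tnorm

    m = template.size
    c = int(round(candidate_time * sampling_rate))
    j = int(round(jitter * sampling_rate))
    # align the template's extremum with the candidate sample
    k_t = int(np.argmax(np.abs(template)))
    best: float | None = None
    for shift in range(-j, j + 1):
        start = c - k_t + shift
        if start < 0 or start + m > x.size:
            continue
        win = x[start : start + m]
        w = win - win.mean()
        wnorm = np.linalg.norm(w)
        if wnorm == 0:
            score = 0.0
        else:
            score = float(np.dot(w / wnorm, tmpl))
        best = score if best is None else max(best, score)
    return 0.0 if best is None else best


def filter_template(template: np.ndarray, template_fs: float,
                    band: tuple[float, float], order: int) -> np.ndarray:
    """Band-pass the template the same way the signal is filtered.

    Candidates are measured on the filtered trace, so the matched template
    must carry the same spectral shaping; the template is zero-padded
    before the zero-phase filter and trimmed back afterwards.
    """
    template = np.asarray(template, float)
    pad = max(template.size, 64)
    padded = np.r_[np.zeros(pad), template, np.zeros(pad)]
    sos = design_bandpass(band, order, template_fs)
    out = signal.sosfiltfilt(sos, padded)
    return out[pad : pad + template.size]


def reject_artifacts(
    recording: Recording,
    events: list[SpikeEvent],
    criteria: ArtifactCriteria,
    channel: int = 0,
) -> list[SpikeEvent]:
    """Flag events near saturation or broadband-power excursions.

    An event is artifact-flagged when it lies within ``veto_pad`` (closed
    boundary) of a saturated sample (|x| >= saturation_level) or of a
    sample whose band-passed broadband magnitude exceeds
    ``broadband_threshold`` robust SDs.  Flags are set in place and the
    list returned for chaining.
    """
    x = recording.samples[channel]
    fs = recording.sampling_rate
    bad = np.zeros(x.size, bool)
    if np.isfinite(criteria.saturation_level):
        bad |= np.abs(x) >= criteria.saturation_level
    if np.isfinite(criteria.broadband_threshold):
        lo, hi = criteria.broadband_band
        hi = min(hi, 0.99 * fs / 2.0)
        sos = design_bandpass((lo, hi), 4, fs)
        bb = signal.sosfiltfilt(sos, x)
        sd = robust_sd(bb)
        if sd > 0:
            bad |= np.abs(bb) > criteria.broadband_threshold * sd
    bad_idx = np.flatnonzero(bad)
    pad = criteria.veto_pad * fs
    for ev in events:
        k = ev.time * fs
        if bad_idx.size:
            j = np.searchsorted(bad_idx, k)
            near = min(
                abs(k - bad_idx[j - 1]) if j > 0 else np.inf,
                abs(bad_idx[j] - k) if j < bad_idx.size else np.inf,
            )
            ev.flags["artifact"] = bool(near <= pad)
        else:
            ev.flags["artifact"] = False
    return events


# ---------------------------------------------------------------------------
# Boolean combination


_WORD = {"and": "and", "or": "or", "not": "not"}


class BooleanRule:
    """Boolean expression over named criterion flags.

    Accepts AND/OR/NOT (case-insensitive) and parentheses, e.g.
    ``"(amplitude AND width) OR template"``.  Parsed once into a validated
    expression tree; evaluation is pure and order-independent.
    """

    def __init__(self, expression: str):
        self.expression = expression
        py = re.sub(
            r"\b(AND|OR|NOT)\b",
            lambda m: _WORD[m.group(1).lower()],
            expression,
            flags=re.IGNORECASE,
        )
        try:
            tree = ast.parse(py, mode="eval")
        except SyntaxError as exc:
            raise ValueError(f"cannot parse rule {expression!r}: {exc}") from exc
        self._tree = tree.body
        self.names = self._validate(self._tree)

    def _validate(self, node: ast.AST) -> set[str]:
        if isinstance(node, ast.BoolOp) and isinstance(node.op, (ast.And, ast.Or)):
            return set().union(*(self._validate(v) for v in node.values))
        if isinstance(node, ast.UnaryOp) and isinstance(node.op, ast.Not):
            return self._validate(node.operand)
        if isinstance(node, ast.Name):
            return {node.id}
        raise ValueError(
            f"rule may only contain flag names, AND/OR/NOT and parentheses "
            f"(got {ast.dump(node)})"
        )

    def evaluate(self, flags: dict[str, bool]) -> bool:
        missing = self.names - flags.keys()
        if missing:
            raise ValueError(f"undefined criterion flag(s): {sorted(missing)}")

        def ev(node: ast.AST) -> bool:
            if isinstance(node, ast.BoolOp):
                vals = (ev(v) for v in node.values)
                return all(vals) if isinstance(node.op, ast.And) else any(vals)
            if isinstance(node, ast.UnaryOp):
                return not ev(node.operand)
            return bool(flags[node.id])

        return ev(self._tree)


def combine_criteria(events: list[SpikeEvent],
                     rule: BooleanRule | str) -> list[SpikeEvent]:
    """Accepted events: those whose flag assignment satisfies the rule."""
    if isinstance(rule, str):
        rule = BooleanRule(rule)
    return [ev for ev in events if rule.evaluate(ev.flags)]


# ---------------------------------------------------------------------------
# pipeline

DEFAULT_RULE = "amplitude AND width AND template AND NOT artifact"


def detect_spikes(
    recording: Recording,
    criteria: SpikeCriteria | None = None,
    artifacts: ArtifactCriteria | None = None,
    rule: BooleanRule | str = DEFAULT_RULE,
    channel: int = 0,
    measure_window: float = 0.100,
) -> list[SpikeEvent]:
    """Full offline pipeline: filter, candidates, per-criterion flags, rule.

    Candidate amplitude/width/template flags are populated from the
    measured values against the criteria; the Boolean rule then selects the
    accepted events, returned sorted by time.
    """
    if criteria is None:
        criteria = default_criteria(recording.sampling_rate)
    if artifacts is None:
        artifacts = ArtifactCriteria()
    single = Recording(recording.samples[channel][None, :],
                       recording.sampling_rate,
                       [recording.channel_labels[channel]])
    filt = bandpass_filter(single, criteria.band, criteria.filter_order)
    x = filt.samples[0]
    events = detect_threshold_crossings(
        filt, criteria.threshold, criteria.polarity, criteria.refractory
    )
    tmpl = None
    if criteria.template is not None:
        tmpl = filter_template(criteria.template, criteria.template_fs,
                               criteria.band, criteria.filter_order)
    amp_floor = criteria.threshold * robust_sd(x)
    for ev in events:
        amp, width = measure_spike(x, filt.sampling_rate, ev.time,
                                   measure_window, criteria.polarity)
        ev.amplitude, ev.width = amp, width
        ev.flags["amplitude"] = amp >= amp_floor
        ev.flags["width"] = bool(
            criteria.width_bounds[0] <= width <= criteria.width_bounds[1]
        ) and width > 0
        if tmpl is not None:
            ev.template_score = template_match(
                x, filt.sampling_rate, ev.time, tmpl, criteria.template_fs,
            )
            ev.flags["template"] = ev.template_score >= criteria.template_min_score
        else:
            ev.flags["template"] = True
    reject_artifacts(single, events, artifacts)
    accepted = combine_criteria(events, rule)
    accepted.sort(key=lambda e: e.time)
    return accepted


def event_times(events: list[SpikeEvent]) -> np.ndarray:
    return np.asarray([ev.time for ev in events], float)


def with_threshold(criteria: SpikeCriteria, threshold: float) -> SpikeCriteria:
    return replace(criteria, threshold=threshold)
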