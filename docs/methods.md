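# Methods

`ictaloop` implements the analysis chain of a closed-loop seizure
experiment: epileptiform-spike detection on local field potential (LFP)
recordings, interspike-interval seizure segmentation, a causal online
detector with light-delivery scheduling, peri-event calcium analysis,
intervention-effect statistics, and human sEEG onset-pattern
classification. A synthetic-data generator with exact ground truth drives
every stage, so the whole pipeline is testable without any recordings.

## Synthetic session model

**LFP.** A single channel sampled at 500 Hz (the preclinical acquisition
rate) contains Gaussian background noise (robust SD `gaussian_sigma`,
default 1; an optional 1/f^a component can be added) plus additively
inserted spike waveforms. The waveform is a parameterized biphasic
transient — a sharp negative Gaussian deflection (sd = width/4) followed
by a slower positive rebound — with default width 40 ms and amplitude 8
noise-SD (SNR 8). Real epileptiform spike amplitudes vary widely across
preparations, so these are free parameters, not claims about any dataset.

**Events.** Interictal spikes are *isolated* transients: their times form
a dead-time renewal process (exponential gaps plus a 2 s minimum
separation, mean rate as configured, default 0.1/s). A pure Poisson stream
would occasionally emit three spikes within two seconds — by the cluster
rule below that *is* a seizure, so the truth labels would contradict
themselves. The renewal mean count still equals rate x duration, the
Poisson closed form.

Seizures are realized purely as spike clusters. Onsets follow exponential
gaps (default mean 100 s) with a 40 s minimum postictal gap — kainate-model
electrographic seizures are typically tens of seconds to minutes apart,
and the gap also keeps consecutive seizures independently resolvable by a
detector with a post-trigger lockout. Durations are lognormal (log-mean
2.0 ~ 7.4 s median, log-sd 0.4, minimum 2 s). Within a seizure, interspike
intervals are Gaussian (mean 0.3 s, sd 0.1 s, clipped to [0.05, 0.85] s),
so every generated seizure satisfies the < 1 s inclusion criterion by
construction. The spike train *spans* its interval exactly: the first
discharge sits at the onset and a terminal discharge at the offset. This
convention makes the truth interval and the signal agree about where the
seizure ends; with offsets drawn beyond the last spike, any segmenter that
measures the end at the last discharge would carry a systematic half-ISI
bias against the truth.

**Intervention.** Light-on truncation multiplies the post-trigger duration
by a factor in (0, 1]: the new offset is `trigger + factor x (offset -
trigger)`; spikes beyond it are removed from truth and signal, a terminal
discharge is placed at the new offset, and a light interval
`[trigger, new_offset)` is recorded. Lengthening (factor > 1) is not
modeled.

**Calcium.** Traces are sampled at 15.49 frames/s (the two-photon
acquisition rate). Latent activity receives an impulse (peak
`spike_amplitude`, default 0.5) per interictal spike and a sustained
elevation (`seizure_gain`, default 1) during seizures, each shaped by a
difference-of-exponentials indicator kernel (rise 50 ms, decay 600 ms,
fast-indicator-like). The impulse response is peak-normalized; the
sustained drive is steady-state-normalized so a seizure plateaus at
`seizure_gain`. Resting fluorescence is 1 per cell (so dF/F is well
defined), per-cell gains are lognormal (sd 0.25), and Gaussian frame noise
is added. Movies render each cell as a disk whose pixels all carry the
trace value, so mask-averaged extraction recovers traces exactly in the
noise-free case.

**sEEG.** Multi-channel cases at 1,000 Hz (the clinical rate): per seizure
and channel, a region-specific rule draws involvement (Bernoulli) and an
onset latency (Gaussian), and an involved channel receives a 5 s ictal
spike cluster from the drawn onset. The emitted onset table is the truth
for classification tests.

**Randomness.** One top-level seed; each sub-generator (noise, interictal,
seizures, calcium, movie, sEEG) draws from an independent stream spawned
with a fixed table via `numpy.random.SeedSequence.spawn`, so adding
calcium cells never perturbs the LFP noise. Identical seeds give
bit-identical outputs.

**What the generator does not emulate.** Biophysical seizure dynamics,
waveform variability and polyspike morphology, electrode drift, movement
artifacts, realistic 1/f background by default, photobleaching, or neuropil
contamination. Passing tests therefore demonstrate the *machinery* —
detection, segmentation, scheduling, statistics — under known truth, not
performance on real recordings, where criterion values must be tuned per
subject exactly as in the experimental workflow this package models.

## Spike detection

Criterion values are experimenter inputs held in `SpikeCriteria`; defaults
are band-pass 5-40 Hz (Butterworth order 4, zero-phase offline), threshold
5 robust SD, negative polarity, width bounds 10-80 ms, template score 0.6,
refractory 100 ms. Thresholds use the robust SD (1.4826 x median absolute
deviation) rather than the plain SD so that seizure-dense records do not
inflate their own threshold; detection is consequently invariant to signal
scaling. Each supra-threshold excursion yields one candidate at its
extremum (candidates closer than the refractory period to the previous
accepted one are suppressed; earlier wins, ties broken by amplitude).
Width is full width at half maximum of the excursion. Template matching is
zero-mean unit-norm cross-correlation, maximized over +-5 ms of jitter;
the template is band-passed exactly like the signal before matching, since
candidates are measured on the filtered trace. Artifact rejection flags
events within a closed `veto_pad` boundary of saturated samples or of
broadband-power excursions. A Boolean rule over the named flags (AND / OR
/ NOT, parsed to a validated expression tree) decides acceptance; the
default rule is `amplitude AND width AND template AND NOT artifact`.

## Seizure segmentation

Two rules, in order. *Inclusion*: clusters grow while consecutive
interspike intervals stay below `max_isi` (1 s). *Termination*: a seizure
is not ended until the spiking rate falls below one spike per `end_gap`
(2 s); trailing spikes with gaps in [1, 2) s therefore extend the seizure,
which ends at the last spike followed by a gap >= 2 s. Where the two rules
disagree (trailing ISIs in [1, 2) s) the termination rule wins. Boundary
conventions, stated once: `<` for inclusion, `>=` for termination.
`min_spikes` (default 3; singleton "clusters" are interictal spikes, not
seizures) applies to the core run of sub-1 s ISIs;
spikes absorbed by the termination rule count toward the event but cannot
seed or qualify a cluster. Clusters closer than `intercluster_interval`
(default = `end_gap`) are merged. Segmentation is validated against an
independent brute-force reference on every subset of 8-point time grids
and on 1,000 random trains. Durations for all intervention statistics are
measured from the closed-loop trigger to the seizure end.

## Online detection and light delivery

The streaming detector re-implements the offline chain causally: a
direct-form IIR band-pass with carried state, a robust-SD threshold
recomputed at fixed 1 s absolute-time boundaries from a trailing 10 s
baseline buffer (detection disabled during a 2 s warm-up), and excursion
tracking that emits a spike when the trace re-crosses the threshold. All
state is carried across calls and all boundaries are defined on absolute
sample indices, so output is exactly invariant to input chunking and no
decision uses future samples. A trigger fires when >= 3 detected spikes
fall within a 2 s window (the minimal rule consistent with spike-cluster
seizures; experimental closed-loop software typically uses per-animal
tuned features, which this rule stands in for), subject to
a 30 s lockout. Light delivery is either continuous from trigger to
seizure end (optogenetic inhibition mode) or a pulse train — 2 s pulses
every 6 s (33% duty cycle) for 10 min, the activity-labeling protocol.
Offline re-segmentation with the zero-phase pipeline is authoritative for
durations, mirroring the semiautomatic experimental analysis.

## Calcium analysis

Raw traces are mask-averaged pixel means. dF/F uses a rolling-percentile
baseline (8th percentile over a centered 30 s window, shrunken at the
edges), a standard choice for indicator imaging; both percentile and
window are configuration values since published recipes vary. Traces are max-normalized per cell
(idempotent; nonpositive maxima dropped with a warning). Peri-event
matrices average max-normalized dF/F across events on a relative-time grid
(event at bin 0, nearest-frame assignment to bin centers for bit
reproducibility; edge-clipped events tracked per bin). The
activity-spiking correlation is the product-moment correlation between
each cell's dF/F and the spike rate binned at a configurable width and
interpolated to frame times, summarized as mean +- s.e.m. across cells.
Note that at one-frame binning the rate is nearly a delta train while the
indicator kernel starts at zero, so instantaneous correlations are
intrinsically small; a ~1 s bin is the physiologically meaningful probe.

## Intervention statistics

The per-seizure duration table carries (animal, group, condition,
duration-from-trigger). Normalized seizure duration is per animal — mean
light-on duration over mean light-off duration, x 100 — summarized as mean
+- s.e.m. *across animals*, never across seizures. The condition effect is
tested with a two-level model (fixed light-condition effect, per-animal
random intercept, REML via statsmodels MixedLM); the F statistic is the
squared Wald statistic on 1 numerator dof with denominator dof n - 2.
This is the minimal structure matching a "mixed-effect model" with few
animals and many seizures; richer structures are possible, so the
contract is behavioral: on table-level simulations (4 animals x 100
seizures per condition, lognormal durations with animal-level log-offsets)
the null rejection rate at alpha = 0.05 must stay in [0.03, 0.07] and
power at truncation factor 0.5 must exceed 95% at alpha = 0.01. Group
comparisons use a two-sample two-tailed t test on the per-animal
normalized durations (equal-variance by default).

## sEEG onset classification

Onset times are inputs (expert-marked or generator truth; automated human
ictal-onset marking is out of scope). Per seizure, the earliest involved
channel per region defines the region onset; patterns follow the 50 ms
rule — separations of 50 ms *or more* are differential (spread from the
earlier region), under 50 ms simultaneous. FC involvement without AH is
labeled `FC_independent`, matching the clinical phrasing; AH without FC is
`AH_without_FC`. The 80-250 Hz marker band-passes the channel, takes the
analytic-signal envelope, and flags windows whose mean envelope exceeds a
robust-SD multiple (default 5) of the whole-record envelope spread.

## Validation problem sizes

The end-to-end recovery experiment runs, per truncation factor in
{1.0, 0.75, 0.5} and per seed batch, 4 synthetic animals with one light-on
and one light-off session each: 2,200 s at 500 Hz, seizure rate 1/25 s^-1
with a 20 s postictal gap and a 15 s trigger lockout, yielding >= 100
triggered seizures per animal. The test suite uses 20 seed batches;
recovery requires the group normalized duration to be monotone in the
factor and to cover the truth within 2 s.e.m. in >= 90% of batches. Model
calibration uses 500 null and 100 effect replicates at the table level.

## Known limitations

Width/template criteria are not evaluated online (amplitude, refractory
and the N-in-window rule are), so the streaming detector is slightly more
permissive than the offline one; offline re-segmentation is authoritative.
The online trigger timestamp is the threshold re-crossing sample of the
N-th spike, a few tens of milliseconds after the spike extremum.
Segmentation requires sorted, unique spike times. EDF ingestion requires
the optional `mne` dependency.
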