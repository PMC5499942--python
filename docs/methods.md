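# Methods

This note documents the models and procedures escapekit implements, the
parameters that matter, what the synthetic-data generators do and do not
emulate, and the numerical choices made where the design was genuinely
open.  All empirical statements below are computed by the test suite or
by `scripts/acceptance.py`; nothing is quoted from elsewhere.

## Tail-angle kinematics

**Processing chain.** A trial is a signed tail-angle trace θ(t) in degrees
at the native frame rate with a known stimulus frame.  The chain is:
median filtering → bout detection → peak detection → categorization →
summaries → exclusion → fast/slow decomposition.

**Median filtering.** Centered sliding median; at the edges the window
shrinks to the available samples, and even windows extend one frame
further to the left than to the right (the convention of
`pandas.Series.rolling(center=True)`, frozen by an independent brute-force
oracle in the tests).  The default window is 10 frames for the 1000 fps
head-embedded configuration.  At 650 fps a 10-frame window spans most of a
fast half-period (55 Hz → 11.8 frames) and attenuates C-bends roughly
four-fold, so the 650 fps freely-swimming configuration uses a 3-frame
window; the tracker output this assay emulates is already spatially
filtered, and the shorter window only removes single-frame outliers.

**Bout detection.** Start = first post-stimulus frame whose absolute
frame-to-frame differential and the next 3 differentials all exceed
0.08°/frame.  End = last frame of the first run of 20 consecutive
differentials below 0.1°/frame after the start ("maximal bout" reading).
Both thresholds are in degrees/frame at the native fps.  If no quiet run
completes before the trace ends, the bout is truncated at the trace end
and flagged; downstream duration/distance/speed are then upper bounds.
These printed thresholds presuppose a post-filter noise floor well below
0.08°/frame — with ≥ 0.2° frame noise the start rule fires in pure noise
and the end rule never latches (measured in development, which is why the
generator's default angle noise is 0.05°, see below).

**Peak detection.** Candidate extrema are local maxima/minima of the
filtered angle after run-compressing equal consecutive samples; a plateau
contributes its first frame, and a plateau overlapping the bout start is
eligible.  A candidate is accepted when |θ| exceeds the value 5 ms earlier
by ≥ 1°, and it lies ≥ 2 ms after the previously accepted peak (violations
keep the earlier peak).  A candidate of the same extremum type as the last
accepted peak replaces it only if larger in magnitude, enforcing
alternation.

**Categorization.** With cycles = n_peaks/2: *escape* iff the first bend
is asymmetric (|p₁| ≥ 1.5·|p₂|) and cycles ≥ 1; *slow swim* iff symmetric,
all |peaks| < 25°, and cycles > 1; otherwise *unclassified*.  The
asymmetry ratio 1.5 is a package choice (no quantitative definition of
"asymmetrical C-bend" exists to copy); it is configurable
(`asym_ratio`).

**Exclusion criteria.** A trial is excluded when (i) the bout-start rule
fires anywhere before the stimulus, (ii) the first post-stimulus peak
comes > 20 frames after the stimulus, or (iii) the first peak is < 60°.

**Fast/slow decomposition.** Hemi-period = interval between consecutive
peaks = half a cycle, so frequency f = fps/(2h); the 30 Hz cutoff at
650 fps is the exact rational 650/60 ≈ 10.83 frames (compared without
rounding to avoid fps-dependent bias).  Sub-cutoff hemi-periods are fast
until the first slow hemi-period; after it, sub-cutoff hemi-periods are
labeled *excluded*, enforcing a single fast→slow transition.  The three
labels partition the bout, so component durations sum to the total
inter-peak duration (property-tested).

## Bioluminescence

1 ms photon counts are summed into 10 ms bins (trailing partial bin
dropped), smoothed with a centered 10-bin running average, and
baseline-subtracted.  The baseline rate is the least-squares slope of the
cumulative pre-stimulus count versus time, rescaled to photons/10 ms; this
estimator is unbiased for Poisson inputs (verified to < 2% at 0.05–0.5
photons/ms over 500 replicates).  Subtraction is uniform and floored at
zero.  Signal start = first post-stimulus point whose next three
differentials exceed 0.4 photons/10 ms; end = first point after the peak
whose next three differentials are below 0.2 in magnitude (the end rule is
applied to the |differential|; the signed/absolute choice was open).
Amplitude is the processed value at the peak; SNR is amplitude over the
pre-stimulus SD of the processed trace.  The decay coefficient comes from
a one-term exponential least-squares fit (log-linear initialisation, then
`scipy.optimize.curve_fit`) between peak and end and is reported only when
R² > 0.95.  Per-larva normalization divides each trial amplitude by that
larva's maximum trial amplitude (no formula was printed; division by the
max maps to [0, 1] and makes a larva's best trial the reference).

The 10-bin running average means a signal rising over ≤ 10 bins has
maximum smoothed differential ≈ amplitude/10, so the 0.4 threshold implies
a ~4 photons/10 ms detection floor: swim-scale signals sit at that floor
and are detected in only a fraction of trials, escape-scale signals
always.  The smoothing-window placement (over binned points rather than
the 1 ms trace) was an open choice; the binned reading is implemented.

## Calcium imaging and VNR

ΔF/F(t) = 100·(F−F₀)/F₀ with F₀ the mean over the 20 frames (1 s at
20 Hz) before each event — the baseline rule is a package choice, the
source states none.  The activity threshold for an event is the maximum
ΔF/F reached by out-of-focus background ROIs during the event: the
ventral background for swims, the larger of ventral and dorsal for
escapes (matching where out-of-focus light arises in each behavior); a
cell is active iff its peak ΔF/F strictly exceeds the threshold, so a
peak exactly at threshold is silent.  Dorso-ventral positions are mapped
affinely to [0, 1] between the ventral and dorsal spinal-cord limits and
clipped.

VNR bursts: the recording is median-centered, rectified, smoothed with a
2 ms moving average, and thresholded at 3× the MAD-derived SD; segments
closer than 5 ms merge.  Baseline noise amplitude is defined as 2× the
robust SD; QC fails above 0.05 mV or at envelope SNR ≤ 3.  Instantaneous
burst frequency is the reciprocal inter-onset interval; a bout reaching
> 30 Hz is escape-like, otherwise swim-like.  The burst operator itself is
a package design (only the QC gates were prescribed).

## Connectivity electrophysiology

Spikes are suprathreshold excursions crossing 0 mV within 20 ms of a light
pulse (the crossing criterion is a package choice); time-to-peak is
measured to the maximum of the first excursion.  EPSC onset is the first
sample after the pulse where the inward deflection from the 50 ms
pre-pulse baseline exceeds 3 baseline SDs for 5 consecutive samples at
10 kHz; amplitude is the largest inward deflection within 20 ms of onset.
Lag = mean EPSC onset − mean spike time-to-peak, with per-cell means taken
over stimulations before any cross-cell averaging; monosynaptic iff
lag < 3 ms (strict).  Conduction velocity v = d/(lag − 0.5 ms) with
mm/ms ≡ m/s; depolarization ΔV = I·R with pA·MΩ = µV.  Current-step
protocols: steady-state ΔV (mean over the last half of the 250 ms step,
minus pre-step baseline) regressed on ΔI over subthreshold steps gives
input resistance; rheobase is the smallest current eliciting ≥ 1 spike.
Liquid-junction potential is not corrected.

## Synthetic data: what it emulates, and what it does not

All generators draw from `numpy.random.SeedSequence([seed, stream_id,
trial])`, so one global seed fans out deterministically and identical
(seed, parameters) give bit-identical output.  Every quantity an analysis
stage estimates is present in the returned ground truth.

**Tail traces.** Escape: θ(t) = A(t)·w(t)·sin φ(t) with amplitude
A(t) = 120°·e^(−t/10 ms) + 20° (initial C-bend, decaying toward a 20°
sustained oscillation), instantaneous frequency f(t) = 24 + 31·e^(−t/60 ms)
Hz decaying from the fast regime through 30 Hz at an analytically known
crossing time, and a smooth taper w(t) ending the bout after ~180 ms —
amplitude and frequency decay together.  Slow swim: symmetric 15°
oscillation at 22–28 Hz.  Per-trial jitter perturbs amplitude, frequencies
and duration.  Head position integrates a speed proportional to
envelope × frequency, calibrated to ~8–10 mm escape paths.  Ground-truth
peaks/hemi-periods/mean TBF come from the extrema of the noiseless
waveform; the fast→slow transition is the exact frequency crossing.
Additive Gaussian angle noise defaults to 0.05° SD: the printed
differential thresholds (0.08, 0.1°/frame) are only meaningful below a
~0.03°/frame post-filter noise floor, so the generator emulates tracker
output at that floor rather than raw video jitter.  Classification is
additionally property-tested at 2° noise, where it remains ≥ 95% correct;
bout-end detection and duration-based quantities are not meaningful at
that noise level and are not asserted there.  Default escapes pass all
three exclusion criteria; default swims fail criterion (iii), as the
escape filter intends.

**Photon trains.** Inhomogeneous Poisson counts per ms with rate =
baseline (0.05/ms) + gain · (drive ⊛ kernel), unit-area single-exponential
kernel with τ = 500 ms.  The motor drive is a front-loaded exponential
envelope (τ = 30 ms) over the bout — maximal output at response onset —
which makes the processed signal rise over ~9 bins so that swim-scale
signals remain at, not under, the printed detection floor.  The gain (60)
is calibrated so the default escape drive peaks near 30 photons/10 ms
after processing, the scale of real escape signals, with the swim drive at
0.15× giving ~4.5.  The ground-truth amplitude and time-to-peak are
obtained by running the deterministic processing chain on the expected
(noiseless) rate, so recovery tests isolate the effect of Poisson noise.

**Calcium populations.** 69 cells, 16 swim-recruited (dv_norm in
[0.05, 0.30]) nested in 61 escape-recruited (the other 45 in
[0.45, 0.95]); transient amplitude grows with dorso-ventral position and
is larger for escapes.  The disjoint position bands guarantee the
recruitment ordering (higher proportion and higher mean dv_norm in
escapes) on every seed, not just on average.  Transients are
difference-of-exponentials GCaMP6f-like kernels (50 ms rise, 400 ms
decay).  Out-of-focus contamination (20% ΔF/F for escapes, half for
swims) is added to all cells and, scaled ×1.5, to both background ROIs —
the backgrounds sit where out-of-focus light is strongest, which is what
makes the thresholding conservative and the default population exactly
recoverable (16/69 and 61/69 on 20/20 seeds).

**Ephys sweeps.** Current-clamp: rest −65 mV plus a stereotyped 90 mV
Gaussian-shaped spike peaking 2.80 ms after each pulse.  Voltage-clamp: an
inward alpha-function EPSC (τ = 1 ms, 28.14 pA) starting 3.71 ms after
each pulse.  Optional per-stimulation Gaussian latency jitter; Gaussian
noise 0.3 mV / 1 pA.

**Not emulated:** video frames and midline tracking, turning/heading
dynamics, burst substructure within calcium events, aequorin consumption,
channel kinetics, electrode artifacts.  Passing tests therefore show the
*analysis chain* recovers known signal parameters under realistic noise;
they cannot validate the upstream tracking or imaging steps.

## Replication studies and problem sizes

`escapekit.studies` runs each recovery suite at sizes chosen to keep the
whole suite fast while leaving Monte-Carlo margins well inside the
asserted bounds: 200 bouts per maneuver class; a 283-trial battery with
21 swims; 500 Poisson replicates per rate; 20 calcium seeds; 200 EPSC
sweeps.  Observed at these sizes (seed 1): 100% classification, mean TBF
error 0.8%, transition error 0.68 hemi-periods, baseline error ≤ 0.3%,
EPSC onset bias +0.09 ms and amplitude error 3.2%.

The fast→slow transition is scored as the mean distance between the start
of the first slow-labeled hemi-period and the generated 30 Hz crossing,
required to be below one mean hemi-period.  A per-trial criterion would be
dominated by integer-frame quantization: near the cutoff a ±1-frame peak
shift changes a hemi-period's frequency by ~2.8 Hz at 650 fps, so single
trials can slip a hemi-period either way; the mean error (≈ 0.7
hemi-periods) is the meaningful resolution of the method at this frame
rate.

## Known limitations

* The bout end rule requires 20 consecutive quiet differentials and fails
  (bout flagged truncated) when frame noise exceeds ~0.1°; duration,
  distance and speed are then upper bounds.
* EPSC onset has a small positive bias (≈ +0.09 ms at 10 kHz): threshold
  crossing on a finite rise plus sample-grid quantization.  Lag estimates
  inherit it.
* Detected amplitudes are argmax statistics and inherit a small positive
  noise bias (~3% for EPSCs at SNR ≈ 28, ~1 photon for bioluminescence).
* Swim-scale bioluminescence signals sit at the detection floor by
  construction; their detected-amplitude mean is conditional on detection
  and overestimates the unconditional mean.
* `classify_active` assumes background ROIs upper-bound contamination in
  cell ROIs; if contamination were locally stronger at a cell than at the
  backgrounds, silent cells could be called active.
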