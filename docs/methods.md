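# Methods

This note documents the models, parameter choices and numerical details
behind `nremtools`, in the order the pipeline runs.

## Synthetic polysomnography

The generator produces multichannel recordings whose statistical structure
matches what the downstream detectors assume, with full ground truth. Each
channel is independent (no volume conduction); channels share the hypnogram
and parameters.

**Background.** FFT-shaped Gaussian noise with amplitude profile
f^(−β/2), so the PSD follows f^(−β) across the analysis range. By default
the series is rescaled to a target RMS; alternatively
`aperiodic_intercept_true` pins the PSD to e^c·f^(−β) in µV²/Hz.

**Slow waves.** Negative half-sines (duration uniform on a configurable
sub-range of [0.5, 2] s; amplitude log-normal) are placed at Poisson counts
(density × analyzed NREM minutes) uniformly within N2/N3 runs, with a 1-s
minimum gap so ground-truth matching is unambiguous. Each down-state
carries flanking up-state lobes (positive half-sines at 0.75× the
down-state amplitude, one duration each side). The lobes serve two
purposes: slow oscillations in vivo are down-state/up-state cycles, and an
isolated half-sine's band-pass rebound otherwise makes the slow-wave phase
advance very non-uniformly around the trough, which would distort any
phase-targeted event placement (recovered coupling angles were biased by up
to ~25° without the lobes, ≤ ~7° with them).

**Spindles.** Hann-enveloped sinusoids at a configurable sigma frequency.
A fraction `p_coupled` is attached to host slow waves by *phase-conditioned
rate modulation*: the peak sample is drawn from the ±1.5 s window around
the host trough with probability proportional to the von Mises density
vM(φ(t); μ, κ) evaluated at the local slow-wave phase of the
background-plus-slow-wave signal. Two properties motivate this rule over
"place at the sample whose phase is nearest a drawn angle":

* at κ = 0 it reduces *exactly* to uniform-in-time placement — the same
  distribution the MRL shuffle null draws from, so the null z-score is
  calibrated by construction (measured over 100 simulations: mean ≈ 0.0,
  SD ≈ 1.1);
* where phase advances uniformly (inside the slow oscillation) or is
  randomized by background noise (outside it), the realized phases are von
  Mises distributed, so μ and MRL = I₁(κ)/I₀(κ) are recoverable.

Uncoupled spindles are placed away from slow-wave troughs (> 2 s) by
default, which makes truth matching unambiguous but also means the overlap
z-score of a default simulation sits *below* chance; `uncoupled_placement
= "uniform"` removes the avoidance for null-calibration studies.

**Defaults** (chosen once as realistic NREM conditions for an adolescent
central channel, and used by the artifact-rejection and end-to-end tests):
background 45 µV RMS with β = 1.5; slow waves 12/min, 100 ± 25 µV,
0.8–1.4 s (the relative-threshold detector is deliberately liberal, so
densities above 10/min are the norm); spindles 3/min, 13 Hz, 15 µV
envelope, 0.8–1.2 s; p_coupled = 0.5, μ = 30°, κ = 3 (coupling
concentration equivalent to mean resultant lengths near 0.7, the range
typically reported at central electrodes). Criterion-specific fixtures in
the tests override these where a recovery experiment specifies its own
conditions (e.g. 5 µV background for spindle detection; 150 µV, 1-s
slow waves for trough-timing checks).

What the generator does **not** emulate: topography and volume conduction,
K-complexes, stage-dependent background slopes, REM phasic events, real
artifact morphology (its artifact modes are stylized: in-band sinusoids,
sample clipping, RMS scaling). Passing tests therefore demonstrate
correctness of the algorithms under the stated generative model, not
clinical performance.

## Conditioning and artifact rejection

Signals are resampled to 128 Hz (polyphase, anti-aliased) and detrended
with a 0.25 Hz zero-phase Butterworth high-pass. Rejection operates on
pooled N2+N3 epochs, per channel, three criteria in fixed order (an epoch
records the first criterion that fired):

1. **Flanking band power** — delta (1–4 Hz) power above mean + 2.5 SD, or
   beta (16–25 Hz) power above mean + 2 SD, of up to 7 pooled-NREM epochs
   on each side (fewer at the record edges; below 3 flankers the epoch
   passes with a logged warning). Band powers enter in decibels: on the
   linear scale the right tail of delta power across perfectly clean epochs
   already trips a 2.5-SD threshold ~5 % of the time, while the dB scale is
   near-symmetric. Per-epoch power is a 4-s-Hann Welch estimate.
2. **Clipping** — more than 5 % of epoch samples equal to the channel's
   global minimum or maximum. A constant channel degenerately pins every
   sample at both extremes; all its epochs are rejected with a warning.
3. **Iterative RMS/Hjorth** — three cycles; an epoch falls when its RMS
   exceeds **twice the whole surviving signal's standard deviation**, or a
   Hjorth score (√activity, mobility, complexity) more than doubles its
   whole-signal counterpart; the reference is recomputed from survivors
   each cycle, so marginal epochs can fall after gross outliers are gone.
   The ratio-to-whole-signal reading (an RMS *is* a standard deviation)
   was chosen over z-scoring the per-epoch metrics: with four correlated
   metrics, three cycles and ~30 epochs, any 2-SD z rule rejects 15–35 %
   of perfectly clean simulated epochs, which would make the criterion
   useless as an artifact filter. Under the ratio rule, clean simulated
   recordings lose ~6 % of epochs (all to the flanking criterion's
   inherent ~2–4 % per band), while each stylized artifact mode is caught
   with sensitivity 1.0 at the fixture magnitudes.

REM epochs are not policed (the criteria are defined on the pooled NREM
set); they enter the aperiodic analysis unmasked, excluding ART stages.

## Spectral analysis

Welch (4-s Hann, 2-s step, per-epoch average), multitaper spectrogram
(30-s windows, 10-s step, 1 Hz bandwidth → 29 Slepian tapers), IRASA with
h ∈ 1.1:0.05:1.9 via rational polyphase resampling, and the log-log
aperiodic fit on 1–20 Hz (below 1 Hz the high-pass shoulder would bias the
slope). Power is linear µV²/Hz internally with a dB view; zero/negative
bins read a −300 dB floor sentinel.

Caveats worth knowing:

* The slow-delta band defaults to 0.25–1.5 Hz and is configurable (the
  literature uses both <1.25 and <1.5 Hz conventions).
* Band powers of the *oscillatory* (residual) spectrum are means of per-bin
  dB values. A background with no oscillatory activity in a band has a
  residual fluctuating around zero, so its "band power" is dominated by the
  floor sentinel (values near −150 dB in the worked example). Such values
  are only meaningful relatively — a recording with genuine oscillatory
  delta or sigma power stands far above the floor.
* NREM aperiodic slopes from recordings with events run steeper than the
  generative background exponent, because slow waves concentrate power at
  low frequencies; REM slopes (background only) recover it directly.

## Event detection

Spindle detection uses `pywt`'s fbsp (m = 2, f_b = 2) continuous wavelet at
the individualized center frequency. This wavelet's spectral profile is a
triangular B-spline of half-width ≈ f_c, i.e. deliberately broad — a tone
4 Hz off a 13 Hz center is only attenuated to ~0.69× — which favors
sensitivity; specificity comes from the 3×-median threshold, the duration
rules and the band-ratio quality metric. The quality metric is a
discriminator against low-frequency transients, not against featureless
noise: on windows statistically identical to the baseline each band's
increase is ≈ 1 and the sigma-vs-rest comparison passes ~50 % of the time
by symmetry.

Slow-wave detection filters each contiguous analyzed segment with a
Hamming-windowed-sinc FIR (0.25–4 Hz, transition 0.25 Hz, length capped by
the segment). The reported amplitude is the trough of the *filtered*
signal: a 150 µV, 1-s raw half-sine reads ≈ −103 µV after the high-pass
side removes its DC pedestal (≈ −146 µV when flanked by up-states). The
2×-median threshold is computed over all negative half-waves before the
amplitude/duration criteria are applied. Candidates touching a segment
edge are discarded (duration unverifiable); thresholds are median-relative,
so detection is exactly invariant to rescaling a channel.

Events closer than 0.5 s merge unless the union exceeds 3 s, in which case
both originals are kept (discarding them would bias density downward).

## Coupling

Phase convention: reported phase = (analytic-signal angle − 90°) mod 360,
which reads 0° at the descending zero crossing, 90° at the trough, 180° at
the ascending crossing, 270° at the peak. Spindles pair with the slow wave
whose trough is nearest their peak (≤ 1.5 s; ties to the earlier trough).

The MRL shuffle null repositions each paired spindle peak uniformly within
its **matching window** (trough ± 1.5 s) by default; shuffling within the
host slow wave's extent is available (`mrl_shuffle_domain = "extent"`) but
is not the default because a 0.5–2 s half-wave spans only about half a
phase cycle, so its null phase distribution is concentrated regardless of
whether coupling exists and the resulting z-score is not centered under
the no-coupling condition. Shuffled peaks that land where no phase is
defined (segment gaps) are redrawn up to 100 times, then dropped from that
shuffle. Below 5 pairs the z is reported missing. The observed mean
coupling angle is computed from raw phases (only overlap and MRL are
z-scored).

Trough-locked scalograms use 17 wavelet frequencies (8–16 Hz, 0.5 Hz
spacing) in a ±2 s window, z-scored per slow wave and per frequency row
against the −2…−1.5 s pre-trough baseline, then averaged (rows with zero
baseline SD are dropped from the average).

## Statistics

The Rayleigh p-value uses the standard exponential approximation; the
Watson–Williams F applies the κ-based correction factor 1 + 3/(8κ) with κ
estimated from the pooled mean resultant length (warned below R̄ = 0.45).
Cluster correction forms maximal adjacency-connected sets of units with
|stat| above a configurable threshold (default: the two-sided t critical
value at α = 0.05 for the available degrees of freedom — the
cluster-forming threshold is a free parameter of the method), uses the sum
of |stat| as cluster mass, and compares against the permutation
distribution of the maximum mass with the (1+k)/(1+N) convention, so
p-values are never zero and are monotone in mass for a fixed null sample.
The per-unit statistic is injected (default: Welch two-sample t on
subject-level values with label-shuffle nulls); group-level mixed models
are out of scope — the correction machinery is the deliverable.

## Problem sizes

The test suite and `scripts/acceptance.py` run on simulated recordings of
5–60 minutes: slope recovery uses 10-minute event-free simulations (10
seeds × β ∈ {1, 1.5, 2}); detector recovery uses 10-minute recordings (10
seeds); coupling recovery uses one 60-minute recording (~260 coupled
spindles) plus 100 8-minute simulations for null calibration; the
cluster-permutation error rate uses 200 null datasets of 24 subjects × 12
frequency bins at 500 permutations. These sizes give stable estimates for
every tolerance asserted while keeping a full run in the minutes range.
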