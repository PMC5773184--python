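# Methods

## The system and the question

The leech heartbeat system is a strictly feedforward rhythmic motor
system: a central pattern generator (CPG) of paired heart interneurons
(HN) drives segmental heart motor neurons (HE), which drive the two
heart tubes. At any moment one body side beats peristaltically
(rear-to-front phase progression, large intersegmental phase difference
Δϕ) while the other beats near-synchronously (Δϕ close to zero), and the
two sides swap coordinations simultaneously every 15–60 beat cycles.
`phasevar` decomposes the variability of Δϕ — the critical output
variable of the motor program — into four sources and asks how each
compares across network levels (CPG pattern, motor pattern, heart-beat
pattern):

1. **cycle-to-cycle** — dispersion of Δϕ across beats within one
   coordination episode (biophysical noise);
2. **repetition** — differences between two repetitions of the same
   coordination by the same neurons minutes apart;
3. **bilateral** — differences between genetically identical left/right
   homologs performing the same coordination;
4. **population** — differences between animals.

## Phase extraction

Spike trains are grouped into bursts wherever consecutive spikes are
separated by at least the interburst-interval threshold (default 1 s);
groups with fewer than `min_spikes` (default 3) spikes are discarded as
stray spikes. The phase marker of a burst is its middle spike by count
(for an even count, the earlier of the two central spikes — a
deterministic choice biased by less than half an interspike interval).
The cycle period `T_r` runs from middle spike to middle spike of the
reference (front-segment) channel, and the phase of a target event is

    ϕ = (t_i − t_r) / T_r  (mod 1).

Each reference cycle is the half-open interval `[t_r, t_r + T_r)`, so
every instant belongs to exactly one cycle; cycles containing zero or
two target markers are flagged and skipped rather than guessed at. Δϕ
is reported in the centered convention `(−0.5, 0.5]` so small leads keep
their sign; all arithmetic is circular underneath.

For constriction signals the per-beat marker is the maximum rate of
rise (MRR) of the smoothed signal (moving average, default 5 samples).
Derivative peaks are refined by the centroid of the derivative's
half-height lobe, which is exact for a symmetric rise and suppresses
sampling noise far better than an argmax; with the default generator
settings (50 Hz, SNR 200) markers are recovered within one sample.

## Coordination segmentation

The analyzed channels do not include the switch interneurons that define
the coordination state physiologically, so the state is inferred from
Δϕ itself. The default rule is relative: at each cycle the side with
the larger |Δϕ| is peristaltic, the other synchronous. This needs no
tuning and tolerates the large animal-to-animal spread of the
peristaltic mean; an absolute threshold rule (side is peristaltic when
its |Δϕ| exceeds a configured value) is available where a calibrated
threshold is preferable. A state change is accepted only when sustained
for `hysteresis` (default 3) cycles, so single-cycle excursions never
register as switches. The confirming cycles after an accepted switch,
and the last cycle before it (whose target marker a slight lead can
drag across the boundary), are marked transitional and excluded from
all statistics. Consecutive episodes pair into switch cycles
(non-overlapping, from the first episode), mirroring the convention
that five observed switches yield two complete switch cycles.

## Circular statistics

A phase sample is summarized by vector summation: each phase maps to a
unit vector at angle 2πϕ; the mean vector's direction is the mean phase
and its length `r ∈ [0, 1]` the concentration. The angular variance is
`s² = 2(1 − r)` in radians squared, converted to phase units squared by
dividing by 4π² (and the angular SD by 2π). Per-recording period
variability is the coefficient of variation of the middle-spike periods
(sample SD, n − 1 denominator).

Group comparisons of mean Δϕ use t-tests on phases unwrapped around the
pooled circular mean; at the dispersions this system exhibits (s ≲ 0.1
cycles) the linearization is exact for practical purposes, and it
removes wrap artifacts when phases straddle zero.

## Variance decomposition and inference

Per episode, the per-cycle Δϕ give the cycle-to-cycle angular variance
(episodes shorter than 7 cycles are excluded). The per-animal summary
entering all higher levels is the circular mean Δϕ of one episode (one
coordination within one switch cycle).

* **Population variance**: angular variance of per-animal means (one
  side, switch cycle 1), with a bootstrap confidence interval. The
  default interval is studentized (bootstrap-t with a linearized
  standard error: the angular variance is to first order the mean of the
  per-observation contributions `2(1 − cos(θ_i − θ̄))`). Percentile
  intervals are available, but for variance-type statistics at n ≈ 25
  they are known to undercover substantially (here ~85% at nominal
  95%), while the studentized interval holds ~94%.
* **Repetition variance**: angular variance of per-animal ΔΔϕ between
  switch cycles 1 and 2.
* **Bilateral variance**: angular variance of per-animal left−right ΔΔϕ
  within a coordination.
* **Scrambling tests**: the observed ΔΔϕ variance is compared with the
  variance distribution obtained by re-pairing the two members across
  different animals, 10,000 times. The default matching is
  fixed-point-free (a random permutation composed with a nonzero cyclic
  shift), so each animal is paired with a different animal and every
  partner is used once per iteration; this makes the reported z-score
  p-value (one-sided toward "observed smaller", from a normal fit to
  the scrambled distribution) well calibrated (type I ≈ 0.05 at n = 24).
  Independent per-animal re-pairing is available and is conservative
  (type I ≈ 0.02–0.03). Two-sided p-values are also reported.
* **Component estimates** (`estimate_variance_components`): method of
  moments. The cycle component is the mean within-episode variance; the
  repetition component the ΔΔϕ variance between switch cycles; the
  bilateral component the side-ΔΔϕ variance *minus* the repetition
  estimate (the two sides' episodes carry independent repetition
  draws); the population component the variance of per-animal means.
  Finite-cycle noise of the episode means (cycle variance / n cycles)
  is subtracted where it enters. Estimates are clipped at zero.
* **Outlier screen**: per-stratum Tukey fences (1.5 × IQR beyond the
  quartiles); flagged animals are excluded with a logged justification.
* No multiple-testing correction is applied; all p-values are raw.

## Synaptic strength

Unitary IPSC amplitudes are estimated by spike-triggered averaging of
the voltage-clamp current: segments aligned on presynaptic spike times,
each baseline-corrected by its pre-trigger mean (default 50 ms), are
averaged, and the peak is the signed extremum within the post-trigger
window (default 200 ms). Estimates from fewer than 10 presynaptic
bursts are refused unless overridden. Peaks convert to conductances by
the driving force, `g = I/(V_hold − E_rev)` with `E_rev = −62 mV`; the
stated ±5 mV holding accuracy propagates to an uncertainty band (the
band is open-ended if it includes a zero driving force). The per-side
proportional strength `g_front/(g_front + g_middle)` cancels
clamp-quality scale factors exactly; the two sides are compared by a
paired t-test, alongside the mean paired-t p-value over 10,000
side-scrambled pairings.

## Synthetic data generator

The generator is the test bed: it emits bilateral pairs of front/rear
bursting channels at two levels (interneuron-like and motor-like),
constriction-like traces, and clamp traces, with every quantity the
analysis estimates recorded as ground truth.

Per-cycle phase differences are hierarchical wrapped-normal draws:
coordination target μ(level, coordination) + animal offset + side
offset + per-episode (repetition) offset + per-cycle noise. The config's
variance components are specified as the *angular* variances the
pipeline's estimators measure; underlying normal variances are obtained
by inverting the wrapped-normal relation `r = exp(−σ²/2)` (i.e.
`σ² = −2 ln(1 − s²/2)`), with the repetition/bilateral components
calibrated through the ΔΔϕ statistics they feed (`u_R = g⁻¹(t_rep)/2`,
`u_S = [g⁻¹(t_bil + t_rep) − g⁻¹(t_rep)]/2`,
`u_A = g⁻¹(t_pop) − u_S − u_R`). This makes parameter recovery unbiased
in expectation; it also imposes the consistency constraint
`var_population ≳ (var_bilateral + var_repetition)/2`, violations of
which are rejected with a diagnostic, as are dispersions too large for
unimodal wrapped-normal sampling (s² ≥ 2 rad²).

Defaults are the study conditions: period 8 s with CV 3% (periods are
drawn independently per cycle — real recordings may have period
autocorrelation, which is deliberately not modeled and configurable
only through the code); episodes 15–60 cycles; two complete switch
cycles per side with exactly simultaneous switches; peristaltic means
0.23 (CPG), 0.13 (motor), 0.21 (beat) and synchronous means 0.02;
variance components (×10⁻³ phase²) population 3.8/2.0, bilateral
5.1/2.1, repetition 1.5/0.8 for CPG/motor, cycle-to-cycle 1.0. Bursts
have 9 spikes placed symmetrically around the middle spike at uniform
intervals, so middle-spike recovery is exact; rear bursts realize the
target phase against the front channel's actual middle-spike grid, so
noise-free analysis recovers the truth to numerical precision.

What the generator does *not* emulate: spike-detection errors (inputs
are spike times by construction), period autocorrelation, gradual
transitions at switches (switches are instantaneous), level-to-level
coupling of the variance components (levels draw independently), and
any load- or temperature-dependence of the beat. Passing tests
therefore demonstrate correctness of the estimators under the assumed
hierarchical model, not robustness to these unmodeled features.

A realism consequence worth knowing: with a synchronous mean of 0.02,
per-cycle noise occasionally places a rear burst just before its
reference marker. The half-open cycle rule then assigns it to the
previous cycle (where it measures as the same point on the circle); at
a sign flip this produces a flagged cycle with zero or two markers,
which is dropped. Synchronous strata therefore lose a fraction of
cycles and their retained means are slightly reweighted toward the
majority sign — visible in synchronous summaries at small n, absent in
peristaltic strata.

## Numerical and reproducibility choices

All randomness (generation, bootstrap, scrambling) flows from a single
seed through named `SeedSequence` substreams, so every table is
independently reproducible and two runs with the same config are
byte-identical. Raw spike/trace files are written at 17 significant
digits (lossless float round-trip); report tables at 12. Degenerate
inputs are handled explicitly: identical phases give r = 1 within one
ulp and zero variance; a zero-spread scrambling null reports p = 0.5
when the observed value coincides with it; identical paired samples
give t = 0, p = 1.

## Problem sizes in the validation suite

The test suite validates the oracle equivalence on 10,000 random
samples; parameter recovery on 20 replicate populations of 100 animals
(tolerance 20% on the Monte-Carlo mean — per-seed variance-estimate
noise at n = 100 is ~14% RMS, so per-seed bounds would measure noise,
not bias); scrambling calibration on 1,000 replicates at n = 24 animals
with 1,000 scrambles; bootstrap coverage on 500 replicates at n = 25
animals with 2,000 resamples. These sizes were chosen so each check is
statistically decisive for the property it tests.
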