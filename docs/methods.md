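# Methods

This note documents the models, numerical choices and limitations behind
`circalum`. It covers the synthetic-data generator, the preprocessing chain,
period and phase estimation, circular statistics, the qPCR branch, and the
pipeline-level statistics.

## The recording model and the synthetic generator

A recording is six days of per-well luminescence at 30-min cadence: three
days under a dual 12:12 light-dark / cold-warm entraining cycle, then three
days of constant darkness and temperature (free run). Recording starts at
ZT12 (lights-off / warm-phase onset is mid-cycle; ZT0 is lights-on and cold
onset). Under constant conditions phases are circadian time (CT), inheriting
the last entrained phase at release.

The generator (`circalum.synth`) emulates this design with an additive
signal model per well:

    y(t) = env(t) · (mesor + amplitude · cos θ(t)) + ε(t),   ε ~ N(0, σ²)

- `env(t)` is a linear luciferase-accumulation ramp saturating at
  `transient_hours` (default 12 h) times an exponential decay
  `exp(−damping_rate · t)` (default 0.01 h⁻¹, i.e. the signal halves in
  ~3 days). Both the baseline and the oscillation are scaled by the
  envelope, as substrate depletion and population aging dim the whole
  signal, not just its mean.
- `θ(t)` advances at the entrained period (24 h) before release and at the
  genotype's free-running period τ afterwards, continuously at the switch.
  A `phase_offset_at_release` parameter (default 0) can emulate the phase
  jumps seen when entrainment is partly masking.
- The entrained acrophase defaults to ZT18 (nocturnal/warm-phase peak);
  mesor 5 and amplitude 2 in arbitrary luminescence units with σ = 0.3 give
  a per-sample signal-to-noise typical of population recordings.
- Each well is rhythmic with probability `fraction_rhythmic` (default 0.5);
  arrhythmic wells keep the same envelope and noise with zero amplitude.
  With these defaults roughly half the wells end up classified rhythmic,
  matching the 44-51 % rhythmic-population rates typical of this assay.
- Per-well random streams are spawned from the plate seed via numpy
  `SeedSequence(entropy=seed, spawn_key=(well_index,))`: wells are
  independent but the plate is bit-reproducible from one integer.

The generator does **not** model luciferase enzyme kinetics, temperature
compensation, inter-well crosstalk, or non-Gaussian noise. Passing tests on
synthetic plates therefore demonstrates correctness of the estimation chain
under the stated signal model, not robustness to every artifact of real
luminometer data.

The qPCR generator plants a known relative-expression profile under the
perfect-doubling model: target Ct = reference Ct + offset − log2(relative
expression) + noise (default 0.25 cycles, 4 replicates), sampled every 4 h
from ZT1 over one entrained plus two free-running days.

## Preprocessing

Chain order: background subtraction → transient trimming → detrend →
smooth → normalize (the order in which these steps are conventionally named
for this assay; whether normalization preceded detrending in the original
workflow is not determinable, so the named order is used).

- **Background** is a single scalar per plate (luminometer dark counts);
  negative values after subtraction are permitted.
- **Trimming** removes the first 12-24 h (default 24 h) of luciferase
  accumulation. Absolute times are preserved so ZT mapping survives.
  Trimming that would leave under two full days is an error, since period
  estimation needs at least two cycles.
- **Detrend** subtracts a centered moving average (default window 24 h);
  **smooth** is a centered moving average (default 2 h). Windows are defined
  over *time*, not sample counts, so gaps are tolerated; samples exactly on
  a window edge take half weight, which keeps the filter symmetric (exact
  for linear trends) when the window spans an even number of sampling
  intervals. Edges average over the available part of the window.
- **Normalization** divides by the maximum over the first 24 h after
  trimming ("initial maximum"); a window with no positive signal flags a
  dead well.

A centered moving average near a record edge is effectively one-sided: the
subtracted trend acquires a phase shift there, which distorts the residual
oscillation over half a window at each edge. The same happens where the
window straddles the entrained→free-run transition, since the two segments
oscillate at different frequencies. The pipeline therefore excludes half a
detrend window (12 h by default, `RunConfig.edge_exclude`) at the trace ends
and after the release from the *period fits*; without this exclusion the
fitted free-running period of a τ = 27.1 h well is biased by ~0.5 h. Peak
phases still use the full segment, because the first post-release peak - the
quantity plotted in Rayleigh figures - can fall inside the excluded zone and
argmax peak location is far less sensitive to the edge response than a
free-period fit.

## Period and phase estimation

- **Lomb-Scargle**: the classical variance-normalized Scargle form with the
  per-frequency time offset (phase-invariant), computed on mean-centered
  values; power is invariant under affine value transforms and time
  translation. The frequency grid runs from 1/37 to 1/18 h⁻¹ with step
  1/(oversampling × span), oversampling 30, inclusive of both period
  bounds. The numerical kernel is `scipy.signal.lombscargle`; tests verify
  equality with an independently coded DFT periodogram on evenly sampled
  records.
- **Cosinor**: `y = M + A·cos(2π(t − φ)/τ)`. For fixed τ the fit is linear
  in `(M, A cos, A sin)` and solved in closed form; A is reported ≥ 0 with φ
  adjusted, and φ is mapped to ZT/CT hours mod 24 via the recording's
  `zt_offset`. For free τ the closed-form solution is profiled over the
  Lomb-Scargle period grid and the best grid point refined by bounded 1-D
  minimization of the SSE profile between its neighbors (tolerance 1e-7 h).
  This avoids the initialization fragility of a joint nonlinear fit; tests
  confirm the profile fit matches an exhaustive (τ, φ) grid-search oracle
  and, at fixed τ, an iterative least-squares solver to 1e-8 in SSE.
  R² = 1 − SS_res/SS_tot; constant traces are an error.
- **Classification**: entrained traces are *Synchronized* when
  |τ − 24| ≤ 1 h (the "24 h period" rule needs a tolerance because sampling
  and grid resolution make exactly 24.00 unattainable; 1 h is
  config-exposed) and R² ≥ 0.5; free-running traces are *Circadian* when
  18 ≤ τ ≤ 37 and R² ≥ 0.5. All bounds inclusive.
- **Peak phases**: per 24 h cycle, the time of the maximum of the
  (smoothed) trace, mod 24 in ZT/CT; free-run summaries use only the first
  post-release peak, matching how Rayleigh plots of release experiments are
  drawn. Free-τ fits are used for both conditions.
- **Percent rhythmic** returns the exact percentage; the `decimals`
  argument reproduces printed roundings (whole percent or one decimal).
  Both tallies - rhythmic among all wells and synchronized among rhythmic -
  can be formed from the results table.

## Circular statistics

Phases (hours mod 24) map to angles by θ = 2πφ/24. A sample is summarized
by the circular mean direction, the resultant length R = |mean unit
vector|, and the Rayleigh uniformity test in Zar's approximation

    p ≈ exp( √(1 + 4n + 4(n² − (nR)²)) − (1 + 2n) ),

accurate to about three decimals for n ≥ 10 (a seeded Monte-Carlo
permutation variant exists for small n). At n = 14 the test's measured
type-I rate at α = 0.05 is 0.046 (10,000 uniform draws). The circular
standard error follows the dispersion convention
σ = √((1 − ρ̂₂)/(2nR²)) radians, with ρ̂₂ the second cosine moment about the
mean direction, converted to hours; a linear mean ± SEM after centering on
the circular mean is also available, since published phase summaries often
use the linear convention. Summaries with R < 0.3 are flagged `dispersed`:
a mean direction is still reported but is poorly determined.

## qPCR: 2^-ddCt and JTK_CYCLE

Replicate Cts are averaged per (timepoint, gene); ΔCt = Ct_target −
Ct_reference, ΔΔCt is taken against a calibrator timepoint (default the
earliest), and fold change = 2^−ΔΔCt, exactly 1 at the calibrator.
Per-replicate fold changes (replicate target Ct vs mean reference Ct) give
SEMs. No amplification-efficiency correction beyond perfect doubling is
applied.

JTK_CYCLE: for each candidate period (default {20, 24, 28} h for 4-h
sampling) and each phase lag on the sampling grid, the series is compared
with a cosine reference by Kendall's τ-b. The two-sided p-value of
Kendall's S uses the exact null distribution - full enumeration of all n!
arrangements, vectorized and cached by the template's tie-group structure -
for n ≤ 10 untied series, and a normal approximation with continuity
correction and tie-corrected variance beyond (typical series here have
12-18 timepoints). Family-wise control is Bonferroni over the whole
period × lag grid, capped at 1; the reported best combination minimizes the
adjusted p, ties broken by the strongest positive correlation. Replicates
are averaged per timepoint before ranking (medians optional). Constant
series return p = 1 with τ undefined and a flag. Entrained-day and
free-run-day samples are analyzed jointly by default; the series can be
sliced for separate analyses.

## Pipeline statistics and determinism

Free-running periods of *Circadian* wells are compared between strains with
a two-sided Welch t-test (reported by default; the pooled-variance test is
emitted alongside for transparency) plus a Shapiro-Wilk normality check on
the pooled residuals; paired entrained-vs-free-run comparisons check
normality of the paired differences. With more than two groups a Sidak
adjustment is added. Identical groups are reported as t = 0, p = 1.

Every run is deterministic given inputs and config: results tables are
byte-identical across reruns, the manifest embeds a config hash and seeds,
and each well lands in exactly one of the results table, the dead-well log,
or the error log.

## Problem sizes used in the checks

The end-to-end recovery check uses 100 plate replicates of 30 control
(τ = 24.2 h) + 30 mutant (τ = 27.1 h) wells; pooled over replicates, the
mean estimated free-running period per genotype is required to sit within
0.3 h of truth, and the Welch comparison must be significant with the
correct sign in ≥ 95 % of plates. JTK_CYCLE calibration uses 1000 null
series and 200 planted-rhythm replicates (2-fold amplitude, 0.25-cycle Ct
noise, 4 replicates). The acceptance script simulates one study-scale plate
(45 control + 71 mutant wells).

## Known limitations

- Moving-average detrending is the only detrending offered (window
  config-exposed); no spline or polynomial variants, no outlier-well
  auto-rejection.
- The Lomb-Scargle false-alarm probability is not computed: rhythmicity is
  gated on cosinor R², not on periodogram significance.
- Cosinor assumes a single stationary sinusoid per segment; damping is
  handled only through the edge-aware fitting described above, and residual
  amplitude decay can bias free-period estimates by ~0.1-0.2 h at the
  default damping.
- JTK_CYCLE's exact null is limited to n ≤ 10 (enumeration); beyond that
  the normal approximation is used, which is slightly conservative with
  heavy template ties.
- No multi-group circular tests (Watson-Williams etc.); Rayleigh summaries
  with low R are flagged rather than suppressed.
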