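# Methods

This note documents the models, conventions and numerical choices behind
somnoscore, and what the synthetic-data generator does and does not emulate.

## Time base and scoring conventions

All analysis is indexed in Zeitgeber time (ZT, hours since light onset;
12:12 light/dark cycle assumed, lights off at ZT12). Recordings are assumed
to start at ZT0 unless a `start_zt` is given; the EDF wall clock is never
used for alignment. The scoring epoch (default 10 s) is the atomic unit:
dosing times that fall mid-epoch snap forward to the next epoch boundary,
and every duration is an integer number of epochs, so the four state
durations in a bin sum to the bin length exactly.

Metric definitions:

- **Bout** — maximal run of consecutive same-label epochs. Any other label,
  artifact included, terminates a run. An opt-in `arousal_tolerant_bouts`
  rule lets a qualifying brief arousal be absorbed into the surrounding NREM
  bout for bout statistics; it is off by default so that bout segmentation
  stays a pure run-length operation.
- **Sleep latency** — minutes from the (snapped) reference time to the start
  of the first bout of the state with at least the state minimum (NREM
  ≥ 30 s, REM ≥ 20 s) *and* whose start is at or after the reference.
  If no bout qualifies, the remaining recording length is returned with a
  censored flag; censored values are never imputed, and downstream statistics
  must choose explicitly to exclude or cap them.
- **Brief arousal** — a maximal wake run of 20–30 s (inclusive at both ends,
  i.e. 2–3 epochs) whose immediately flanking epochs on both sides are NREM.
  Runs at the recording edge never qualify.
- An epoch contributes to the time bin containing its start.

## Spectral estimation

Per scoring epoch, Welch's method: Hamming-windowed segments with 50 %
overlap, density scaling (the integral over frequency estimates the signal
variance), averaged within the epoch. The default segment length is 4 s
(0.25 Hz native resolution). Rationale: the native grid must resolve the
0.5 Hz lower band edge, and with a 0.25-Hz grid an on-grid tone's Hamming
leakage (confined to ±1 native bin for exact-bin tones) stays inside a
single 1-Hz output bin; a 2-s segment would put that leakage exactly on an
output-bin boundary. Segment length, overlap and window are configurable
(`SpectralConfig`).

Output bins: 1-Hz bins whose bin *k* covers [k − 0.5, k + 0.5) Hz, tiling
0.5–100.5 Hz with the last bin truncated at 100 Hz (so the analysis span is
exactly 0.5–100 Hz and the last bin is half-width). Native Welch bins are
integrated (power × df) into output bins by their frequency.

Relative power divides each bin by the epoch's 0.5–100 Hz total; band power
sums bins weighted by the fractional overlap of the bin with the band
interval. Overlap weighting (rather than bin-center membership) is used
because the conventional band edges (4, 8, 12, 16, 24, 30, 50 Hz) bisect the
output bins: with overlap weights the bands partition the spectrum without
double counting, a uniform per-Hz spectrum yields band fraction =
band width / 99.5, and the unbanded 24–30 Hz remainder reconciles totals
to 1.

Two known discretization properties, quantified by the test suite:

- the half-bin split at a band edge allocates a sharp density step by area,
  not by the true within-bin distribution, so a step of height Δd biases the
  adjacent band fractions by up to Δd/4 per edge (≈ 0.04 for a delta-dominant
  NREM spectrum). This is a property of any 1-Hz binning whose bins straddle
  the band edges, and it cancels between conditions compared on the same
  pipeline;
- at 200 white-noise epochs, each bin's mean power has ≈ 2 % sampling error,
  so flatness is asserted as the RMS relative deviation across bins (≤ 5 %),
  not the maximum over 100 bins (which is ≈ 6 % by chance at that n).

Epochs containing non-finite samples are marked missing (NaN rows) and
excluded downstream; zero-total epochs propagate as missing, never as zeros.
No artifact rejection or line-noise filtering is applied beyond label-based
exclusion — scored artifact epochs are excluded from all qEEG averages.

Baseline normalization computes, per subject × state × band, the
epoch-weighted mean over bins wholly inside the baseline window (ZT0–2 by
default; ZT0–1 for designs dosing at ZT1) and reports
100 × (value − baseline)/baseline. Per-subject percent change is computed
before any group averaging.

## Statistics

- **Paired t** — standard two-sided test on differences, df = n − 1;
  zero-variance differences are an error, not t = ∞.
- **Simple linear regression** — OLS with R² = 1 − SSE/SST and
  F = (n − 2)·R²/(1 − R²) on (1, n − 2) df (identity asserted to 1e-10
  relative in tests). R² = 1 reports p = 0 with a perfect-fit flag; constant
  x is an error.
- **One-way RM-ANOVA** — classical two-way decomposition
  F = MS_condition / MS_(subject × condition) on complete cases, with the
  Greenhouse–Geisser ε from the double-centered condition covariance;
  corrected df = ε·df, ε ∈ [1/(k − 1), 1] and exactly 1 at k = 2 (where
  F = t² of the paired t). Commercial packages fit these designs as
  mixed-effects models with REML; this module deliberately implements the
  closed-form classical analogue, which is testable against its defining
  formulas, and does not claim numeric identity with mixed-model output on
  unbalanced data.
- **Dunnett many-to-one** — paired t statistics of each condition against
  the control over pairwise-complete subjects. The family-wise adjustment is
  the Monte Carlo tail probability of the maximum absolute statistic under a
  parametric bootstrap: difference-score matrices are drawn from a
  multivariate normal at the correlation estimated from the observed
  difference scores (PSD-projected if pairwise estimation broke positivity),
  and the t-vector is recomputed per replicate so variance estimation is part
  of the null. Default 10⁵ replicates with a fixed, recorded seed. The
  bootstrap was chosen over a plug-in multivariate-t because the latter
  measured slightly liberal family-wise error in null calibration runs;
  the bootstrap measures ≈ 0.046–0.061 at nominal 0.05 (n = 12, k = 4).
  Adjusted p is clamped to ≥ raw p, making monotonicity exact.

Significance is two-sided at a configurable threshold (0.05 by default).

## The sleep simulator

A semi-Markov chain over {WAKE, NREM, REM}: bout durations are exponential
with state- and phase-specific means, rounded to whole epochs (minimum one);
transitions follow a propensity matrix in which REM is enterable only from
NREM; the initial state is drawn from the analytic stationary occupancy
(π_i μ_i, with π the embedded-chain stationary distribution), which makes
the process stationary from the first epoch because exponential residuals
are exponential. Circadian structure is a two-phase (light/dark) parameter
switch, matching designs that only distinguish the two phases; a bout uses
the parameters in force at its start.

Defaults (configuration, not claims about any dataset — chosen once as
literature-typical for adult rats):

| parameter | light | dark |
|---|---|---|
| wake mean bout | 150 s | 480 s |
| NREM mean bout | 200 s | 150 s |
| REM mean bout | 90 s | 60 s |

with propensities WAKE→NREM 1.0; NREM→WAKE 0.7, NREM→REM 0.3; REM→WAKE 0.4,
REM→NREM 0.6, giving light-phase occupancy ≈ 35 % wake / 57 % NREM / 8 % REM
and dark-phase ≈ 70 / 27 / 3. Artifact epochs are overlaid independently at
rate 0.002 (clean telemetry; higher rates fragment observed bouts and bias
the run-length bout-duration estimate low, which is a real property of
artifact-rich recordings, not of the estimator).

**Interventions** are time-windowed multiplicative effects: a multiplier on
transitions into WAKE (rows renormalized), multipliers on wake/NREM/REM bout
means, and a forced-wake latency delay (exponentially drawn mean, in
minutes) starting at onset. `wake_mean_mult` extends the minimal multiplier
set because a one-sided forced delay alone cannot express both an
opioid-like latency *increase* and a hypnotic-like latency *decrease*.
Every dosing event additionally carries a handling arousal (forced wake,
mean 12 min, applied to vehicle arms too): injections wake the animal, and
without this the simulated vehicle latency is unrealistically near zero.
Sedative or arousing effects active at the dosing time scale the drawn delay
through their wake-bout multiplier. Shipped presets:
`lactic_acid_5p6` (transient 1.5-h wake promotion with NREM/REM
suppression), `morphine` (4-h NREM/REM suppression, long latency delay),
`at403` (6-h NREM promotion, REM suppression, shortened waking bouts),
`meloxicam_null` (no effect).

**Surrogate EEG** shapes per-epoch Gaussian noise in the frequency domain to
a per-state template: stated band fractions are rendered as flat density
within each band, and the remainder as a 1/f^α continuum over the
unspecified part of the span, so the stated fractions are the actual band
fractions of the synthesized spectrum. The density is continued 1 Hz past
the 0.5/100 Hz span edges at the edge value so spectral-estimation leakage
across the span boundary is balanced rather than one-sided. Contiguous
epochs are cross-faded over 0.1 s to avoid splice artifacts. The surrogate
is spectrally realistic only in the band-fraction sense: it contains no
spindle/K-complex morphology, no amplitude nonstationarity within a state,
and no EMG, so passing round-trip tests demonstrates correctness of the
spectral pipeline, not fidelity to biological EEG waveforms.

**Cohorts** are within-subject crossovers with cyclic Latin-square condition
order (error if conditions exceed subjects), ≥ 3-day washout, and Poisson
behavior counts (stretching/rearing/grooming per 30-min window) whose
log-rates are linear in the noxious-stimulus concentration. A per-animal-
session severity latent (Normal, scaled by concentration) raises the
stretching rate and, through the wake-propensity multiplier, lowers NREM
sleep — the minimal structure that makes the within-condition
stretching × NREM regression meaningful. `severity_coupling_for_target_r2`
scans a common coupling scale to hit a target population R² (the fitted R²
is monotone in the scale). All randomness flows from one seed; per-(subject,
session) streams are derived child streams, so cohorts are reproducible
subject by subject.

## What passing tests do and do not show

The simulator draws bout durations from the same family (exponential) that
the run-length metrics implicitly measure, and the surrogate EEG is exactly
the stationary Gaussian process the Welch estimator assumes. Green tests
therefore demonstrate internal correctness (definitions, conservation laws,
estimator calibration, statistical error rates) — not that the pipeline's
numbers on real recordings are unbiased, since real sleep has heavy-tailed
bout distributions, within-state spectral drift, and scorer-dependent
artifact labelling that the generator deliberately omits.

## Problem sizes used in the checked examples

Brute-force agreement uses 1,000 random 500-epoch hypnograms; spectral
calibration uses 200 white-noise epochs; parameter recovery uses 200
simulated animals × 12 light-phase hours; drug-effect orderings use n = 15
paired arms × 9 h; the Dunnett null study uses 1,000 simulated 12 × 4
designs with 10⁴ Monte Carlo replicates each (the API default is 10⁵).
These sizes keep the default suite fast while leaving each check's sampling
error well inside its assertion margin.
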