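# Methods

This note documents the models and procedures `cubescreen` implements, the
choices made where the underlying instrument description leaves the design
open, and what the synthetic data do and do not establish.

## Signal model and feature extraction

A cube reports a uniformly sampled, gravity-free acceleration magnitude
(m/s², default 50 Hz; the rate is stored per stream and never assumed
downstream). Instantaneous speed is the trapezoidal integral of acceleration
over time, in m/s.

**Movements.** A movement is a maximal run in which the integrated speed is at
least `speed_threshold` (default 0.02 m/s, configurable). Because a magnitude
signal can never integrate back to zero, the integrator restarts whenever
|acceleration| falls below a rest threshold (0.05 m/s²): physically, the cube
has stopped. Signed traces are also accepted — deceleration then reduces the
running speed directly — which makes the detector exact on analytically
constructed pulse inputs. An episode is extended backwards to the sample at
which the cube last left rest, so the entire burst is analysed, and episodes
shorter than 100 ms are rejected as single-sample noise. Speed within an
episode restarts at zero at the episode start; without the rest-reset,
integration drift would accumulate across a session.

**Shakings.** Within an episode, the acceleration segment is partitioned at
strict interior local minima into "mounds", each containing one peak. With
`s` the number of samples on the narrower flank of the peak inside its mound,
the mound is a shaking of level `min(s, 4)`; `s = 0` (peak on a mound
boundary, e.g. a monotone rise) is not a shaking. The level-4 class therefore
reads "four or more samples" as *per flank* (symmetric-minimum reading);
asymmetric mounds take the smaller side. Tie-breaking: the peak is the first
maximum of the piece; plateaus do not occur in the synthetic signals and are
measure-zero for continuous noise.

**Summary variables.** Each experiment reduces to: number of movements, mean
movement time (ms), mean of per-movement mean speeds ("mean of means"), and
the mean/highest/lowest of per-movement maximum speed and maximum
acceleration, plus the per-level mean shaking counts — 13 sensor variables —
and the mean expert rating (1–10) as the performance score. The "lowest
maximum speed/acceleration" variables are the minima of the per-movement
*maxima* (the operational reduction, not a minimum of minima). The time at
which maximum speed occurs is computed per movement but, like the raw
instrument, not summarized at experiment level.

## Synthetic sessions

The generator emulates the tower task: per cube, one or more movement bursts
separated by rest. A burst is a *rise-and-stop* profile: zero or more
symmetric tremor mounds (half-width 1–5 samples, local minima held well above
the rest threshold) followed by a strictly monotone rise to the burst peak,
after which the signal drops to rest in one sample — the placement impact.
This shape was chosen over a symmetric accelerate/decelerate pulse for two
reasons: a magnitude-only trace genuinely ends at the stop, and the terminal
rise contributes no countable mound (its peak has an empty right flank), so a
movement with zero injected tremor has exactly zero shakings. With noise
disabled (the default), ground-truth episode boundaries — last at-rest sample
before the burst, through the burst peak — and the injected shaking levels
are recovered *exactly* by the extractor; additive sensor noise is available
(`noise_sd`) but then exactness is no longer guaranteed, because local-minima
detection is deliberately unsmoothed, as in the instrument.

Latent profile → signal mapping: `trembling_rate` is the Poisson mean of
mounds per movement (movements with more tremor are also longer, reproducing
the empirical association between movement time and tremor);
`speed_scale` multiplies burst amplitudes; `accuracy_level ∈ [0,1]` lowers
the amplitude floor of the weakest movements and adds Poisson-distributed
fumbled movements beyond the ideal one per cube.

**Raters.** Ratings are true score + Gaussian rater noise with variance set
from the one-way ANOVA decomposition, `σ_w² = σ_b²(1−ρ)/ρ` for target
ICC(1,1) = ρ, clipped to [1,10] (a small accepted bias; Monte Carlo over 25
seeds recovers ρ = 0.8 within ±0.05 at n = 500).

**Cohorts.** The 13 standardized variables are generated as `Λ f + ψ½ e`
with independent standard-normal factors and noise; the default `Λ` is the
instrument's reference rotated loading pattern. Ages are truncated-normal on
the 23–37-month study band (mean 29.02, SD 3.81 months); the parent location
is shifted so the truncated mean equals the configured mean. Performance is
generated from the latent factors through the reference performance equation
with residual SD equal to its SEE by default, and left unclipped so that
generating coefficients remain recoverable by regression.

## Psychometrics

**ICC.** Each child is rated by a different randomly assigned pair of
experts, which mandates the one-way random model. From the one-way ANOVA,
`ICC(1,1) = (MSB−MSW)/(MSB+(k−1)MSW)` and `ICC(1,k) = (MSB−MSW)/MSB` (the
Spearman–Brown step-up of the former). Confidence intervals use the
F-quantile method: `F_L = F/F_{1−α/2}(df1, df2)`, `F_U = F·F_{1−α/2}(df2,
df1)`, pushed through the ICC formulas. The canonical residual df is
`n(k−1)`; because some packages print `(n−1)(k−1)` for this design, both
conventions are exposed (`ICCResults.conf_int(alt_df=True)`) and reported —
for n = 65, k = 2 the bounds differ only in the fourth decimal.

**Factor analysis.** Principal axis factoring with squared-multiple-
correlation initial communalities, iterated eigendecomposition of the reduced
correlation matrix, tolerance 1e−4 on the largest communality change, at most
100 iterations; non-convergence is flagged, not raised, and communalities
exceeding 1 (Heywood cases) are clipped and flagged. The number of factors is
fixed at 3 (no exploratory selection); rotation is varimax with Kaiser
normalization (SVD-based iteration, convergence 1e−12, so round-trip recovery
of a simple structure is accurate to <1e−6). Rotated factors are ordered by
explained variance and matched to the reference trembling/speed/accuracy
pattern by Tucker congruence, with signs fixed so the pattern-defining
loadings are positive.

**Factor scores.** Regression (Thurstone) scores `Z R⁻¹ Λ`, rescaled by
`diag(Λᵀ R⁻¹ Λ)^{−1/2}`. The rescaling makes the sample variance exactly 1 on
the estimation sample — consistent with the unit-SD predictors implied by the
reference regression coefficients — and is what allows the fixed screening
equations to consume scores from new cohorts. A singular correlation matrix
falls back to a ridge-adjusted inverse with a warning. Bartlett scoring is
not implemented; the choice is documented so results can be compared if it is
added.

**Regression.** OLS (via statsmodels) with an intercept; reported quantities
are the validation-table set: B, SE, standardized beta `B·sd(x)/sd(y)`,
t = B/SE with df `n−p−1`, two-sided p (uncorrected, to machine precision),
R, R², adjusted R², and the standard error of the estimate
`√(SSE/(n−p−1))` in response units. A constant response defines R² = 0 with
intercept = mean(y). Rank-deficient designs raise an error.

## Screening

The two fixed-coefficient equations are stored at full table precision
(0.050 for trembling in the performance model; 0.003 for speed in the age
model, where a lower-precision in-text variant, 0.03, also circulates — the
table value governs). Outputs are never clipped to the 1–10 scale: clipping
would silently hide extrapolation. Signs encode the validated directions:
higher accuracy → better performance, higher speed → worse performance.

The advisory rule defaults are repository choices, not instrument claims:
"monitor" when predicted performance < intercept − 1·SEE = 6.106, or when
observed age exceeds predicted age by more than 1·SEE = 3.637 months; both
thresholds are configurable (YAML for the CLI) and echoed into every result.
Factor scores entering the screening are standardized against the cohort
they were estimated on (pilot-cohort convention).

## What the synthetic data show — and what they do not

Passing tests establish internal correctness: exact ground-truth recovery of
the detector on noise-free signals, oracle equivalence against brute-force
scans, recovery of a known factor structure (Tucker congruence ≥ 0.95 at
n = 2000) and of known regression coefficients (within 3 SE in ≥95% of
replicates at n = 200), and the closed-form F↔ICC identities. They do not
establish clinical validity: the generator produces idealized rise-and-stop
bursts, Gaussian rater noise, and exactly linear factor structure; real
recordings contain gravity leakage, sensor quantization, multi-axis effects
and attempt-selection ambiguity that the pipeline does not model. The
inter-attempt gap rule (episodes separated by rest) stands in for the manual
first-attempt selection used with video.

## Problem sizes

Default verification sizes were chosen to make sampling error negligible
relative to each tolerance: cohorts of n = 2000 for structure recovery
(loading SE ≈ 0.01), n = 5000 for correlation convergence (entrywise
tolerance 0.05), 100 replicates of n = 200 for coefficient-recovery coverage,
250 random instances per oracle-equivalence family, and 24-child sessions for
the end-to-end determinism chain (enough for a well-conditioned 13-variable
correlation matrix).
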