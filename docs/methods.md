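# Methods

This note documents the models and procedures `gazecog` implements, the
choices made where the design was genuinely open, and what the synthetic
generator does and does not emulate.

## Task and scoring model

The task shows two side-by-side displays of coloured squares blinking on
(500 ms) and off (250 ms) for 10 s; one display changes one square's
colour after every blink. Gaze is coded into AOI labels {left, right,
away, missing} from either a 500 Hz eye-tracker export or 30 fps
hand-coded video. All measures are computed on **time-weighted half-open
intervals** `[t_i, t_{i+1})` rather than sample counts, which makes the
two cadences commensurable without resampling; a gap before the first
sample counts as missing, and the last sample extends to the 10 000 ms
trial end.

- **First-look classification.** The AOI governing t = 1000 ms (the first
  change onset) decides directly when on-screen. Away is treated like
  missing for the fallback — an away sample does not answer *which
  display* the infant is watching — so the scan walks forward to the
  first on-screen sample at t ≤ 2500 ms (inclusive); otherwise the trial
  is unclassified. Truncating the stream after 2500 ms can never change
  the outcome (tested).
- **Change preference** is on-display time on the changing side divided
  by on-display time on both sides, inside [1750, 6750) ms. Away/missing
  time is excluded from the denominator: the measure is a preference
  between the two displays. Trials with **more than** 75% of the full
  trial off-screen (away + missing) are excluded — the boundary is
  strict, 75.0% exactly is retained. A window-restricted variant of the
  away filter is available by config.
- **Shift rate** collapses the stream to its sequence of on-screen looks;
  intervening away/missing time neither breaks a run nor counts as
  looking. Rate = side-to-side switches ÷ seconds of on-display looking
  over the full trial.
- **LookingWindow1** is the share of early-window on-display time spent
  on the first-fixated display. The window is the first 750 ms,
  implemented as [0, 750) in 0-based trial time so that the window
  length is exactly 750 ms and worked arithmetic like 600/750 is exact.
- **Cohen's κ** = (p_o − p_e)/(1 − p_e) with chance agreement from
  marginal label frequencies (via scikit-learn); two identical constant
  codings (p_e = 1) are reported as perfect agreement.

The default analysis unit downstream is the participant × year ×
load-level (× first-look class) **cell mean**; trial-level analysis is
available by config flag.

## Exposure model

Device logs (10 s cadence, US AQI units, 3-day rounds up to six times per
household) pass three steps:

1. **Round QC** — a household-round is dropped iff its coverage
   (samples × median sampling interval) is below 5 h; the boundary is
   inclusive.
2. **Device plausibility** — readings outside configurable bounds
   (default [1, 750] AQI) are flagged; a device whose flagged share in a
   round exceeds 10% is retired from that round onward (forward-only:
   earlier rounds stand, since retirement in the field happens after the
   fact).
3. **Hourly downsampling** — arithmetic mean per household-hour, no
   imputation. This damps the very strong 10 s autocorrelation.

Hourly AQI is then modelled as

    aqi ~ intercept + f(hour, date) + b_household,

where `f` is a tensor-product spline — cubic B-spline margins with 11
basis dimensions each, **cyclic** on the hour margin (23:00 adjoins
00:00; diurnal continuity demands it) — penalized by second differences
per margin (P-spline construction), and `b` are household intercepts
shrunk by a ridge penalty, i.e. random effects in penalized-regression
form. Remaining serial dependence of consecutive within-round hours is
handled by AR(1) whitening at a fixed ρ = 0.6 (row_t − 0.6·row_{t−1};
gaps > 1 h break the chain). The three penalty weights are chosen by
generalized cross-validation on the whitened problem. Tensor columns are
mean-centered for identifiability against the intercept.

The **exposure score** is the centered household intercept: positive
means poorer air than the sample grand mean, in AQI units, so downstream
regression coefficients are per-AQI-unit. The grand mean (intercept +
mean household effect) is reported alongside; adding it to a score
recovers the health-band AQI scale. The estimator is translation-
equivariant (adding c to all readings moves only the grand mean) and, on
synthetic data, its scores correlate > 0.99 with the ledger offsets and
> 0.9 with naive per-household means; a test cross-checks the whole fit
against an mgcv GAMM with the same structure.

PM2.5 ↔ AQI conversion uses the EPA 24 h breakpoint table (2012 PM2.5
standard) with piecewise-linear interpolation; the two directions are
exact mutual inverses at every breakpoint, inputs above the table clamp
with a warning, and categories follow the published bands (≤ 50 good,
51–100 moderate, 101–150 unhealthy for sensitive groups, 151–200
unhealthy, 201–300 very unhealthy, above that hazardous).

## Association machinery

Mixed outcomes (change preference by first-look class, shift rate) are
fit with a **random-intercept linear mixed model implemented in
`gazecog.lmm`**: the marginal covariance of a grouped random intercept
has a closed-form inverse, so both ML and REML deviances profile to a
one-dimensional search over the variance ratio, making thousands of
simulation fits cheap. Estimates, standard errors and likelihoods match
statsmodels MixedLM to ~1e-5, and Satterthwaite denominator df — computed
from the gradient of the contrast variance and the curvature of the
restricted likelihood in (σ²_e, σ²_b), both by central differences —
match lmerTest to ~0.1%. When the variance ratio hits the zero boundary
or the curvature is numerically singular, the df falls back to the naive
residual df, capped at n − p.

Codings: Year and Age cohort −0.5/+0.5 (difference coding), SES centered
at the sample mean, load as a three-level factor with sum-to-zero
contrasts (columns Load1/Load2), exposure in centered AQI units
(unscaled, so per-unit coefficients are small numbers).

**Forward selection** starts from main effects and tests interaction
candidates in order (all two-way before three-way before four-way),
respecting marginality, by likelihood-ratio comparison of ML fits at
α = 0.05; the final model is refit by REML for reporting — conventional
practice, since REML likelihoods of models with different fixed effects
are not comparable. **Exposure augmentation** always adds the AQI main
effect and keeps Year × AQI iff it improves ML fit at α; the
baseline-vs-augmented LRT is recorded as the variance-explained check.

**Type-3 Wald χ²** per term is the quadratic form of the term's
coefficients against their covariance block — valid as a marginal test
under the centered/sum-to-zero codings above (it coincides with the
sequential test on balanced designs; tested). **Partial η²** is
χ²/(χ² + df_den) with df_den the term's Satterthwaite denominator df
(mean over its coefficients for multi-df terms), the residual df for
plain linear models. Singular covariance blocks are flagged, never
silently skipped; zero-variance regressors (e.g. an all-zero exposure
column) are dropped from the solve and reported with estimate 0 and
undefined SE.

Robustness analyses: each of the CP and shift-rate exposure models refit
with the other score as covariate (near-duplicate covariates are flagged
as collinear at |r| > 0.999), and a load-matched analysis restricted to
absolute load 2 — the year-1 'medium' and year-2 'low' level, identical
stimuli across years — reporting an F-type test of Year × AQI.
Assessment outcomes (Mullen composite in year 1; ASQ problem-solving,
fine motor, gross motor in year 2) are plain OLS: score ~ Age + SES,
then + AQI.

## Synthetic generator

Defaults are the study conditions: 215 households (one enrolled infant
per household; participant and household ids coincide), two cohorts (6
and 9 months at enrolment), 4 logging rounds of 3 days at 10 s cadence
(max 6), 36 trials in 6 blocks per session with loads {1,2,3} in year 1
and {2,4,6} in year 2 and balanced change sides, completion rates
averaging ~21 (year 1) and ~26 (year 2) trials, 30% of trials video-coded
at 30 fps, 13% sample missingness.

- **AQI series** = baseline 160 + annual cosine (amplitude 40, winter
  peak) + Gaussian diurnal bumps at the meal hours 07:00 and 18:00
  (amplitude 45, width 1.5 h) + household offset + AR(1) noise
  (φ = 0.9 at 10 s, marginal sd 20), clipped at zero. These levels put
  the simulated grand mean in the mid-180s AQI, matching the scale of
  heavily polluted rural north-Indian homes. Household offsets = fuel
  effect (cow dung +25 > wood +10 > LPG −20) + SES slope (−1.15/point) +
  N(0, 25²); fuel assignment depends on an SES median split so LPG
  concentrates in high-SES homes.
- **Gaze streams** come from a two-state semi-Markov look process: looks
  alternate between displays with exponential durations and occasional
  away periods; after the first change, discriminability
  g = sigmoid(capacity − load) shortens no-change looks (sameness
  detected, fixation released) and lengthens change-side looks. This
  reproduces the qualitative signatures — CP above chance within
  capacity, CP and shift rate falling with load — with few parameters.
  Latent processing speed is 0.63 shifts/s + β_shift × offset +
  N(0, 0.12); the CP exposure effect enters the discriminability logit,
  year-specifically (default: negative in year 1, zero in year 2).
- **Effect sizes**: β_shift = −7×10⁻⁴ shifts/s per AQI unit by default,
  chosen so that with offset sd 30 and ~200 participants the exposure
  term's partial η² is ≈ 0.02 — the magnitude such field studies report.
  Assessment scores carry a positive SES effect (0.8/point) and a zero
  exposure effect.
- **Reduced-form cell generators** (`generate_shift_cells`,
  `generate_cp_cells`) draw the same linear structure at the analysis-
  cell level directly, so replicate-heavy power/type-I simulations skip
  stream simulation.

What the generator does **not** emulate: per-trial look-duration
distributions are a modelling choice, not calibrated to any corpus;
missingness is i.i.d. per sample, so bursty tracker dropouts — and hence
realistic rates of first-look classification loss — are understated;
demographic structure beyond the qualitative fuel × SES × electricity
pattern is not reproduced. Passing recovery tests therefore show the
estimators are correct under the stated data-generating process, not
that real gaze or air-quality data meet its assumptions.

## Numerical choices and problem sizes

Timestamps are ISO-8601 in a fixed +05:30 zone (no DST). Seeding uses
`SeedSequence` with crc32-keyed sub-streams, so identical (config, seed)
give byte-identical outputs across processes. The GCV search runs
Nelder–Mead on log penalty weights from (1,1,1); the variance-ratio
search is bounded on log λ ∈ [−12, 12] with an explicit boundary check at
zero. Exposure-model failures (too few distinct dates/hours, singular
penalized systems) raise informative errors suggesting a smaller basis.

Test and acceptance runs use scaled problem sizes chosen as the smallest
that leave the checked properties comfortably identified: 25–100
households at 60–300 s logging cadence for exposure recovery, 500 random
trials for scorer/oracle equivalence, 200-participant cell tables with
200 power and 500 null replicates for the association operating
characteristics, and a 40-household full-chain run in the acceptance
script.

## Known limitations

- The exposure model's household SEs are plug-in penalized-regression
  approximations (no smoothing-parameter uncertainty).
- Satterthwaite df rely on numerical second derivatives; very small
  group counts (< ~10) can make them unstable, where the n − p cap
  applies.
- The mixed model supports a single random intercept grouping — the
  design used throughout — not crossed or nested random effects.
- No multiplicity correction across outcomes is applied, by design.
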