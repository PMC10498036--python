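# Methods

This note documents the models implemented in `metabehave`, the design of
the synthetic-data generator, the numerical choices that matter, and what
the test suite does and does not establish.

## Respirometry

The chamber is modelled as a single well-mixed compartment flushed at flow
rate FR (default 1600 ml min⁻¹, volume 12 l), so gas fractions relax
exponentially with time constant τ = V/FR = 7.5 min — consistent with a
chamber flush-out time of roughly 8 min.  Steady-state excurrent fractions
are obtained by inverting the rate equations; e.g. V̇O₂ = 9.108 ml min⁻¹ at
ambient FiO₂ = 0.2095 implies FeO₂ = 0.2050.

*Drift correction.* The ambient reference at time t is interpolated
linearly between the mean of the first baseline segment (anchored at the
segment's mid-time) and the mean of the second.  Because the animal-phase
readings pass through the same analyser, a linear drift cancels exactly in
the incurrent-minus-excurrent difference; only the second-order effect via
the (1 − FiO₂) denominator remains, well below 0.5% for realistic drift.

*Window selection.* Rates are averaged over a 5-min window, by default
minutes 13–18 of the animal trace.  "Stable" is operationalised as the peak
30-s rolling SD of both gas traces inside the window staying at or below a
threshold; the default threshold is 3× the median rolling SD of the trace,
a per-session, scale-free criterion (no absolute threshold is defensible
across analysers).  If the default window fails, the qualifying 5-min
window (1-s start grid) nearest the default start is used; if none
qualifies, the globally calmest window is used.  Both fallbacks are flagged
`shifted_window`.

*Numerical notes.* Gas quantities are fractions in (0, 1) internally;
percent-scale inputs are divided by 100 at I/O.  Computed rates that come
out slightly negative (within 1% of the oxygen delivered) are clipped to
zero with a warning; larger negatives raise.  The V̇O₂ equation is used
exactly as stated, without a CO₂ term in the denominator; rigs that scrub
CO₂ before the O₂ analyser motivate variants, which are out of scope.

*What the 20-min trace can and cannot give.* With τ = 7.5 min, a chamber
starting at ambient has only partially equilibrated by minute 13, so
absolute rates read from a 20-min trace are biased low by a known factor
(the window mean of e^(−t/τ)); between-individual comparisons are
unaffected because the factor is common.  The generator's round-trip
accuracy guarantees (0.1% noise-free) therefore apply to windows at least
five time constants into the animal phase, and the recovery tests use
longer simulated traces.  In the protocol being emulated the birds sit in
their chambers well before their measurement slot, so real traces start
much closer to steady state than the generator's conservative
cold-start default.

## Radial-arm-maze nulls

Errors are revisits: visits minus distinct arms.  The random null draws
arms uniformly *with replacement* — immediate returns allowed — until all
n arms are seen.  This is the coupon-collector process:
E[errors] = n·H_n − n (13.7429 for n = 8) and
Var[errors] = Σᵢ (1 − pᵢ)/pᵢ² ≈ 76.01, so a 10 000-iteration simulation has
SEM ≈ 0.087.  Forbidding immediate returns would drop the mean to about
10.2, far from published simulation values near 13.6, which is why the
with-replacement variant is the default.  The simulator samples the
geometric stage lengths of the process directly (an exact, vectorised
equivalence of arm-by-arm draws); the stereotypic simulator, by contrast,
walks its Markov chain arm by arm, so the two engines are independent code
paths that can be checked against each other (a uniform transition matrix
must reproduce the random null distributionally).

The stereotypic transition matrix pools consecutive visit pairs over all
trials and chicks, by default as an absolute 8×8 matrix ("where to next,
given the current arm"); a relative-offset mode (probabilities on
(next − current) mod n) is available.  Rows never observed fall back to
uniform rather than being pseudo-count-smoothed, keeping the chain
well-defined without inventing structure.  Start arms are uniform by
default, with the empirical first-visit distribution as an option.
Simulations are uncapped by default; `visit_cap` mimics truncated trials,
and an absorbing chain without a cap raises after 10⁴ steps.

Observed error counts are compared to a null with a one-sample, one-sided
t-test (alternative: observed mean below the simulated mean, the direction
that indicates memory use).  Zero-variance observations degenerate to an
exact comparison of means with p ∈ {0, 0.5, 1}.

## Repeatability

Repeatability is the intraclass correlation of a Gaussian random-intercept
model with no fixed predictors, fitted by REML.  The one-way likelihood is
profiled analytically: for a given variance ratio λ = σ²_A/σ²_E both μ and
σ²_E have closed forms, leaving a 1-D bounded search over log λ.  A fit
costs well under a millisecond, which is what makes 10⁴-replicate
parametric bootstraps routine.  On balanced designs the REML solution
coincides with the one-way ANOVA estimators (σ̂²_E = MSW,
σ̂²_A = (MSB − MSW)/k), and on unbalanced data it matches a general
mixed-model fitter to numerical precision; both facts are asserted in the
tests.

Significance uses a likelihood-ratio test of ML fits with and without the
random effect; because the null places σ²_A on the boundary, p-values come
from the 50:50 mixture of a point mass at zero and χ²₁.  The 95% CI is the
percentile interval of R over parametric-bootstrap refits (resimulate from
the fitted model on the observed design); bootstrap failures are counted
and warn above 5%.

Censored latencies (birds that never left the shelter) enter the ICC at
the 600 s cap — matching how such assays are scored — rather than being
treated as statistically censored; a log-transform option is provided and
used by the pipeline, since latencies are right-skewed and positive.  Note
that entering caps as values attenuates R slightly when censoring is
heavy; the censoring-aware treatment lives in the survival models, not in
the ICC.

## David's score

From the pooled winner–loser matrix, dyadic proportions are
P_ij = wins_ij/(wins_ij + wins_ji), with never-interacting dyads
contributing zero in both directions (no information is manufactured; the
convention is logged).  The sample-size-corrected dyadic index
D_ij = (wins_ij + 0.5)/(n_ij + 1) is available behind a flag and shrinks
small samples toward one half.  Scores are
DS = w + w₂ − l − l₂ (w row sums, w₂ = Pw, l column sums, l₂ = Pᵀl); they
sum to zero, negate under transposition of the win matrix, and recover the
latent order exactly on transitive tournaments.  Ties in DS are broken by
identifier order and flagged.  Trials are pooled by summing tallies before
scoring (per-trial scoring is available by calling the scorer on each
matrix).  Feeder-occupancy time is carried as a descriptive column only.

## Explanatory models and the ΔAIC rule

All model likelihoods are evaluated exactly, so AIC = 2k − 2·logL holds by
construction, and the selection rule is: the candidate replaces the
simpler model only when it undercuts the simpler model's AIC by at least
2.00 (the boundary counts as an improvement).

These fits are deliberately simplified maximum-likelihood stand-ins for
the mixed-effects machinery a full analysis would use, and every pipeline
report carries a deviations note saying so:

- **Counts** (maze errors): NB2 negative-binomial regression with log link
  (the conventional link for a count model); the dispersion α
  (Var = μ + αμ²) is profiled by an outer 1-D maximum-likelihood search
  around weighted GLM fits, with the Poisson boundary (α = 0) checked
  explicitly.  For within-chick predictors (trial number) chick enters as
  a categorical term.  For the chick-level metabolic predictor, trials are
  pooled to per-chick totals: a chick term would absorb the predictor, and
  per-trial rows are correlated within chicks, so leaving them
  disaggregated would overstate the evidence for any chick-level covariate
  (design effect 1 + (m − 1)·ICC).
- **Latencies**: Weibull accelerated-failure-time model with
  right-censoring at 600 s, optimised over (β, log shape) by BFGS from a
  least-squares start; fixing shape = 1 gives the exponential special case
  with its closed-form MLE.  The pipeline adds a shared per-chick gamma
  frailty whose marginal likelihood is closed form
  (logL_i = Σ_unc log h + ν⁻¹log ν⁻¹ + lnΓ(ν⁻¹ + d_i) − lnΓ(ν⁻¹)
  − (ν⁻¹ + d_i) log(ν⁻¹ + S_i)); the frailty plays the role of the random
  effect in the mixed survival model and keeps cluster-level predictors
  honestly tested.  ν → 0 recovers the independent AFT.
- **Time trends** of V̇O₂: Gaussian random-intercept model fit by ML
  (statsmodels MixedLM) so AICs are comparable across fixed-effect
  structures; a singular random intercept falls back to ordinary least
  squares, flagged.
- **David's score**: ordinary Gaussian linear model (n = one row per
  chick).

At 12 chicks, the ΔAIC ≥ 2 rule applied to ML fits has an intrinsic
type-I rate near 7.5% per comparison (for the linear model it is exactly
P(F₁,₁₀ ≥ 10(e^{1/3} − 1)) ≈ 0.075), not the asymptotic
P(χ²₁ ≥ 4) ≈ 4.6%.  Null-model selection rates of roughly 92–95% per
trait under a true null are therefore the calibrated behaviour of the
method at this sample size, not an implementation artefact.

Scaling uses (x − mean)/SD with the sample (n − 1) SD convention,
configurable via `ddof`.

## The synthetic-data generator

The generator's defaults encode the emulated study design: 12 chicks, 6
respirometry sessions each (days 21–41, 20 min baseline / 20 min animal /
10 min baseline at 1 Hz), 14 trials on an 8-arm maze, two 3-trial
personality blocks per trait with a 600 s cap, 6 group dominance trials.
One master seed fans out into an independent substream per data type, so
altering one table never perturbs another, and every dataset carries its
generating truth as metadata so recovery tests never re-derive truth from
data.

- *Respirometry*: first-order washout toward the inverted-equation steady
  state, linear analyser drift (default 2×10⁻⁶ fraction min⁻¹) and i.i.d.
  Gaussian noise (default SD 10⁻⁵, of the order of a fuel-cell analyser's
  resolution).  Per-chick mass-specific intensity declines gently with age
  while absolute V̇O₂ grows with mass, reproducing the rising-raw /
  falling-mass-corrected time-trend pattern.
- *Maze agents*: memory agents choose an unvisited arm with probability ρ
  and otherwise any arm uniformly; ρ = 0 is the random agent; stereotypic
  agents follow a supplied transition matrix.  Pipeline chicks draw
  ρ ~ U(0.3, 0.7), a range in which simulated birds beat the random null
  clearly but imperfectly, as real subjects do.
- *Latencies*: log-normal with chick intercepts sized to an ICC target
  (defaults 0.45 for boldness, 0.31 for neophobia), a post-block shift
  (default +0.7 on the log scale, making post-block latencies longer and
  censoring more frequent, as seen after maze exposure), and right-
  censoring at the cap.
- *Dominance*: latent abilities ~ N(0, σ²) (σ = 1 default), Poisson
  encounters per dyad (mean 2.4 per trial, giving on the order of 900
  interactions over six pooled trials at study scale), win probabilities
  logistic in ability differences (a Bradley–Terry model, chosen because
  any transitive latent model suffices and logistic gives a tractable
  rank-recovery oracle), and wins split randomly across the three recorded
  behaviours.
- *Body mass*: linear growth (170 g + 16 g day⁻¹) with chick-level offsets.

What the generator does **not** emulate: circadian or thermal structure in
metabolic traces, trial truncation at 30 min (a `visit_cap` exists but the
empirical truncation distribution of stopped trials is unknown),
behaviour-specific dominance structure (wins are split uniformly across
behaviours), and any genuine coupling between traits unless `rmr_effect`
is set.  Passing tests on these data demonstrate the *statistical
machinery* — estimator calibration, null-model behaviour, selection-rule
operating characteristics — not the biology of any particular dataset.

## Pipeline and reproducibility

Stages run in the order simulate → rmr → ram → personality → dominance →
models → report, each writing CSV outputs under the run directory; a
checksum manifest makes re-running a completed stage a no-op unless its
inputs changed.  Full runs are byte-reproducible given the master seed.
Input validation (schema, ranges, id consistency across tables) is
report-only and runs before the analysis stages.

Problem sizes used by the test suite: the heavy calibration checks use
200 replicates with 500 bootstraps for CI coverage, 500 replicates for the
LRT, and 100 full pipeline runs for the null-selection pattern, with
respirometry traces sampled at 0.2 Hz and ancillary Monte Carlo sizes
reduced in the runs where they are not the quantity under test; these
sizes give the binomial assertions comfortable margins while keeping the
suite quick.

## Known limitations

- The ICC treats capped latencies as observed values; under heavy
  censoring R is attenuated relative to a censoring-aware estimator.
- The NB and AFT stand-ins do not reproduce the coefficient estimates of
  lme4/coxme fits and are not meant to; only the ΔAIC decisions are
  comparable, and the frailty/aggregation choices above are what make
  those decisions well-calibrated for chick-level predictors.
- The washout model is single-compartment; multi-compartment chambers or
  tubing delays would need an extended generator.
- David's score inherits sampling noise from finite dyad encounter counts;
  with few encounters per dyad, scores of adjacent-ranked birds are not
  meaningfully distinct.
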