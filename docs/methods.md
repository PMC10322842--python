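# Methods

## Scope

`navgap` measures, per country and per cultural cluster, the discrepancy
between a population's self-rated navigation ability and its measured
wayfinding performance, and relates that discrepancy to country-level
cultural dimensions. Because the analysis is designed for very large
volunteer gaming cohorts that cannot be redistributed, the package ships a
synthetic cohort generator with planted effects; every stage is validated
by recovering what was planted.

## Performance scoring

An attempt's path length is the sum of Euclidean distances between
consecutive sampled positions (2 Hz by default; timestamps are used only
for ordering). Scoring then proceeds:

1. **First attempts** on the test levels {3, 6, 7, 8, 11, 12}. "First"
   means the minimum recorded attempt number, not literally attempt 1, so
   the step is robust to upstream log loss; a minimum ≠ 1 is preserved
   rather than discarded.
2. **Tutorial baseline**: sum over practice levels {1, 2} of the mean path
   length across up to the first three attempts. Up to three attempts are
   averaged to damp early technical glitches and training effects; the
   baseline removes device/motor-skill variance common to all levels.
3. **Correction**: test distance / baseline (dimensionless).
4. **Standardisation**: per-level z-scores with the sample sd (n−1),
   computed on the demographically complete, age-valid, level-complete
   population. Outliers are removed *afterwards* without re-standardising:
   re-standardising would change the metric's definition mid-cascade.
5. **Score**: minus the mean of the player's available standardised
   values; the sign reversal makes larger = better. Players missing a test
   level keep a score over completed levels (`n_levels_used` records how
   many), but the inclusion cascade separately requires all six, so the
   analysis set always uses six.

A constant level column (z undefined) and a zero baseline are hard errors,
not silently propagated NaNs.

## Inclusion cascade

Applied in a fixed order, each step auditing (n_before, n_excluded,
n_after): complete demographics (numeric age, gender ∈ {female, male} —
the models use binary gender, so other labels are excluded visibly at this
step; country; one of the four self-estimate labels) → age 19–70 inclusive
→ all six test and both tutorial levels attempted → score outliers,
excluded when |score − mean| ≥ 2 sd with mean/sd computed once on the
current sample (single pass; sd = 0 excludes nobody) → countries with at
least 500 players, evaluated once → cluster membership (unmapped countries
dropped). The audit chains exactly and conserves counts; re-running the
cascade on its own output excludes nothing except possibly a small
second-pass outlier tail (mean/sd are recomputed), which is tested as
bounded by the first pass.

Country names are matched case-insensitively after trimming, with an
optional user alias table (e.g. "Russia" → "Russian Federation"); there is
no fuzzy matching, because a silent misjoin is worse than an explicit
drop. The 46-country/11-cluster membership table is bundled as package
data and its counts are asserted on load. Cultural profiles (six Hofstede
dimensions, optional GDP per capita and gender-inequality index) are
user-supplied CSV — the source studies publish these scores under their own
terms, so no values are bundled; missing optional cells become explicit
`None`, never zero.

## Mixed models and conditional modes

Four models: response ∈ {performance score, numeric self-estimate} ×
grouping ∈ {country, cluster}, each `y ~ age + gender + (1 | group)`.
The self-estimate enters as the −2/−1/1/2 coding; treating an ordinal
response as numeric in the LMM is a deliberate fidelity-over-purity choice
and a known limitation. Age is continuous years centred at 19 (the modes
are invariant to the centring); gender is an indicator with female as
reference. Cluster models fit cluster directly as the grouping factor
(11 groups) rather than aggregating country modes.

Estimation is REML with the variance ratio λ = σ_u²/σ_e² profiled out:
both β and σ_e² have closed forms given λ, and all terms of the criterion
reduce to per-group sums, so one evaluation is O(np + kp²). The criterion
is maximised by bounded scalar search on log₁₀λ ∈ [−8, 8] (xatol 1e−10),
then polished by solving the analytic profile-score equation with a
bracketing root solver — bounded Brent alone localises an optimum only to
about √ε relative, which is not enough for the closed-form equivalences
the test suite demands (balanced-design REML equals the ANOVA moment
estimators to machine precision). λ = 0 is admitted: when the interior
gain over the boundary is within numerical noise (relative tolerance
1e−6·|loglik|), the fit snaps to σ_u² = 0 with a flag, which also covers
the one-observation-per-group flat ridge. Rank-deficient fixed designs
raise, naming the collinear columns.

Conditional modes are the standard shrinkage estimator
u_j = λn_j/(1+λn_j) · (group mean GLS residual), with conditional sd
√(σ_e²λ/(1+λn_j)). With an intercept in X the modes sum to zero exactly.

## Gap statistic and cultural correlations

Self-estimate and performance modes are min–max normalised to [0, 1]
separately for the 46-country and the 11-cluster tables (normalising
jointly would mix two scales), then subtracted. The gap lies in [−1, 1]
by construction: +1 = highest self-belief with lowest performance. The
ordering of gaps is invariant to positive affine transforms applied
jointly to either mode vector; an all-equal mode vector makes the
normalisation undefined and is an error (the pipeline reports the grouping
level as not computable rather than inventing a scale).

Gaps are Spearman-correlated (mid-ranks for ties; two-sided p from the t
reference) with each cultural dimension; Bonferroni correction uses m = 6,
the number of Hofstede dimensions, not the total number of correlations in
a run. Units with missing profile values are dropped pairwise with the
count logged; fewer than three complete pairs flags the row as not
computable. Gender-split gaps re-run the whole modes → normalise → gap
chain within each stratum, with age as the only fixed effect (gender is
constant within a stratum).

## Demographic regressions

The ordinal model of the self-estimate on gender and five age bands
(19–29, 30–39, 40–49, 50–59, 60–70) is a proportional-odds cumulative
logit, fitted via `statsmodels` `OrderedModel` (BFGS, gradient tolerance
1e−8); the thresholds-only null model is fitted in-house by direct
optimisation over the cutpoint parametrisation. Predictor blocks are
tested by likelihood ratio. Empty response categories are collapsed with a
warning; a single observed category is an error. The five band edges are a
design choice: the included age range is 19–70 and bands of width ~10
years are conventional; only the outer anchors are externally fixed.

Hierarchical OLS comparisons use the F-change statistic
((RSS_b − RSS_f)/Δp)/(RSS_f/(n − p_f)), which reduces exactly to t² for a
single added column. Effect sizes are Type-II partial η² (the common
default for unbalanced data without interactions). Collinearity uses the
Fox–Monette generalised VIF from determinants of the predictor correlation
matrix, reported alongside GVIF^(1/(2df)).

## Synthetic cohort generator

The generator's job is to emulate the statistical structure the pipeline
assumes, so that planted country-level over/under-confidence is
recoverable end-to-end.

* **Skill**: `skill = a_c + β_age·(age−19) + β_male·[male]` with planted
  country intercept a_c.
* **Distances**: on test levels, `optimal_length(L) · (1 + detour) ·
  device`, `detour = softplus(−skill + ε)`, ε ~ N(0, σ_resid) per attempt.
  Softplus keeps every path at least as long as the optimal route. On the
  two tutorial levels the detour is `softplus(ε)` — deliberately
  independent of navigation skill: tutorials measure interface
  familiarity, which is exactly the nuisance the baseline correction is
  meant to remove. The per-player device factor `exp(N(0, σ_device))`
  multiplies every level alike and is cancelled by the correction. (If
  tutorial distances carried the same skill term as test levels, the
  baseline division would cancel the planted country signal itself and no
  pipeline could recover it.)
* **Self-estimates**: a latent `b_c + β_age_se·(age−19) + β_male_se·[male]
  + noise` cut at three ascending thresholds; probit-style normal latent
  by default, logistic via `latent_link="logit"`. Default thresholds
  (−1.881, −1.036, 0.674) put ~85% of a neutral population in the
  good/very-good categories, matching the strong positive skew of field
  samples.
* **Attempts**: 1–3 per tutorial level (exercising the up-to-three
  baseline rule); test levels get one attempt plus a 10% chance of a
  second, of which only the first is consumed downstream.
* **Trajectories**: jittered constant-speed walks (heading random-walk,
  sd 0.3 rad/step) whose segment lengths sum to the planted distance
  exactly; `round(duration · rate)` segments, 2 Hz and 5 s by default.
  Short traces keep large cohorts cheap; path *shape* carries no signal in
  this analysis, only length does.

Defaults: ages uniform on 19–70, 55% male (echoing the field sample's
gender mix), β_age_perf = −0.02/yr, β_male_perf = 0.25,
β_age_se = +0.01/yr, β_male_se = 0.5, σ_country (both) = 0.5, σ_resid = 1
(country/residual variance ratio 0.25), σ_device = 0.2. `plant_world`
draws a_c and b_c and couples a synthetic masculinity score (50 ± 20) to
the planted overconfidence b_c − a_c through a Gaussian copula whose
coefficient r = 2·sin(π·ρ_s/6) targets a chosen population Spearman ρ_s
(0.6 by default). Countries take real names from the bundled cluster
table so cluster aggregation works downstream.

All randomness flows from one seeded generator in a documented stream
order (ages, genders, covariates, self-estimate noise, device factors,
attempt counts, detour noise, trajectory headings); identical (config,
seed) give bit-identical output.

What the generator does **not** emulate: level geometry and checkpoint
semantics, level-specific difficulty beyond optimal length, non-binary or
missing demographics patterns, self-selection of volunteers, and any
dependence of self-estimates on actual skill beyond the shared covariates.
Passing recovery tests therefore show the *pipeline* is correct and
well-calibrated, not that real populations follow this generative model.

## Validation experiments and problem sizes

The recovery experiment (`navgap.recovery`) generates 40 countries × 500
players, runs the complete pipeline, and rank-correlates recovered country
modes with planted intercepts; the median over 10 seeds exceeds 0.9 (0.99
observed), and the planted masculinity–overconfidence association (ρ_s =
0.6) returns positive with median Bonferroni p ≪ 0.05. These runs use a
country-size threshold of 400 rather than the production default 500:
countries are planted at exactly 500 players and the 2 sd outlier step
removes ~4.5%, so the production threshold would empty the sample — a
scaling choice of the experiment, not a change to the analysis defaults.
Countries whose planted effects are extreme can still fall below the
threshold (their players are preferentially trimmed as outliers);
correlations are computed over the surviving countries.

Null calibration of the ordinal LR test uses 2000 replicates at n = 500
(rejection rate at α = 0.05 inside [0.040, 0.061]); the planted male odds
ratio of 2 is recovered within three standard errors at n = 10⁵. The REML
implementation is checked on 50 random unbalanced instances (≤ 200 rows)
against an independent 2-parameter Nelder-Mead optimiser of the same
criterion (agreement ≤ 1e−6 in log-likelihood; observed ~1e−13) and
against `statsmodels` `MixedLM` on simulated data.

## Known limitations

* Ordinal self-estimates are treated as numeric (−2/−1/1/2) inside the
  LMMs; distances between categories are assumed equal.
* The min–max normalised gap depends on which units are in the sample: it
  is a relative, not absolute, (mis)calibration measure, and the extreme
  units always sit at exactly 0 and 1.
* A single random intercept per model: no random slopes, no
  crossed/nested factors, no clustered standard errors.
* Step order within the cascade (outliers before the country-size filter;
  standardisation before outlier removal) is fixed to one defensible
  reading; alternative orderings would change counts slightly and are
  exposed only through the audit, not as config.
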