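# Methods

## The problem

Among community-dwelling people aged 75 and over, the clinically useful
question for a general practice is: who will suffer a *relevant* decline in
daily functioning within the next year?  Functioning is measured with the
Groningen Activities Restriction Scale (GARS): 18 items — 11 basic and 7
instrumental activities of daily living — each scored 1 ("fully
independently") to 4 ("only with someone's help"), total 18–72.  Candidate
predictors are restricted to what a GP already has: age, sex, polypharmacy
(> 3 daily medications), multimorbidity (> 1 of a fixed list of 17 chronic
conditions), living situation, the GP's own three-level vulnerability
judgement, and the ISCOPE score — the number of health domains (somatic,
functional, psychological, social) in which a 23-item postal screening
questionnaire records at least two problems.

## Outcome definition

A raw GARS change is not comparable across baselines: a participant at 30
can deteriorate by 42 points, one at 65 by at most 7.  The ceiling-corrected
**proportional increase**

    (GARS_12 − GARS_0) / (72 − GARS_0)

expresses the observed change as a fraction of the change still possible.
Participants are divided into six baseline strata (18–26, 27–35, 36–44,
45–53, 54–62, 63–72) and flagged when their proportional increase exceeds
the 90th percentile of their stratum, so roughly the worst-declining tenth
of every stratum is labelled regardless of where it started.  Death and
nursing-home admission during follow-up count as relevant decline
unconditionally; lost-to-follow-up participants are excluded from labelling
and from the percentile computation (complete-case analysis).

Numerical choices, all configurable:

* **Quantile rule**: nearest-rank — the ⌈0.9 n⌉-th order statistic, the
  smallest value with at least 90% of observations at or below it.  With
  tie-free data the strictly-exceeding fraction is then provably ≤ 10% per
  stratum.  A linear-interpolation alternative is exposed.
* **Inequality**: strictly greater than the cut-off by default; a weak
  (≥) variant is exposed because descriptions of such rules vary.
* **Ceiling cases**: a participant at 72 at both visits has no possible
  increase and gets proportional increase 0 (not declined); an improvement
  *from* 72 has a zero denominator and is carried as NaN — never flagged,
  never contributing to a cut-off.  A sensitivity switch removes
  both-at-ceiling participants entirely; on synthetic cohorts the ladder is
  essentially unchanged, mirroring the robustness such analyses report.

## Models and comparison

Eight nested logistic regressions form a ladder: (1) age + sex;
(2) + polypharmacy, multimorbidity, living situation; (3) model 1 + ISCOPE
score; (4) model 1 + GP opinion; (5) model 1 + both; (6) model 2 + ISCOPE
score; (7) model 2 + GP opinion; (8) everything.  Age enters per year,
untransformed; GP opinion and ISCOPE score enter as treatment dummies
(references: "not vulnerable", score 0) so the univariate per-category odds
ratios and the multivariable models share one coding.  Categorical coding of
the ISCOPE score is an assumption — a linear trend would be defensible —
and is the package default because it reproduces the per-category
reference structure of the univariate table.  Baseline GARS is deliberately
*not* a ladder predictor; it appears only univariately and in the outcome
definition.

Fitting is by iteratively reweighted least squares with step-halving
whenever a Newton step would reduce the likelihood; convergence is declared
when no coefficient moves by more than 1e-8, within 50 iterations.
Complete or quasi-complete separation is detected (diverging coefficients,
fitted probabilities collapsing onto the outcomes) and reported through a
non-convergence flag — never returned silently.  The fit is cross-checked
against `statsmodels.Logit` in the test suite to 1e-6.  Model fit is
summarised by Nagelkerke's R²: the Cox–Snell pseudo-R² rescaled by its
maximum attainable value so perfect prediction gives 1.

Discrimination is the in-sample AUC — the normalized Mann–Whitney
statistic, identical to the trapezoidal area under the empirical ROC curve
(asserted against a brute-force pair-counting oracle in the tests).  No
cross-validation is applied: the procedure evaluates each model on its
training cohort, so AUCs carry in-sample optimism and comparisons between
nested models are the meaningful quantity.  Paired model comparison uses
DeLong's nonparametric test, with the variance of the AUC difference built
from per-case and per-control placement values; the comparison structure is
fixed (2 vs 1, 3 vs 1, 4 vs 1, 5 vs 4, 6 vs 2, 7 vs 2, 8 vs 7), plus the
AUC of the GP opinion entered alone.  A seeded paired bootstrap (2000
resamples) is provided as a cross-check.  The type-I error of the DeLong
test at nominal 0.05 is verified to lie in [0.03, 0.07] over 500 null
replications of n = 400.

Univariate odds ratios come from 2×2 cross-products with Woolf (log-scale
Wald) 95% intervals; on a single binary predictor these coincide with the
logistic fit's Wald interval to better than six significant figures, which
the suite asserts.  Zero cells raise an error offering the Haldane–Anscombe
0.5 correction rather than applying it silently.  Baseline group
comparisons use the two-sided Mann–Whitney test for continuous variables
and Pearson's chi-square without continuity correction over each variable's
full category set.

## Synthetic cohort generator

No individual-level data are public, so every end-to-end path runs on
synthetic cohorts with a known generating process: one standard-normal
latent frailty Z per participant, with one loading per channel.

* Questionnaire items: per-item Bernoulli with logit = intercept
  + loading·Z + a shared per-domain normal effect, so problems cluster
  within domains and the ISCOPE-score distribution becomes realistically
  bimodal-ish rather than binomial.
* GP opinion: ordered-threshold model on loading·Z + standard-normal noise,
  two cut-points, giving the three-level rating.
* Baseline GARS items: ordinal four-level thresholds on loading·Z + item
  noise.
* 12-month change: a raw normal increment (mean 3, SD 8 points,
  frailty-loaded) proportionally shrunk toward whichever scale bound it
  approaches — positive raw changes are scaled by the remaining headroom
  (72 − GARS₀)/54, negative ones by the floor room — then distributed over
  the 18 items.  This reproduces the ceiling effect the outcome definition
  exists to correct.
* Death and nursing-home admission: Bernoulli with frailty-loaded log-odds,
  intercepts recentred by b²/2 so the marginal rates stay near their
  configured fractions under loading.
* Dropout: independent of frailty (a simplification: in real cohorts
  dropouts are frailer, which biases observed predictive value downward;
  the generator does not emulate that informativeness).

Defaults are calibrated once to study-like marginals — median age ~82
(IQR ~79–87), 68% female, ~68% polypharmacy, ~91% multimorbidity, ~10% in
a home for older persons, GP rating ≈ 40/28/32%, median baseline GARS ~31
(IQR ~24–41), 12-month change median ~2 points, ~6.5% deaths, ~2%
nursing-home admissions, ~18.5% lost — and the defaults are the study
conditions for every test.  Age is drawn independently of frailty — the
frailty channels are the questionnaire, GP opinion, GARS, decline and the
two events — so the age–outcome association is essentially null in
synthetic cohorts and the age-and-sex base model hovers near AUC 0.5;
the *increments* up the ladder, not the absolute AUC levels, are the
quantities the synthetic pipeline is meant to exercise.  The item-to-domain
mapping of the screening questionnaire is configuration (default: items
1–6, 7–12, 13–18, 19–23) because the instrument's exact mapping is not in
the public record.  An optional switch emulates the original home-visit
selection (15% of score 0/1, 60% of score 2, 100% of score 3/4).

Reproducibility: each channel draws from its own child stream of one
`SeedSequence`, spawned in a fixed, append-only order.  Identical
config + seed gives byte-identical cohort files, and changing only loading
coefficients leaves every other channel's draws untouched.

Because the percentile outcome flags a fixed within-stratum fraction, no
fixed covariate→outcome log-odds exists along that path; parameter-recovery
calibration therefore uses a companion simulator that draws a binary
decline directly from a logistic law over the generated covariates with a
stated coefficient, which the inference stage must recover within 3 SE in
at least 90% of replications (n = 2000, 100 replications).

## What passing tests do and do not show

The suite demonstrates: exact agreement of the odds-ratio machinery with
published 2×2 tables; oracle-equivalence of AUC; correctness of the
likelihood optimum (score equations, statsmodels agreement, nested-model
monotonicity); the hand-enumerable mechanics of the percentile outcome; and
distributional calibration of the DeLong test and the estimator on data
whose generating process is known.  It does not demonstrate that the
synthetic frailty structure matches the real cohort's dependence structure,
nor that in-sample AUC levels transfer to new practices — both are
properties of data this package cannot access.

## Problem sizes

Defaults keep the whole suite under a few minutes on one CPU: cohorts of
400–5000 for unit and property tests, 2711 (the study-scale cohort) for
end-to-end runs, 500 replications of n = 400 for test calibration, and 100
replications of n = 2000 for recovery.
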