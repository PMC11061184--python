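# Methods

This note documents the models, the synthetic-data generator, the
numerical choices and the known limitations of `affectmed`. It describes
what the code computes; every empirical figure quoted here is produced by
the test suite or by `scripts/acceptance.py`.

## The analysis chain

The package targets a common online-experiment design: N participants rate
90 images (30 neutral, 30 threat-of-infection, 30 threat-of-harm, order
randomized, one of three counterbalanced image sets) on four 0–100 slider
scales — felt disgust, felt fear, appraised sickness risk, appraised harm
risk — then self-report a binary exposure (prior COVID-19 diagnosis),
demographics, and ten 5-point Likert items on pandemic-related disruption
of daily social and emotional life. The chain is:

1. **Screening.** Four sequential exclusion filters: any failed attention
   check (slider not on the target number, tolerance configurable, default
   exact); pooled sample SD of all 360 rating responses strictly below 10
   (straight-lining/bot signature); questionnaire rows that cannot be
   aligned to rating data (blank survey code; duplicate IDs either abort
   or are routed here by config); missing demographic covariates. A
   participant failing several filters is counted only under the first;
   counts are conserved by construction and the report is machine-readable.
   The SD is pooled over all four scales — the strictest reading of a
   "low rating variance" rule — and computed with the n−1 denominator;
   a scale-wise variant would catch less straight-lining across scales.
2. **Aggregation and normalisation.** Ratings are averaged per participant
   within each condition × scale cell (12 mediators, exactly 30 trials per
   cell enforced). Slider data are strongly right-skewed, so each mediator
   is Box-Cox transformed, `((x+1)^λ − 1)/λ` with `ln(x+1)` at λ = 0. The
   +1 shift admits exact-zero ratings; it is fixed, recorded in the fit
   object, and deliberately minimal. λ maximizes the profile
   log-likelihood on a grid over [−2, 2] in steps of 0.01 followed by
   bounded scalar refinement inside the winning cell; the whole profile is
   returned for inspection. λ is fitted per mediator on the full analysis
   sample (not per exposure group, and not on trial-level data, since the
   mediation operates on person-level variables). Extreme values are
   flagged by Tukey's far-out fences (Q1 − 3·IQR, Q3 + 3·IQR, type-7
   quartiles) but never removed; the transformation, not deletion, is the
   skew remedy.
3. **Disruption scale.** Single-factor exploratory factor analysis by
   minimum residual: the loading vector minimizes the sum of squared
   off-diagonal residuals of the item correlation matrix (L-BFGS-B with
   analytic gradient, principal-component start, loadings bounded away
   from ±1, sign-aligned to a positive mean). Eigenvalues of the raw
   correlation matrix are reported for the scree decision (their sum
   equals the number of items); eigenvalues of the reduced matrix —
   diagonal replaced by fitted communalities — are also exposed because
   published "eigenvalue" figures may follow either convention, and the
   two differ materially (on generator defaults at N ≈ 734 the raw first
   eigenvalue is ≈ 5.1 and the reduced one ≈ 4.6). Items with |loading|
   below 0.5 (configurable) are dropped, the factor refit on the survivors,
   and the score is the plain mean of retained items — deliberately not a
   factor score, matching standard scale-construction practice. The scree
   decision itself is reported (first/second eigenvalue and their ratio),
   not automated.
4. **Manipulation check.** Per rating scale, a trial-level linear mixed
   model with a participant random intercept and two dummy-coded fixed
   effects contrasting each threat condition against the reference
   (default neutral), estimated by REML (statsmodels MixedLM), with
   two-tailed 95% Wald intervals. Trial-level ratings are Box-Cox
   transformed first (per scale), with a raw-scale flag for sensitivity.
   Refitting after releveling the factor yields the third pairwise
   contrast; by linear reparameterization it equals the difference of the
   original two, which the tests verify to 1e−6, and the fixed effects
   agree with the closed-form GLS estimator given the fitted variance
   components. No covariates, random slopes or image-identity effects
   enter these models.
5. **Mediation.** See README for the model. Choices worth recording:
   - The b-path model includes the exposure (standard product-method
     practice, keeps the c = c′ + Σ a·b decomposition exact); a toggle
     removes it.
   - Standardization is semi-standardized: continuous variables (mediator,
     outcome, age, income, education) z-scored on the analysis sample,
     0/1 dummies (exposure, gender, race, ethnicity, image-set codes)
     untouched. For a binary exposure the a-path beta is then the group
     mean difference in SD units. The convention is recorded in the
     output metadata.
   - Wild-bootstrap weights: Rademacher ±1 by default; Mammen two-point
     and standard normal available. One weight vector per iteration is
     shared across the a and b models (and across all four models in an
     indirect-effect contrast) so the product reflects one jointly
     perturbed sample; independent weights are available for sensitivity.
   - Because the wild scheme never changes the design matrix, the per
     iteration OLS refit has the closed form β* = β + h'(w∘r) with h the
     focal row of (X'X)⁻¹X'; the implementation evaluates all iterations
     as one matrix product. Tests verify equality with literal refits.
   - Intervals are two-tailed percentile intervals of the stored draws
     (no BCa correction); significance is exclusively CI-excludes-zero.
   - No multiple-testing correction across the 12 mediation tests; the
     results file records the number of tests prominently.
   - A master seed spawns per-mediator substreams (CRC-keyed), so adding
     or removing a mediator never shifts another mediator's draws, and
     rows are canonically ordered by participant ID before weights are
     drawn, so results are invariant to input row order.
   - Rank-deficient designs abort with the names of the collinear columns.

## The synthetic-data generator

The generator emulates the statistical structure the analysis assumes,
with ground truth retained for recovery testing. Defaults encode the
emulated study's conditions: 734 participants, exposure probability
0.1866, 90 trials, three image sets, ten Likert items with nine strong
loadings (0.70–0.78) and one weak one (0.43, item 7), and demographic
margins (age 39.6 ± 11.1, 43.6% female, 16.6% non-White, 11.2% Hispanic,
nine-level income and five-level education distributions) used as
parametric stand-ins rather than resampled tables.

Person-level reactivity per condition × scale cell is unit-variance
normal: `Z = a·D + s·(√ρ·G + √(1−ρ)·ε)`, with `s` chosen so Var(Z) = 1,
`D` the 0/1 exposure, `G` a shared negativity factor (ρ = 0.4 by default)
that induces realistic correlation among the 12 mediators, and `a` the
*standardized* exposure effect — the group mean difference in SD units,
i.e. exactly what the semi-standardized a-path estimator targets. Trial
ratings pass `Z` through a lognormal-type link,
`clip(18·exp(0.5·(shift_c + Z)) + N(0, 16), 0, 100)`: this produces the
right skew that motivates Box-Cox downstream while keeping the log of the
person-level condition mean approximately affine in `Z`, so the analysis
chain can undo the link. The base (18), log-scale (0.5) and trial noise SD
(16 rating units) were chosen so that slider ranges look like human data
and the pooled rating SD of attentive simulated responders stays safely
above the SD < 10 bot filter (empirically ≥ ~11.5). Condition shifts
(neutral 0, harm 0.7, infection 1.2) reproduce the expected rating
ordering; they apply to all four scales unless a (condition, scale) key
overrides them, and are acknowledged as ad hoc — per-condition rating
means are rarely published.

The disruption factor is `F = Σ b·Z + γ'X_std + e`, scaled to unit
variance, with `b` *structural* weights and `e` sized from the exact
latent covariance of `Z`; configurations whose implied signal variance
exceeds 0.9 are rejected rather than silently rescaled. Items are
congeneric indicators of `F` discretised to 1–5 at fixed thresholds
(−2, −1, −0.2, 0.8), giving a right-of-centre mean near the 3.5 typical of
such scales. Careless responders are injected post hoc: constant-response
mode overwrites all 360 ratings with one value plus SD ≈ 2 jitter;
attention-fail mode corrupts one of the three check responses; two further
helpers blank survey codes and single covariates to exercise the
remaining cascade steps. Regeneration with the same seed is bit-identical.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: image-level heterogeneity (all trials in a cell
are exchangeable), response-time or order effects, non-monotone response
styles (e.g. midpoint anchoring), missing trial data, measurement
non-invariance across exposure groups, and any causal confounding beyond
the parametric covariate effects. Two measurement facts of the generator
matter when reading recovery numbers: (i) the disruption score is an
imperfect indicator of `F` (reliability ≈ 0.93 with default loadings plus
Likert discretisation), so recovered b paths and indirect effects are
attenuated by roughly 10% — the 200-seed recovery run measures a mean
product of ≈ 0.049–0.050 against a structural 0.06; (ii) discretisation
shrinks the item SD slightly more than group mean differences, so
standardized *total* effects on the score can mildly exceed the latent
ones. With several correlated mediators carrying non-zero structural
weights, marginal per-mediator b estimates exceed the structural values
by design; recovery tests therefore use single-mediator configurations.

## Calibration properties

Measured by the acceptance tests on generator data (single mediator,
n = 700, B = 2000 unless noted): the type-I error of the CI-excludes-zero
indirect-effect test under a = 0, b = 0.3 is ≈ 0.035–0.045 over 500
replicates (nominal 0.05); coverage of the true product under a = 0.2,
b = 0.3 is ≈ 0.93–0.94; bias of the recovered product at n = 5000 is
≈ −0.011 (attenuation, see above). Power at a = 0.3, b = 0.4 is ≈ 0.83–0.88
rather than above 0.95: with an unbalanced binary exposure
(p ≈ 0.187) the a-path standard error is 1/√(n·p(1−p)) ≈ 0.097 at
n = 700, so even a bias-free estimator operates at a product z of about
3.5, and the attenuated one at about 3.0. This is a property of the
design (exposure imbalance), not of the estimator; only a balanced
exposure or a larger sample would push the power of this test above 0.95.

## Numerical details and degenerate inputs

- Box-Cox uses `expm1` so the power form is accurate down to λ → 0;
  constant input, n < 10, or non-positive shifted values raise.
- The pooled-SD filter and the `rating_sd` statistic share one numpy code
  path so the strict `< cutoff` comparison can never disagree between
  report and filter.
- Minres falls back to the best L-BFGS-B iterate; singular correlation
  matrices (constant items, collinear items) raise before optimisation.
- Percentile CI endpoints come from `np.quantile` (linear interpolation)
  on the stored draw vector, which is exposed on request so the interval
  is re-derivable.
- MixedLM boundary fits (zero intercept variance) emit suppressed
  convergence warnings; the variance is reported as ~0 rather than
  masked.
- Bootstrap specs below 1000 iterations warn; degenerate all-zero
  residuals and self-contrasts are flagged rather than silently returned.

## Limitations

Cross-sectional mediation: nothing here licenses causal claims; the
estimator recovers the generative parameters of the simulation, not
sequential-ignorability-robust effects. Ordinal items are treated as
numeric (no polychoric option). The manipulation-check models deliberately
omit Kenward–Roger/Satterthwaite corrections and random slopes. The
acceptance simulations use desk-scale replicate counts (200–500) chosen as
a compromise between Monte-Carlo error (±0.01–0.02 on rates) and runtime;
they are package defaults, not statements about any external dataset.
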