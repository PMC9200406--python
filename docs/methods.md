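# Methods

This note documents the statistical procedures implemented in cavemetab,
their assumptions, the defaults and why, and what the synthetic-data
tests do and do not establish about real data.

## Data model and normalization

Inputs are processed peak-height tables (features x samples, arbitrary
non-negative instrument units) with per-feature identification flags and
category labels, plus a sample table of design factors. Absent
metabolites are encoded as intensity 0; NaN is rejected so missingness
decisions are made explicitly upstream. Raw spectral processing (peak
picking, annotation) is out of scope — the pipeline starts where the
quantification software ends.

mTIC normalization divides each sample by its identified-peak sum and
multiplies by the group's average sum. The grouping defaults to
population x tissue — each sample is scaled to the average of its own
population/organ group pooled over feeding states — with a `global`
option that uses one reference for the whole table. The per-group default
follows the described laboratory procedure; the global variant exists
because the normalization formula is sometimes glossed with a global
reference. Note the group references differ between groups, so
cross-population comparisons retain a harmless between-group scalar; the
downstream log10 + per-feature z-scoring removes it entirely.

Zeros are replaced before the log10 transform by half the smallest
positive intensity of that feature within the comparison (deterministic
half-minimum imputation, the common metabolomics convention; the source
protocol is silent here). Features with no positive intensity in a
comparison are dropped with a warning; features constant within a
comparison are flagged and set to all-zero z-scores. z-scores use the
sample SD (n−1). Constancy is detected at relative tolerance 1e-9 so that
exactly-cancelling scale factors do not register as variance.

## Body-condition metrics and the univariate router

Fulton's condition factor is `K = (m/x³) x 100` (mass in g, standard
length in cm). The percentage changes `ΔWt% = (m_f − m_i)/m_f x 100` and
`ΔK% = (K_f − K_i)/K_f x 100` divide by the *final* value. That is an
unconventional baseline; it is kept because it is the printed convention
of the protocol this package reproduces, and `denominator="initial"`
switches to the conventional form.

Multi-group comparisons of such metrics are routed by a normality screen:
four tests (D'Agostino–Pearson, Shapiro–Wilk, Lilliefors-form
Kolmogorov–Smirnov, Anderson–Darling) on the pooled within-group
residuals at alpha 0.05 each. Passing at least three routes to one-way
ANOVA with Tukey's HSD; failing more than one routes to Kruskal–Wallis
with Dunn's rank-based post-hoc (tie-corrected, Bonferroni-adjusted —
written in-package since no installed library provides Dunn's test).
The KS test estimates mean and SD from the data (Lilliefors), the only
variant that can ever pass on residuals with unknown scale. Significance
is star-coded ns / * / ** / *** / **** at 0.05 / 0.01 / 0.001 / 0.0001.

## O-PLS

Single-response NIPALS O-PLS per orthogonal component on the centred
samples x features matrix X with labels y in {−1, +1}:
w ∝ Xᵀy (unit norm), t = Xw, p = Xᵀt/(tᵀt),
w_o = p − (wᵀp)w normalized, t_o = Xw_o, p_o = Xᵀt_o/(t_oᵀt_o),
X ← X − t_o p_oᵀ. Because w ∝ Xᵀy, every removed score satisfies
t_oᵀy = 0 exactly, and deflation preserves Xᵀy, so the predictive
direction is identical before and after filtering. Two invariants are
asserted in the tests: exact reconstruction (X_filtered plus the removed
rank-one terms equals the input) and w_o ⊥ w. The orthogonal *loadings*
p_o are generally not orthogonal to w — only the weights are — which is
a property of the algorithm, not an error.

Defaults: one orthogonal component (the procedure removes "a" single
orthogonal component; more are configurable); no re-centring between
components (z-scoring upstream); ‖w_o‖ < 1e-12·‖p‖ is treated as "no
orthogonal variation", returning the input unchanged with
`n_orth_effective = 0`. A minimum of 3 samples is accepted so that
leave-one-out folds over 4-sample comparisons can refit the filter.
If the nuisance structure is exactly disjoint from the predictive
structure (loadings orthogonal to p), the filter correctly does nothing:
such variation cannot contaminate a PLS predictor. The filter is fit per
comparison, matching the per-comparison z-scoring.

## PLS1, Q2/DQ2 and the permutation test

The classifier is one PLS component: w ∝ Xᵀy on the column-centred
training matrix, scores t = Xw, y regressed on t by least squares;
prediction of a new sample projects through the training centre and w.
Cross-validation is leave-one-out (12 samples per comparison make k-fold
folds unstable), and the O-PLS filter is refit inside every fold so the
held-out label never leaks into the filtering step.

Q2 = 1 − PRESS/TSS with TSS about the label mean, so 0 is the
mean-predictor baseline. DQ2 truncates each out-of-sample prediction to
[−1, 1] before computing residuals: a model predicting +1.8 for a +1
sample made no error of discriminatory consequence. Truncation can only
shrink residuals, so DQ2 ≥ Q2 always; both are at most 1. (The truncation
is applied to the prediction, not the label — clipping ±1 labels would be
a no-op.)

Significance: the labels are fully shuffled `n_perm` times (default 1000;
200 in the scaled-down test suites), the complete filter+classifier+LOO
pipeline is re-run per shuffle, and a normal is fitted to the permuted
DQ2 values by mean and SD. The reported p is the two-tailed survival
probability of the observed DQ2 under that normal, clamped to [0, 1]; a
degenerate null (SD = 0) reports p = 1 with a warning. The normal fit is
an approximation to the permutation distribution; its null calibration is
verified empirically (rejection rate at alpha 0.05 inside the 95%
binomial band over 200 null replicates). Everything is bit-reproducible
given (seed, n_perm).

## Bayesian logistic regression

Each feature is tested marginally with a single-covariate logistic model.
Covariates are centred and rescaled to SD 0.5 (the convention the prior
scales are calibrated to; coefficients are back-transformed, so scaling a
covariate by c scales the slope by 1/c and leaves z and p unchanged).
Priors are independent Student-t with 1 df (Cauchy): scale 2.5 on the
slope, 10 on the intercept — the weakly-informative default under which a
typical covariate change should not move the response by more than about
±5 logits. The posterior mode is found by EM-augmented IRLS, writing the
t prior as a scale mixture of normals: E-step
E[1/σ_j² | β_j] = (ν+1)/(ν s_j² + β_j²), M-step one ridge-penalized IRLS
step; iterated to a 1e-8 relative tolerance or 100 iterations. The fixed
point is the mode of the marginal posterior with the exact Cauchy prior
(verified against a zooming 2-D grid search of the exact log-posterior to
better than 1e-3 per coordinate). Standard errors come from the curvature
at the mode (observed information plus the E-step prior precision);
p-values are two-sided Wald tests.

Complete separation is detected directly: for a single covariate it is
exactly the condition that the classes split at a threshold on x, so the
geometric check replaces iterative divergence monitoring (deterministic,
no overflow guards). Separated fits return finite slopes — that is the
point of the prior.

No multiple-testing correction is applied by default: the prior is the
conservatism, by design. A consequence worth stating plainly: at n = 12
the shrinkage makes the Wald test *conservative* under the null (the
measured type-I error of the full feature-test path runs at roughly half
the nominal 5%), and the O-PLS step pushes mildly the other way by
concentrating class-correlated variance. The test is validity-preserving
(never anti-conservative on independent null features in our checks), but
it is not calibrated to the nominal level at this sample size, and on
data with a strong shared latent factor the *realized* false-positive
fraction of a single comparison is highly variable because the marginal
tests are correlated. Benjamini–Hochberg adjustment is available behind
`bh_fdr=True`.

Category/class-level tests use the mean member z-score per sample as the
covariate (sum is configurable) with the same GLM machinery, skipping
classes with fewer than 2 members; free-fatty-acid saturation bins derive
from double-bond counts (0 = SFA, 1 = MUFA, ≥2 = PUFA).

## Parallel-adaptation contrast

For one tissue and one feeding-state pair, z-scores are computed within
each population over its 12 samples; replicate k of Pachón is paired with
replicate k of Tinaja and Surface by sorted replicate id, and
x_k = (P_k + T_k)/2 − S_k. Fish are not biologically paired — any pairing
is exchangeable under the null, and the sorted rule makes results
deterministic; unequal replicate counts are an error rather than being
imputed. The contrast is symmetric in the two cave populations, and a
response present in only one cave enters at half weight, which is what
makes the statistic selective for shared (parallel) responses. The
pseudo-sample matrix is O-PLS-filtered against the feeding-state labels
*after* forming the combination (filtering before is switchable via the
building blocks), then each feature gets the Bayesian logistic fit, with
"up" meaning increased in the fasted cave state. All three state pairs
are generated; per tissue the 20 most significant features (p ascending,
ties by |slope| descending then feature id) are tabulated with signed
−log10 p for heatmap rendering.

## Synthetic metabolome generator

The generator emulates the study design — 3 populations x 3 tissues x 3
feeding states x 6 replicates, 174 identified primary metabolites and 483
identified lipid-like features by default, plus 50 unidentified peaks so
mTIC normalization is exercised — with multiplicative intensities: log10
value = feature baseline N(5, 0.8) + per-tissue offset N(0, 0.4) +
planted effects + nuisance loading N(0, 0.3) x per-sample score N(0, 1) +
residual N(0, 0.25), exponentiated, with whole (feature, population x
tissue) cells blanked to zero at rate 0.02 to mimic absent metabolites
and a per-sample multiplicative jitter (log10 SD 0.1) so normalization
has work to do. A baseline log10 intensity of ~5 with ~0.25 residual SD
is typical of GC-TOF peak-height tables at six replicates. Planted
effects are expressed in z-units (multiples of the residual SD), scoped
to shared-cave / single-cave / surface and to feeding-state responses or
constitutive baseline shifts; the default suite spans 2.0 z (comfortable)
to 0.5 z (marginal) so power curves are meaningful at n = 6. The latent
nuisance factor is drawn independently of the class labels, so it is
orthogonal to them in expectation — exactly the structure O-PLS is meant
to remove. Everything is reproducible from (config, seed).

What the generator does *not* emulate: retention-time drift, batch
effects, heteroscedastic intensity-dependent noise, correlated metabolite
modules beyond the single latent factor, and missingness that depends on
abundance. Passing tests therefore demonstrate that the pipeline's
statistics behave as designed under the model they assume, not that the
biological conclusions of any particular dataset are correct.

`recovery_report` scores pipeline flags against the planted truth
(sensitivity per scope/axis, false-positive rate on null features,
overall precision, NA when nothing is flagged).

## Orchestration and reporting

`run_pipeline` executes normalize → comparisons → per-category
O-PLS+DQ2 classification → per-feature tests → parallel contrasts →
top-20 tables, writing TSVs and a JSON summary free of timestamps so
reruns are byte-comparable; per-comparison permutation seeds are spawned
deterministically from the master seed. PCA scores (SVD on the centred
matrix, component signs fixed by making the largest-|loading| element
positive) are provided for cluster inspection. The test suites and the
acceptance script run scaled-down problem sizes — 20–500 features,
100–500 permutations, 100–200 replicates — chosen to make the
statistical checks decisive on a single CPU while keeping the full suite
in the minutes range.

## Known limitations

- The Wald-at-the-mode p-value is not a posterior tail probability and,
  as noted, runs conservative at n = 12.
- The normal fit to the permutation DQ2 null is an approximation; with
  n_perm ≥ 200 its miscalibration was not measurable in our checks, but
  extreme p-values inherit the normal tail rather than the empirical one.
- One orthogonal component is removed by default; datasets with several
  strong structured nuisance factors need `n_orth > 1`, at the cost of
  increasingly optimistic within-comparison correlation.
- The contrast's replicate pairing is a modelling convenience; pairing
  permutation diagnostics can be built from `build_contrast` directly.
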