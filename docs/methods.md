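# Methods

## Outcome model and estimands

Four binary six-month toxicity outcomes are modeled separately: xerostomia
grade ≥ 2 and ≥ 3, dysphagia grade ≥ 2 and ≥ 3. Each uses a fixed,
pre-specified predictor set in NTCP practice units:

- **xerostomia** (4 columns): submandibular mean dose (Gy), one combined
  parotid term `sqrt(ipsilateral dose) + sqrt(contralateral dose)`, and two
  baseline-xerostomia dummies (grade ≥ 2 and ≥ 3);
- **dysphagia** (8 columns): oral-cavity and PCM superior/medius/inferior
  mean doses (Gy), two baseline-dysphagia dummies, and two tumor-location
  dummies (pharynx, larynx; "other" is the reference).

Both baseline dummies enter regardless of the modeled grade, and the
grade ≥ 2 / ≥ 3 variants of a toxicity share the predictor set. This
encoding is the unique reading consistent with the published predictor
counts (four vs. eight); whether the original models split the parotid
doses or used one baseline dummy is not documented, so the encoding is
serializable to YAML and configurable without code changes.

Performance is judged at external validation: AUC with DeLong's standard
error; calibration-in-the-large on two scales — the probability-scale mean
difference `mean(p̂) − mean(y)` (the definitional "average predicted
probability minus the overall outcome rate") and the logit-scale
recalibration intercept (offset-logistic fit with slope fixed at 1) —
because published result tables of this kind are typically on the logit
scale while the prose definition is on the probability scale; the
calibration slope (free-slope recalibration, ideal 1); and a lowess
calibration curve evaluated at the deciles of the predictions.

## The six variants

Models 1/2 (logistic, ridge) use labeled rows only. Models 3/4 first turn
the unlabeled outcomes into a fully labeled dataset by chained-equations
imputation (m = 1 completed dataset by default, matching a protocol that
creates "a" fully labeled dataset; m is configurable). Models 5/6 wrap the
base learner in self-training: confidence = `max(p, 1−p)` so both classes
can be pseudolabeled; all qualifying rows are added per iteration (batch
mode) with unit weight, permanently; ties at p = 0.5 take label 1; stopping
when an iteration adds nothing, no unlabeled rows remain, or 50 iterations.
Defaults τ = 0.8, cap 50. Batch addition, the two-sided confidence and the
tie rule are implementation choices documented here because the upstream
description leaves them open.

## Fitting

Both learners are fit by iteratively reweighted least squares (IRLS),
convergence when the largest coefficient change falls below 1e-8 or at 100
iterations. The ridge fit maximizes `loglik − (λ/2)·Σ b_j²` with slopes
standardized internally (intercept unpenalized) and back-transformed, so
reported coefficients stay per-Gy. λ is chosen by 10-fold cross-validated
deviance over 50 log-spaced values spanning `[1e−4, 1e4]·(n/p)`, fold
assignment seeded; λ is re-selected at every refit — per imputed dataset
and per self-training iteration — because each is a new training set.
Within the CV loop fits warm-start along the descending λ path at a looser
tolerance (1e-6); the returned model is always refit at 1e-8. Complete
separation in an *unpenalized* fit is a hard error naming the separating
column — models 1/3/5 must remain unpenalized, so the experiment layer
records such runs as failed cells rather than silently penalizing.

## Missing data

Missingness in the registries this emulates is confined to baseline and
six-month toxicity scores, with the grade ≥ 2 and ≥ 3 flags of one
toxicity/timepoint missing together (missingness acts on the underlying
grade). Imputation is by chained equations: all incomplete fields are
binary, so each conditional model is a logistic regression on all other
covariates and toxicity fields; missing cells are initialized from observed
marginals, then 10 sweeps (default) cycle the fields, each time drawing the
coefficients from a normal approximation to their posterior before
redrawing the cells Bernoulli — the parameter draw is what makes the
procedure proper multiple imputation. Separation in a conditional model
falls back to a ridge-stabilized fit (λ = 1, logged in the imputation-model
descriptors). The grade hierarchy (≥ 3 ⇒ ≥ 2) is re-enforced on imputed
cells after every sweep. The development cohort is imputed once, the
validation cohort ten times and separately per center; validation metrics
are computed per completed dataset and pooled with Rubin's rules
(`Q̄`, `T = W̄ + (1 + 1/m)B`), curves averaged pointwise. Whether the
original analysis pooled across centers before or after Rubin pooling is
not documented; here metrics are computed on the recombined full validation
cohort per imputation, then pooled over imputations.

## Synthetic cohort generator

The generator is the package's stand-in for the non-public registries and
defines the study conditions for every experiment.

**Doses.** Seven mean organ doses (submandibular, ipsi-/contralateral
parotid, oral cavity, PCM superior/medius/inferior) are drawn through a
Gaussian copula with truncated-normal marginals on [0, 80] Gy.
Pre-truncation (μ, σ) are adjusted numerically so the post-truncation mean
matches the published value exactly and the sd as closely as the family
allows; sds above the truncated-family supremum (≈ 22 Gy at these means —
the published parotid sd of 32 Gy is geometrically unattainable inside
[0, 80] for a unimodal law) are matched at the achievable maximum. Default
correlations: 0.5 between PCM organs, 0.4 between the parotid pair, 0.2
elsewhere — anatomically adjacent organs share dose; no correlations are
published, so these are config-overridable defaults. The published table
pools the parotid glands into one row (mean 51.7) and omits the oral
cavity; both glands default to the pooled marginal and the oral cavity to
46 Gy (21) in development / 44 Gy (21) in validation, a realistic
mid-range head-and-neck value. A truncated "23." in the extracted
validation column for the PCM superior sd is read as 23.0.

**Covariates and baselines.** Age is normal (63.1, 10.2 development; 64,
9.4 validation), sex/stage Bernoulli and location categorical at the
published prevalences. Baseline toxicity uses a shared latent uniform per
toxicity thresholded at the two prevalence levels, which enforces
≥ 3 ⇒ ≥ 2 by construction.

**Outcomes.** Each outcome's risk is `expit(β₀ + Xβ)` on its own design.
The two grades of a toxicity share slope defaults, and both grades are
thresholded against one shared uniform, so the ≥ 3 flag is nested in ≥ 2
pointwise. β₀ is calibrated by monotone root-finding on a 100 000-patient
Monte-Carlo estimate of the marginal rate (cached per configuration), with
an explicit error when the target cannot be bracketed. Default slopes are
generator defaults, *not* estimates from any patient data; their magnitudes
were sized once so the true model's large-sample AUC falls in 0.68–0.75,
the range within which the real models operate, and frozen
(xerostomia: 0.022/Gy submandibular, 0.13 per √Gy-sum, 0.9/0.5 baseline;
dysphagia: 0.016/0.0176/0.0128/0.0096 per Gy, 0.9/0.5 baseline, 0.44/0.20
location).

**Missingness and masking.** MAR amputation: the missingness probability of
each of the four field groups depends only on always-observed fields
(logit-linear in age, stage and standardized mean dose: 0.03/yr, 0.5,
0.3/sd) with the intercept root-found so the realized rate matches the
published rate; realized fractions are binomially noisy around the target
(±3 points is a ~2-sd event at n = 750). Label masking selects exactly k
rows (default 40) uniformly among rows with observed outcomes, flags them
unlabeled and hides their outcomes while retaining the pre-mask values and
generator truth for pseudolabel-error accounting. Masking and missingness
are deliberately distinct mechanisms.

**Validation centers.** Per-center composition is not published; the
default splits 395 patients into near-equal thirds with ±2 Gy dose-mean
shifts and no extra intercept shifts (case-mix differences then propagate
to outcome rates through the dose effect). Both shift vectors are
configurable.

**What the generator does not emulate:** longitudinal toxicity
trajectories, dose-volume histograms beyond mean doses, within-patient
organ-dose physics (only a fixed copula), measurement error in toxicity
grading, or the true (unpublished) joint distribution and coefficients of
the registries. Tests passing on this generator therefore certify the
pipeline's statistical machinery and qualitative behavior, not the
registries' numeric results.

## Experiments

All experiments run the six variants per outcome in the 750-patient /
40-unlabeled regime and externally validate on the 395-patient cohort:
baseline; labeled decrement (labeled 710, 670, … to a floor of 70 by
default, unlabeled fixed at 40, removal sets nested so each step removes 40
more from the previous step's set); threshold sweep (τ ∈ {0.5, 0.6, 0.7,
0.8, 0.9, 0.95} for self-training with logistic regression, alongside the
two non-self-training logistic comparators; the 0.5 cell runs at 0.5 + ε so
exactly-ambiguous predictions are never added); and ratio sweep (labeled
decreased by 40s with the total held at 750, the removed rows becoming
unlabeled). A master seed fixes generation, amputation, imputation,
masking, fold assignment and self-training, making whole result tables
bit-for-bit reproducible; every failed fit is recorded as a failed cell
with its reason and the run continues.

The real study runs each experiment once on fixed registries; here the
default is 200 Monte-Carlo replicates so that "similar performance" claims
become testable averages. The shipped analysis drivers and the test suite
run smaller, stated replicate counts (3–10 replicates, 5 CV folds, 15 λ
values, 3–5 imputations via `small_config`) — the package's desk-scale
problem sizes; cohort sizes and the 40-unlabeled regime are never scaled.

## Numerical choices

- Probabilities are clipped to [1e-8, 1 − 1e-8] before logit transforms
  (warned, configurable constant).
- Lowess curves use frac = 2/3 and zero robustness iterations — the robust
  reweighting assumes continuous residuals and distorts fits on 0/1
  outcomes.
- AUC ties count 1/2; the rank-based implementation is verified against
  exhaustive pair enumeration.
- Intercept-calibration and truncated-normal moment-matching results are
  cached per configuration; calibration Monte-Carlo n defaults to 100 000
  (MC error on a rate ≈ 0.16 points).
- Degenerate CV folds (single-class training split) are skipped; λ ties
  resolve to the first minimum on the descending grid.
- Seeds are combined through `numpy.random.SeedSequence` paths so every
  stage draws from an independent stream; all user-facing seeds are taken
  modulo 2³¹.

## Known limitations

- The truncated-normal dose family cannot reach the published parotid sd
  (32 Gy) inside [0, 80] Gy; the generator gets within ~10 Gy of it while
  matching the mean exactly.
- Development imputation uses m = 1 (per the emulated protocol), so
  development-side imputation uncertainty is not propagated into the
  fitted models — only validation-side uncertainty is Rubin-pooled.
- Self-training error accounting uses generator truth and is therefore
  available only on synthetic data.
- Plain-logistic cells can fail by separation at very small labeled counts;
  they are reported as failed cells, mirroring how unpenalized models break
  down in practice, not retried.
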