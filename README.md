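# ntcp-semisup

Supervised versus semi-supervised NTCP modeling of radiotherapy toxicities
in head-and-neck cancer, with a fully synthetic, calibration-checked cohort
generator.

## The problem

Normal Tissue Complication Probability (NTCP) models predict a patient's
risk of radiation-induced toxicity — here patient-reported xerostomia (dry
mouth) and physician-rated dysphagia (swallowing difficulty) at six months
after radiotherapy, each dichotomized at grade ≥ 2 and grade ≥ 3 — from mean
organ doses, baseline toxicity and tumor characteristics. In routine
practice a slice of the registry is always *unlabeled*: patients treated
less than six months ago have covariates and doses on file but no outcome
yet. Semi-supervised **self-training** promises to use those rows: fit a
classifier on the labeled data, pseudolabel the unlabeled rows whose
predicted class probability clears a confidence threshold τ, refit on
labeled + pseudolabeled rows, and repeat until nothing is added (or an
iteration cap is hit).

This package implements the full comparison of six model variants for each
of the four outcomes:

1. logistic regression on the labeled rows only,
2. ridge-penalized logistic regression on the labeled rows only,
3. logistic regression after chained-equations imputation of the unlabeled
   outcomes,
4. ridge regression after that imputation,
5. self-training with logistic regression (τ = 0.8, ≤ 50 iterations),
6. self-training with ridge regression,

with external validation on a separate three-center cohort: AUC (DeLong SE),
calibration-in-the-large (both the probability-scale mean difference
`mean(p̂) − mean(y)` and the logit-scale recalibration intercept *a* in
`logit P(y=1) = a + logit(p̂)`), the calibration slope *b* in
`logit P(y=1) = a + b·logit(p̂)`, and a smoothed calibration curve. Missing
baseline/outcome data are handled by chained-equations multiple imputation
and metrics are pooled across imputations with Rubin's rules
(`T = W̄ + (1 + 1/m)B`).

Because the underlying patient registries are not public, the package ships
a first-class synthetic generator that reproduces the published cohort
description: truncated-normal organ-dose marginals with a Gaussian-copula
correlation structure, binary covariate prevalences, outcomes drawn from
logistic dose–toxicity models whose intercepts are root-found so the
marginal six-month rates match the published percentages (44/13/29/15 % in
development; 48/15/19/6 % in validation), MAR missingness at the published
rates, a 40-patient unlabeled mask, and a three-center validation cohort
with case-mix shifts.

## Worked example

```python
from ntcp_semisup import (development_config, generate_cohort, ampute,
                          mask_labels, chained_impute, spec_for,
                          build_design, fit_logistic, self_train,
                          SelfTrainConfig)

cfg = development_config()                   # n=750, table-calibrated
coh = generate_cohort(cfg, seed=1)           # complete cohort
coh = ampute(coh, cfg.missing_rates, seed=1) # MAR missingness
coh = chained_impute(coh, m=1, seed=2).cohorts[0]
coh = mask_labels(coh, 40, seed=3)           # 710 labeled + 40 unlabeled

spec = spec_for("xer_g2")                    # 4-column xerostomia design
X, y, labeled = build_design(coh, spec)
unlab = coh["unlabeled"].astype(bool).to_numpy()
model, trace = self_train(X[labeled], y[labeled], X[unlab],
                          SelfTrainConfig(tau=0.8), seed=5,
                          term_names=spec.term_names)
print(trace.n_iterations, trace.total_pseudolabels, trace.stopping_reason)
# 1 6 no pseudolabels added
print(model.to_json())
```

The trace says one self-training iteration pseudolabeled 6 of the 40
unlabeled patients (those with confidence ≥ 0.8) and the next iteration
added none, so the loop stopped; the final model is the refit on the
716-row set, with coefficients in per-Gy / per-dummy units.

The replicated comparison is driven by the numbered scripts:

```bash
python analysis/01_generate_cohorts.py      # cohorts + calibration echo
python analysis/02_baseline_comparison.py   # six variants, four outcomes
python analysis/03_labeled_decrement.py     # shrink labeled set, 40 unlabeled fixed
python analysis/04_threshold_sweep.py       # tau in {0.5 ... 0.95}
python analysis/05_ratio_sweep.py           # grow the unlabeled fraction
```

`02_baseline_comparison.py` prints the pooled external-validation table; on
the synthetic cohorts (6 replicates) the six variants show near-identical
discrimination per outcome (e.g. dysphagia ≥ 2: AUC 0.692–0.694 across all
six) while the ridge variants sit closer to the ideal calibration slope of
1 (0.87–0.89 vs 0.75–0.79 for the logistic variants). `04` shows
pseudolabel counts falling from 40 (τ=0.5) to 0 (τ=0.95) with no effect on
AUC, and `05` shows self-training calibration degrading only once the
unlabeled fraction is large and incorrect pseudolabels accumulate — the
same qualitative behavior reported for the real registries. Equivalent
subcommands exist on the CLI (`ntcp-semisup generate|baseline|decrement|
threshold-sweep|ratio-sweep`).

## Layout

- `src/ntcp_semisup/` — library: `config`/`cohort` (generator), `design`
  (predictor encodings: 4 xerostomia columns, 8 dysphagia columns),
  `impute` (chained equations + Rubin pooling), `learners` (IRLS logistic
  and ridge with CV penalty selection), `selftrain`, `metrics`,
  `experiments`, `cli`.
- `analysis/` — numbered narrative drivers over the library.
- `tests/` — unit, property and acceptance suites.
- `docs/methods.md` — model and generator assumptions, parameter defaults,
  numerical choices, limitations.
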