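"""End-to-end experiments over the six model variants.

Variants: (1) logistic and (2) ridge regression on labeled rows only;
(3)/(4) the same after chained-equations imputation of the masked outcomes;
(5)/(6) self-training with the respective base learner.  Each experiment
generates a development cohort (default n=750, 40 outcomes masked as
unlabeled) and a three-center validation cohort (default n=395), handles
missing data per the imputation protocol (development once, validation ten
times per center), fits all variants per outcome, and externally validates
them with Rubin-pooled metrics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import ampute, generate_cohort, mask_labels
from .config import OUTCOMES, GeneratorConfig, development_config, validation_config
from .design import build_design, spec_for
from .impute import ImputationSet, chained_impute, impute_unlabeled
from .learners import CVConfig, fit_logistic, fit_ridge
from .metrics import validate
from .selftrain import SelfTrainConfig, self_train

MODELS = (
    "logistic",
    "ridge",
    "mice_logistic",
    "mice_ridge",
    "selftrain_logistic",
    "selftrain_ridge",
)

DEFAULT_THRESHOLDS = (0.5, 0.6, 0.7, 0.8, 0.9, 0.95)


@dataclass
class ExperimentConfig:
    dev: GeneratorConfig = field(default_factory=development_config)
    val: GeneratorConfig = field(default_factory=validation_config)
    outcomes: tuple[str, ...] = OUTCOMES
    models: tuple[str, ...] = MODELS
    n_unlabeled: int = 40
    decrement_step: int = 40
    decrement_floor: int = 70
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS
    tau: float = 0.8
    max_iter: int = 50
    replicates: int = 200
    val_m: int = 10
    mice_m: int = 1  # imputations of the masked outcomes (models 3/4)
    sweeps: int = 10
    cv: CVConfig = field(default_factory=CVConfig)
    master_seed: int = 0


def _child_seed(master: int, *path: int) -> int:
    return int(np.random.SeedSequence([int(master) % 2**31, *path]).generate_state(1)[0] % 2**31)


def _prepare_development(cfg: ExperimentConfig, seed: int) -> pd.DataFrame:
    """Generate, ampute, impute once, then mask the unlabeled outcomes."""
    dev = generate_cohort(cfg.dev, seed=_child_seed(seed, 1))
    dev = ampute(dev, cfg.dev.missing_rates, seed=_child_seed(seed, 2))
    dev = chained_impute(dev, m=1, sweeps=cfg.sweeps, seed=_child_seed(seed, 3)).cohorts[0]
    return mask_labels(dev, cfg.n_unlabeled, seed=_child_seed(seed, 4))


def _prepare_validation(cfg: ExperimentConfig, seed: int) -> ImputationSet:
    """Generate and ampute the validation cohort, then impute it val_m times
    separately per center; recombine into val_m completed datasets."""
    val = generate_cohort(cfg.val, seed=_child_seed(seed, 5))
    val = ampute(val, cfg.val.missing_rates, seed=_child_seed(seed, 6))
    per_center = []
    for ci, center in enumerate(cfg.val.centers):
        sub = val[val["center"] == center]
        if sub.isna().any().any():
            imp = chained_impute(sub, m=cfg.val_m, sweeps=cfg.sweeps,
                                 seed=_child_seed(seed, 7, ci))
        else:
            imp = ImputationSet(m=cfg.val_m, cohorts=[sub.copy() for _ in range(cfg.val_m)])
        per_center.append(imp)
    combined = [
        pd.concat([imp.cohorts[i] for imp in per_center]).sort_index()
        for i in range(cfg.val_m)
    ]
    return ImputationSet(m=cfg.val_m, cohorts=combined, seed=seed)


def _fit_variant(
    cfg: ExperimentConfig,
    name: str,
    dev: pd.DataFrame,
    outcome: str,
    seed: int,
    tau: float | None = None,
):
    """Fit one model variant on a (masked) development cohort.

    Returns (model, trace-or-None).  Raises on fit failure (recorded by the
    caller as a failed cell).
    """
    spec = spec_for(outcome)
    X, y, labeled = build_design(dev, spec)
    names = spec.term_names
    if name == "logistic":
        return fit_logistic(X[labeled], y[labeled], names), None
    if name == "ridge":
        return fit_ridge(X[labeled], y[labeled], cv=cfg.cv, seed=seed, term_names=names), None
    if name in ("mice_logistic", "mice_ridge"):
        imp = impute_unlabeled(dev, m=cfg.mice_m, seed=seed)
        # m=1 by default: the protocol builds one fully labeled dataset
        df = imp.cohorts[0]
        Xi, yi, lab = build_design(df, spec)
        if name == "mice_logistic":
            return fit_logistic(Xi[lab], yi[lab], names), None
        return fit_ridge(Xi[lab], yi[lab], cv=cfg.cv, seed=seed, term_names=names), None
    if name in ("selftrain_logistic", "selftrain_ridge"):
        st = SelfTrainConfig(
            tau=tau if tau is not None else cfg.tau,
            max_iter=cfg.max_iter,
            base="logistic" if name == "selftrain_logistic" else "ridge",
            cv=cfg.cv,
        )
        unlab = np.asarray(dev["unlabeled"], dtype=bool)
        truth = np.asarray(dev[f"truth_out_{outcome}"], dtype=float)
        model, trace = self_train(
            X[labeled], y[labeled], X[unlab], st, seed=seed, term_names=names,
            true_unlabeled=truth[unlab],
        )
        return model, trace
    raise ValueError(f"unknown model variant {name!r}")


def _metrics_row(vm) -> dict:
    return {
        "auc": vm.auc.value, "auc_se": vm.auc.se,
        "citl_meandiff": vm.citl_meandiff.value, "citl_meandiff_se": vm.citl_meandiff.se,
        "citl_logit": vm.citl_logit.value, "citl_logit_se": vm.citl_logit.se,
        "slope": vm.slope.value, "slope_se": vm.slope.se,
        "n_val": vm.n, "events_val": vm.events, "m_val": vm.m,
    }


def _trace_row(trace) -> dict:
    if trace is None:
        return {"st_iterations": None, "st_pseudolabels": None,
                "st_errors": None, "st_stop": None}
    return {
        "st_iterations": trace.n_iterations,
        "st_pseudolabels": trace.total_pseudolabels,
        "st_errors": trace.total_errors,
        "st_stop": trace.stopping_reason,
    }


def _evaluate_cell(cfg, name, dev, val_set, outcome, seed, tau=None, extra=None):
    row = {"outcome": outcome, "model": name, **(extra or {})}
    try:
        model, trace = _fit_variant(cfg, name, dev, outcome, seed, tau=tau)
        vm = validate(model, val_set, spec_for(outcome))
        row.update(status="ok", reason="", **_metrics_row(vm), **_trace_row(trace))
    except (ValueError, np.linalg.LinAlgError) as exc:
        row.update(status="failed", reason=str(exc), **_trace_row(None))
    return row


def run_baseline(cfg: ExperimentConfig) -> pd.DataFrame:
    """Six variants x four outcomes, replicated; the 40-unlabeled regime."""
    rows = []
    for rep in range(cfg.replicates):
        seed = _child_seed(cfg.master_seed, 100, rep)
        dev = _prepare_development(cfg, seed)
        val_set = _prepare_validation(cfg, seed)
        n_lab = int((dev["unlabeled"] == 0).sum())
        for outcome in cfg.outcomes:
            for mi, name in enumerate(cfg.models):
                rows.append(
                    {"replicate": rep,
                     **_evaluate_cell(cfg, name, dev, val_set, outcome,
                                      _child_seed(seed, 8, n_lab, mi))}
                )
    return pd.DataFrame(rows)


def _removal_order(dev: pd.DataFrame, seed: int) -> np.ndarray:
    """Fixed random order in which labeled rows are removed/masked; nested
    across steps (each step removes 40 more from the previous step's set)."""
    labeled_idx = dev.index[(dev["unlabeled"] == 0)].to_numpy()
    rng = np.random.default_rng(np.random.SeedSequence([seed, 90_001]))
    return rng.permutation(labeled_idx)


def run_labeled_decrement(cfg: ExperimentConfig) -> pd.DataFrame:
    """Unlabeled fixed at 40; labeled reduced 710, 670, ... down to the floor
    by dropping nested random subsets; all variants refit per step."""
    rows = []
    min_events_guard = 2
    for rep in range(cfg.replicates):
        seed = _child_seed(cfg.master_seed, 100, rep)
        dev = _prepare_development(cfg, seed)
        order = _removal_order(dev, seed)
        n_labeled0 = int((dev["unlabeled"] == 0).sum())
        steps = list(range(n_labeled0, cfg.decrement_floor - 1, -cfg.decrement_step))
        val_set = _prepare_validation(cfg, seed)
        for n_lab in steps:
            removed = order[: n_labeled0 - n_lab]
            sub = dev.drop(index=removed)
            p_max = max(spec_for(o).n_columns for o in cfg.outcomes)
            if n_lab < 2 * p_max:
                import warnings

                warnings.warn(f"step with {n_lab} labeled rows below 2*p; skipped")
                continue
            for outcome in cfg.outcomes:
                for mi, name in enumerate(cfg.models):
                    rows.append(
                        {"replicate": rep, "n_labeled": n_lab, "n_unlabeled": cfg.n_unlabeled,
                         **_evaluate_cell(cfg, name, sub, val_set, outcome,
                                          _child_seed(seed, 8, n_lab, mi))}
                    )
    _ = min_events_guard
    return pd.DataFrame(rows)


def run_threshold_sweep(cfg: ExperimentConfig, outcome: str = "xer_g2") -> pd.DataFrame:
    """Self-training across the confidence-threshold grid, alongside the two
    non-self-training logistic comparators."""
    rows = []
    for rep in range(cfg.replicates):
        seed = _child_seed(cfg.master_seed, 300, rep)
        dev = _prepare_development(cfg, seed)
        val_set = _prepare_validation(cfg, seed)
        for name in ("logistic", "mice_logistic"):
            rows.append(
                {"replicate": rep, "tau": np.nan,
                 **_evaluate_cell(cfg, name, dev, val_set, outcome, _child_seed(seed, 8, 0))}
            )
        for ti, tau in enumerate(cfg.thresholds):
            # the grid's lowest threshold 0.5 is run as 0.5+eps: every row
            # whose prediction is not exactly ambiguous qualifies
            eff_tau = max(float(tau), np.nextafter(0.5, 1.0))
            rows.append(
                {"replicate": rep, "tau": tau,
                 **_evaluate_cell(cfg, "selftrain_logistic", dev, val_set, outcome,
                                  _child_seed(seed, 8, 1), tau=eff_tau)}
            )
    return pd.DataFrame(rows)


def run_ratio_sweep(cfg: ExperimentConfig) -> pd.DataFrame:
    """Labeled decreased in steps of 40 with the total held fixed: the
    removed rows become unlabeled, so unlabeled = total - labeled; incorrect
    pseudolabels are counted against generator truth."""
    rows = []
    for rep in range(cfg.replicates):
        seed = _child_seed(cfg.master_seed, 400, rep)
        dev = _prepare_development(cfg, seed)
        order = _removal_order(dev, seed)
        n_total = len(dev)
        n_labeled0 = int((dev["unlabeled"] == 0).sum())
        steps = list(range(n_labeled0, cfg.decrement_floor - 1, -cfg.decrement_step))
        val_set = _prepare_validation(cfg, seed)
        for n_lab in steps:
            extra_mask = order[: n_labeled0 - n_lab]
            sub = dev.copy()
            if len(extra_mask):
                for oc in ("out_xer_g2", "out_xer_g3", "out_dys_g2", "out_dys_g3"):
                    sub.loc[extra_mask, f"premask_{oc}"] = sub.loc[extra_mask, oc]
                    sub.loc[extra_mask, oc] = np.nan
                sub.loc[extra_mask, "unlabeled"] = 1
            assert int((sub["unlabeled"] == 1).sum()) + n_lab == n_total
            for outcome in cfg.outcomes:
                for mi, name in enumerate(cfg.models):
                    rows.append(
                        {"replicate": rep, "n_labeled": n_lab,
                         "n_unlabeled": n_total - n_lab,
                         **_evaluate_cell(cfg, name, sub, val_set, outcome,
                                          _child_seed(seed, 9, n_lab, mi))}
                    )
    return pd.DataFrame(rows)


def small_config(replicates: int = 3, master_seed: int = 0, **kw) -> ExperimentConfig:
    """Reduced-size configuration for fast runs: smaller CV grid and fewer
    imputations; cohort sizes and the 40-unlabeled regime are unchanged."""
    cfg = ExperimentConfig(
        replicates=replicates,
        master_seed=master_seed,
        val_m=3,
        sweeps=5,
        cv=CVConfig(k=5, n_lambdas=15),
        **kw,
    )
    return cfg
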