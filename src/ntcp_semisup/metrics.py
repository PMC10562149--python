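"""External-validation metrics: discrimination (AUC with DeLong SE) and
calibration (calibration-in-the-large on two scales, calibration slope,
smoothed calibration curve), plus Rubin pooling across imputed validation
datasets.

Calibration-in-the-large is reported both as the prose definition (mean
predicted probability minus observed event rate) and as the intercept of a
logistic recalibration model with the logit of the predictions as a fixed
offset; the slope comes from the analogous free-slope recalibration model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import special

from .impute import ImputationSet, rubin_pool

PROB_CLIP = 1e-8


@dataclass
class Estimate:
    value: float
    se: float


@dataclass
class ValidationMetrics:
    auc: Estimate
    citl_meandiff: Estimate
    citl_logit: Estimate
    slope: Estimate
    curve: np.ndarray  # (k, 2): predicted, observed-smoothed
    n: int
    events: int
    m: int = 1


def _check_binary(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("y must be binary 0/1")
    return y


def auc(y: np.ndarray, p: np.ndarray) -> Estimate:
    """Concordance probability (ties count 1/2) with DeLong standard error."""
    y = _check_binary(y)
    p = np.asarray(p, dtype=float)
    pos = p[y == 1]
    neg = p[y == 0]
    n1, n0 = len(pos), len(neg)
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present to compute the AUC")
    order = np.sort(neg)
    # placement of each positive among negatives: P(neg < pos) + 0.5 P(tie)
    lt = np.searchsorted(order, pos, side="left")
    le = np.searchsorted(order, pos, side="right")
    v10 = (lt + 0.5 * (le - lt)) / n0
    order_p = np.sort(pos)
    gt = n1 - np.searchsorted(order_p, neg, side="right")
    ge = n1 - np.searchsorted(order_p, neg, side="left")
    v01 = (gt + 0.5 * (ge - gt)) / n1
    a = float(v10.mean())
    s10 = float(np.var(v10, ddof=1)) if n1 > 1 else 0.0
    s01 = float(np.var(v01, ddof=1)) if n0 > 1 else 0.0
    return Estimate(a, float(np.sqrt(s10 / n1 + s01 / n0)))


def auc_bruteforce(y: np.ndarray, p: np.ndarray) -> float:
    """Exhaustive all-pairs concordance count; oracle for small n."""
    y = _check_binary(y)
    pos = p[y == 1]
    neg = p[y == 0]
    total = 0.0
    for a in pos:
        for b in neg:
            total += 1.0 if a > b else (0.5 if a == b else 0.0)
    return total / (len(pos) * len(neg))


def _clip_probs(p: np.ndarray, context: str) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if (p <= 0).any() or (p >= 1).any():
        warnings.warn(f"probabilities clipped to [{PROB_CLIP}, 1-{PROB_CLIP}] for {context}")
        p = np.clip(p, PROB_CLIP, 1 - PROB_CLIP)
    return p


def calibration_in_the_large(y: np.ndarray, p: np.ndarray) -> tuple[Estimate, Estimate]:
    """Mean calibration on both scales.

    Returns ``(mean_diff, logit_intercept)``: the average predicted
    probability minus the observed event rate (ideal 0; positive means
    overestimation), and the intercept of ``y ~ 1`` with ``logit(p)`` as a
    fixed offset (ideal 0; positive means the model underestimates risk).
    """
    y = _check_binary(y)
    if len(y) < 2:
        raise ValueError("need n >= 2")
    p = np.asarray(p, dtype=float)
    diff = float(p.mean() - y.mean())
    diff_se = float(np.std(p - y, ddof=1) / np.sqrt(len(y)))

    pc = _clip_probs(p, "logit calibration-in-the-large")
    offset = special.logit(pc)
    fit = sm.GLM(y, np.ones((len(y), 1)), family=sm.families.Binomial(), offset=offset).fit()
    return Estimate(diff, diff_se), Estimate(float(fit.params[0]), float(fit.bse[0]))


def calibration_slope(y: np.ndarray, p: np.ndarray) -> Estimate:
    """Slope of the logistic recalibration of y on logit(p); ideal 1."""
    y = _check_binary(y)
    lp = special.logit(_clip_probs(p, "calibration slope"))
    if np.std(lp) < 1e-12:
        raise ValueError("predictions are constant; calibration slope undefined")
    X = sm.add_constant(lp)
    fit = sm.GLM(y, X, family=sm.families.Binomial()).fit()
    return Estimate(float(fit.params[1]), float(fit.bse[1]))


def calibration_curve(
    y: np.ndarray, p: np.ndarray, method: str = "lowess", frac: float = 2 / 3
) -> np.ndarray:
    """Smoothed observed-vs-predicted curve points (no rendering).

    ``lowess``: local-regression smoother of y on p evaluated at the deciles
    of p.  ``bins``: equal-width 10-bin means of (p, y).
    """
    y = _check_binary(y)
    p = np.asarray(p, dtype=float)
    if len(y) < 20:
        raise ValueError("need n >= 20 for a calibration curve")
    if method == "bins":
        edges = np.linspace(p.min(), p.max() + 1e-12, 11)
        idx = np.digitize(p, edges) - 1
        pts = [
            (float(p[idx == b].mean()), float(y[idx == b].mean()))
            for b in range(10)
            if (idx == b).any()
        ]
        return np.asarray(pts)
    if method != "lowess":
        raise ValueError(f"unknown method {method!r}")
    xvals = np.quantile(p, np.linspace(0.05, 0.95, 10))
    # it=0: robustness iterations assume continuous residuals and distort
    # the fit on 0/1 outcomes
    smoothed = sm.nonparametric.lowess(y, p, frac=frac, it=0, xvals=xvals)
    return np.column_stack([xvals, np.clip(smoothed, 0.0, 1.0)])


def single_dataset_metrics(y: np.ndarray, p: np.ndarray) -> ValidationMetrics:
    a = auc(y, p)
    cd, cl = calibration_in_the_large(y, p)
    sl = calibration_slope(y, p)
    curve = calibration_curve(y, p)
    y = np.asarray(y, dtype=float)
    return ValidationMetrics(
        auc=a, citl_meandiff=cd, citl_logit=cl, slope=sl, curve=curve,
        n=len(y), events=int(y.sum()), m=1,
    )


def validate(model, imputation_set: ImputationSet, spec) -> ValidationMetrics:
    """Metrics per imputed validation dataset, Rubin-pooled per metric
    (squared SE as within-imputation variance); curves averaged pointwise."""
    from .design import build_design
    from .learners import predict_prob

    per = []
    for df in imputation_set.cohorts:
        X, yv, labeled = build_design(df, spec)
        yv = yv[labeled]
        p = predict_prob(model, X[labeled])
        per.append(single_dataset_metrics(yv, p))

    def pool(get):
        pe = rubin_pool([get(v).value for v in per], [get(v).se ** 2 for v in per])
        return Estimate(pe.qbar, pe.se)

    curve = np.mean([v.curve for v in per], axis=0)
    return ValidationMetrics(
        auc=pool(lambda v: v.auc),
        citl_meandiff=pool(lambda v: v.citl_meandiff),
        citl_logit=pool(lambda v: v.citl_logit),
        slope=pool(lambda v: v.slope),
        curve=curve,
        n=per[0].n,
        events=per[0].events,
        m=len(per),
    )
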