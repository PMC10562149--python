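"""Chained-equations imputation of binary toxicity fields and Rubin pooling.

All incomplete fields here are binary (baseline and 6-month toxicity flags),
so every conditional model is a logistic regression on all other covariates
and toxicity fields.  Parameter uncertainty is propagated by drawing the
coefficients from a normal approximation to their posterior before each
redraw of the missing cells, which makes the procedure a proper multiple
imputation.  The grade hierarchy (>=3 implies >=2) is re-enforced on imputed
cells after every sweep.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special

from .cohort import DOSE_COLUMNS, OUTCOME_COLS, PREMASK_COLS
from .learners import SeparationError, fit_logistic, fit_ridge

#: binary fields eligible for imputation
IMPUTABLE_FIELDS = (
    "base_xer_g2", "base_xer_g3", "base_dys_g2", "base_dys_g3",
    "out_xer_g2", "out_xer_g3", "out_dys_g2", "out_dys_g3",
)

#: hierarchy pairs (grade>=2 column, grade>=3 column)
_HIERARCHY = (
    ("base_xer_g2", "base_xer_g3"),
    ("base_dys_g2", "base_dys_g3"),
    ("out_xer_g2", "out_xer_g3"),
    ("out_dys_g2", "out_dys_g3"),
)

_ALWAYS_OBSERVED = ("age", "sex_male", "stage_t34", "loc_pharynx", "loc_larynx") + DOSE_COLUMNS


@dataclass
class PooledEstimate:
    """Rubin's-rules pooled estimate across m imputations."""

    qbar: float
    wbar: float
    b: float
    t: float
    m: int

    @property
    def se(self) -> float:
        return float(np.sqrt(self.t))


@dataclass
class ImputationSet:
    """m completed cohorts, identical to the input on observed cells."""

    m: int
    cohorts: list[pd.DataFrame]
    models: dict[str, list[str]] = field(default_factory=dict)  # field -> per-sweep notes
    seed: int = 0

    def write_csv(self, path) -> None:
        """All completed datasets stacked, tagged by an imputation_id column."""
        stacked = pd.concat(
            [df.assign(imputation_id=i + 1) for i, df in enumerate(self.cohorts)],
            ignore_index=True,
        )
        stacked.to_csv(path, index=False)


def rubin_pool(estimates, variances) -> PooledEstimate:
    """Pool point estimates and their (squared-SE) variances across
    imputations: ``T = Wbar + (1 + 1/m) * B`` with B the between-imputation
    sample variance (0 when m=1)."""
    q = np.asarray(list(estimates), dtype=float)
    w = np.asarray(list(variances), dtype=float)
    if q.size == 0 or q.shape != w.shape:
        raise ValueError("estimates and variances must be equal-length nonempty lists")
    if (w < 0).any():
        raise ValueError("variances must be >= 0")
    m = q.size
    qbar = float(q.mean())
    wbar = float(w.mean())
    b = float(q.var(ddof=1)) if m > 1 else 0.0
    t = wbar + (1 + 1 / m) * b
    return PooledEstimate(qbar=qbar, wbar=wbar, b=b, t=t, m=m)


def _predictor_matrix(df: pd.DataFrame, target: str, fields: list[str]) -> np.ndarray:
    cols = list(_ALWAYS_OBSERVED) + [f for f in fields if f != target]
    X = np.asarray(df.loc[:, cols], dtype=float)
    # standardize continuous columns for numerical stability of the draws
    sd = X.std(axis=0)
    sd[sd < 1e-12] = 1.0
    return (X - X.mean(axis=0)) / sd


def _fit_conditional(X: np.ndarray, y: np.ndarray, note: list[str], target: str):
    """Logistic conditional model; ridge-stabilized fallback on separation
    or a single-class response."""
    try:
        if y.min() == y.max():
            raise SeparationError(target)
        model = fit_logistic(X, y)
        note.append("logistic")
        return model
    except SeparationError:
        note.append("ridge-fallback")
        if y.min() == y.max():
            # degenerate: constant field among observed rows; keep marginal
            rate = float(np.clip(y.mean(), 1e-4, 1 - 1e-4))
            model = fit_ridge(X, np.concatenate([y[:-1], [1 - y[-1]]]), lam=1e6)
            model.intercept = float(special.logit(rate))
            model.coefs = np.zeros_like(model.coefs)
            return model
        return fit_ridge(X, y, lam=1.0)


def chained_impute(
    cohort: pd.DataFrame, m: int = 10, sweeps: int = 10, seed: int = 0
) -> ImputationSet:
    """Multiple imputation by chained equations of the binary toxicity fields.

    Missing cells are initialized by draws from the observed marginals, then
    each incomplete field is cycled ``sweeps`` times: a logistic model of the
    field on all other covariates/fields is fit on originally observed rows,
    its coefficients perturbed by a draw from their normal posterior
    approximation, and the missing cells redrawn Bernoulli.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    fields = [f for f in IMPUTABLE_FIELDS if cohort[f].isna().any()]
    for f in fields:
        if cohort[f].isna().all():
            raise ValueError(f"field {f!r} is missing for every row; cannot impute")
    non_imputable = [
        c for c in cohort.columns
        if cohort[c].isna().any() and c not in IMPUTABLE_FIELDS and c not in PREMASK_COLS
    ]
    if non_imputable:
        raise ValueError(f"missingness outside imputable fields: {non_imputable}")

    base_rng = np.random.default_rng(np.random.SeedSequence([int(seed) % 2**31, 78_001]))
    models: dict[str, list[str]] = {f: [] for f in fields}
    completed = []
    masks = {f: cohort[f].isna().to_numpy() for f in fields}
    for _ in range(m):
        rng = np.random.default_rng(base_rng.integers(2**31))
        df = cohort.copy()
        if not fields:
            completed.append(df)
            continue
        for f in fields:
            obs = df[f].dropna().to_numpy(dtype=float)
            df.loc[masks[f], f] = rng.choice(obs, size=int(masks[f].sum()))
        for _sweep in range(sweeps):
            for f in fields:
                miss = masks[f]
                X = _predictor_matrix(df, f, fields)
                y_obs = np.asarray(df.loc[~miss, f], dtype=float)
                model = _fit_conditional(X[~miss], y_obs, models[f], f)
                beta = np.concatenate([[model.intercept], model.coefs])
                if model.cov_unscaled is not None:
                    try:
                        L = np.linalg.cholesky(
                            model.cov_unscaled + 1e-12 * np.eye(len(beta))
                        )
                        beta = beta + L @ rng.standard_normal(len(beta))
                    except np.linalg.LinAlgError:
                        pass
                eta = beta[0] + X[miss] @ beta[1:]
                df.loc[miss, f] = (rng.random(int(miss.sum())) < special.expit(eta)).astype(float)
            for g2, g3 in _HIERARCHY:
                if g2 in masks or g3 in masks:
                    bad = (df[g3] > df[g2])
                    if bad.any():
                        # imputed grade>=3 without grade>=2: demote the >=3 flag
                        df.loc[bad & pd.Series(masks.get(g3, False), index=df.index), g3] = 0.0
                        still = df[g3] > df[g2]
                        df.loc[still, g2] = 1.0
        completed.append(df)
    return ImputationSet(m=m, cohorts=completed, models=models, seed=seed)


def impute_unlabeled(cohort: pd.DataFrame, m: int = 1, seed: int = 0) -> ImputationSet:
    """Treat masked (unlabeled) outcomes as missing, fill them by chained
    equations, and clear the unlabeled flag in the completed datasets."""
    unlabeled = np.asarray(cohort["unlabeled"], dtype=bool)
    if not unlabeled.any():
        warnings.warn("no unlabeled rows; impute_unlabeled is the identity")
        return ImputationSet(m=m, cohorts=[cohort.copy() for _ in range(m)], seed=seed)
    work = cohort.copy()
    for col in OUTCOME_COLS:
        work.loc[unlabeled, col] = np.nan
    result = chained_impute(work, m=m, sweeps=10, seed=seed)
    for df in result.cohorts:
        df["unlabeled"] = 0
    return result
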