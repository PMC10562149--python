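"""Base classifiers: maximum-likelihood and ridge-penalized logistic regression.

Both are fit by iteratively reweighted least squares.  The ridge fit
maximizes ``loglik - (lam/2) * sum(b_std_j^2)`` where slopes are penalized on
an internally standardized scale (intercept unpenalized) and back-transformed
to per-Gy / per-dummy units on output, so reported coefficients stay in NTCP
practice units.  The penalty strength can be given directly or selected by
seeded k-fold cross-validated deviance over a log-spaced grid.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import special

MAX_ITER = 100
COEF_TOL = 1e-8


class SeparationError(ValueError):
    """Perfect separation: the unpenalized likelihood has no finite maximum."""

    def __init__(self, column: str):
        super().__init__(
            f"complete separation detected (diverging coefficient on {column!r}); "
            "an unpenalized logistic fit does not exist"
        )
        self.column = column


@dataclass
class CVConfig:
    """Cross-validation settings for ridge penalty selection."""

    k: int = 10
    n_lambdas: int = 50
    log10_range: tuple[float, float] = (-4.0, 4.0)

    def grid(self, n: int, p: int) -> np.ndarray:
        lo, hi = self.log10_range
        return np.logspace(lo, hi, self.n_lambdas) * (n / p)


@dataclass
class FittedModel:
    """A fitted (possibly penalized) logistic model."""

    term_names: tuple[str, ...]
    intercept: float
    coefs: np.ndarray
    lam: float = 0.0
    lam_trace: list[tuple[float, float]] | None = None
    converged: bool = True
    n_iter: int = 0
    n_obs: int = 0
    outcome: str | None = None
    cov_unscaled: np.ndarray | None = field(default=None, repr=False)

    def linear_predictor(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != len(self.coefs):
            raise ValueError(
                f"design has {X.shape[1] if X.ndim == 2 else '?'} columns, "
                f"model expects {len(self.coefs)}"
            )
        return self.intercept + X @ self.coefs

    def to_json(self) -> str:
        return json.dumps(
            {
                "outcome": self.outcome,
                "lambda": self.lam,
                "intercept": self.intercept,
                "coefficients": dict(zip(self.term_names, map(float, self.coefs))),
            },
            indent=2,
        )


def predict_prob(model: FittedModel, X: np.ndarray) -> np.ndarray:
    """Predicted event probabilities, strictly inside (0, 1)."""
    p = special.expit(model.linear_predictor(X))
    return np.clip(p, 1e-15, 1 - 1e-15)


def _irls(
    X1: np.ndarray,
    y: np.ndarray,
    lam_vec: np.ndarray,
    beta0: np.ndarray | None = None,
    tol: float = COEF_TOL,
) -> tuple[np.ndarray, np.ndarray, bool, int]:
    """IRLS on a design with explicit intercept column; per-coefficient ridge.

    Returns (beta, unscaled covariance of the penalized fit, converged, iters).
    """
    n, p1 = X1.shape
    beta = np.zeros(p1) if beta0 is None else beta0.copy()
    converged = False
    it = 0
    for it in range(1, MAX_ITER + 1):
        eta = np.clip(X1 @ beta, -35, 35)
        mu = special.expit(eta)
        w = np.maximum(mu * (1 - mu), 1e-12)
        grad = X1.T @ (y - mu) - lam_vec * beta
        hess = (X1 * w[:, None]).T @ X1 + np.diag(lam_vec)
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(hess, grad, rcond=None)[0]
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            converged = True
            break
    eta = np.clip(X1 @ beta, -35, 35)
    mu = special.expit(eta)
    w = np.maximum(mu * (1 - mu), 1e-12)
    hess = (X1 * w[:, None]).T @ X1 + np.diag(lam_vec)
    cov = np.linalg.pinv(hess)
    return beta, cov, converged, it


def _check_two_classes(y: np.ndarray) -> None:
    if y.min() == y.max():
        raise ValueError("outcome vector has a single class; cannot fit")


def fit_logistic(
    X: np.ndarray, y: np.ndarray, term_names: tuple[str, ...] | None = None
) -> FittedModel:
    """Maximum-likelihood logistic regression (IRLS, tol 1e-8, 100 iters).

    Complete separation raises :class:`SeparationError` naming the column
    with the largest diverging standardized coefficient.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-d")
    if np.isnan(X).any() or np.isnan(y).any():
        raise ValueError("rows must be complete (no NaN) for fitting")
    _check_two_classes(y)
    names = tuple(term_names) if term_names else tuple(f"x{j}" for j in range(X.shape[1]))
    X1 = np.column_stack([np.ones(len(X)), X])
    beta, cov, converged, it = _irls(X1, y, np.zeros(X1.shape[1]))
    scale = np.concatenate([[1.0], np.maximum(X.std(axis=0), 1e-12)])
    std_beta = beta * scale
    if not converged and np.max(np.abs(std_beta[1:])) > 50:
        j = int(np.argmax(np.abs(std_beta[1:])))
        raise SeparationError(names[j])
    if not np.all(np.isfinite(beta)):
        raise SeparationError(names[int(np.argmax(~np.isfinite(beta[1:])))])
    return FittedModel(
        term_names=names,
        intercept=float(beta[0]),
        coefs=beta[1:].copy(),
        lam=0.0,
        converged=converged,
        n_iter=it,
        n_obs=len(y),
        cov_unscaled=cov,
    )


def _bernoulli_deviance(y: np.ndarray, p: np.ndarray) -> float:
    p = np.clip(p, 1e-12, 1 - 1e-12)
    return float(-2.0 * np.sum(y * np.log(p) + (1 - y) * np.log(1 - p)))


def _fit_ridge_fixed(
    X: np.ndarray, y: np.ndarray, lam: float, names: tuple[str, ...]
) -> FittedModel:
    n, p = X.shape
    mean = X.mean(axis=0)
    sd = np.maximum(X.std(axis=0), 1e-12)
    Xs = (X - mean) / sd
    X1 = np.column_stack([np.ones(n), Xs])
    lam_vec = np.concatenate([[0.0], np.full(p, lam)])
    beta, cov, converged, it = _irls(X1, y, lam_vec)
    coefs = beta[1:] / sd
    intercept = float(beta[0] - np.sum(beta[1:] * mean / sd))
    if lam == 0.0:
        scale = np.concatenate([[1.0], np.ones(p)])
        if not converged and np.max(np.abs(beta[1:])) > 50:
            raise SeparationError(names[int(np.argmax(np.abs(beta[1:])))])
    return FittedModel(
        term_names=names,
        intercept=intercept,
        coefs=coefs,
        lam=float(lam),
        converged=converged,
        n_iter=it,
        n_obs=n,
        cov_unscaled=cov,
    )


def fit_ridge(
    X: np.ndarray,
    y: np.ndarray,
    lam: float | None = None,
    cv: CVConfig | None = None,
    seed: int = 0,
    term_names: tuple[str, ...] | None = None,
) -> FittedModel:
    """Ridge-penalized logistic regression.

    Give ``lam`` directly, or leave it ``None`` to select it by k-fold
    cross-validated deviance (fold assignment seeded by ``seed``) over
    ``cv.grid(n, p)``.  ``lam=0`` reproduces the maximum-likelihood fit.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.isnan(X).any() or np.isnan(y).any():
        raise ValueError("rows must be complete (no NaN) for fitting")
    _check_two_classes(y)
    names = tuple(term_names) if term_names else tuple(f"x{j}" for j in range(X.shape[1]))
    if lam is not None:
        if lam < 0:
            raise ValueError("lambda must be >= 0")
        return _fit_ridge_fixed(X, y, float(lam), names)

    cv = cv or CVConfig()
    n, p = X.shape
    grid = np.sort(cv.grid(n, p))[::-1]  # descending: warm starts shrink less
    rng = np.random.default_rng(int(seed) % 2**31)
    perm = rng.permutation(n)
    folds = np.array_split(perm, cv.k)
    mean = X.mean(axis=0)
    sd = np.maximum(X.std(axis=0), 1e-12)
    Xs1 = np.column_stack([np.ones(n), (X - mean) / sd])
    dev = np.zeros(len(grid))
    for fold in folds:
        test = np.zeros(n, dtype=bool)
        test[fold] = True
        ytr = y[~test]
        if ytr.min() == ytr.max():  # degenerate fold; skip its contribution
            continue
        beta = None
        for gi, g in enumerate(grid):
            lam_vec = np.concatenate([[0.0], np.full(p, g)])
            beta, _, _, _ = _irls(Xs1[~test], ytr, lam_vec, beta0=beta, tol=1e-6)
            pte = special.expit(np.clip(Xs1[test] @ beta, -35, 35))
            dev[gi] += _bernoulli_deviance(y[test], pte)
    best = int(np.argmin(dev))
    model = _fit_ridge_fixed(X, y, float(grid[best]), names)
    model.lam_trace = [(float(g), float(d)) for g, d in zip(grid, dev)]
    return model
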