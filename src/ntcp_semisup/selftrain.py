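"""Self-training wrapper: iterative pseudolabeling of unlabeled rows.

Each iteration fits the base learner on labeled + previously pseudolabeled
rows, predicts event probabilities for the remaining unlabeled rows, and
permanently pseudolabels every row whose confidence ``max(p, 1-p)`` reaches
the threshold (label 1 when ``p >= 0.5``).  Stops when an iteration adds
nothing, no unlabeled rows remain, or the iteration cap is hit.  With zero
unlabeled rows the result is bit-identical to the plain supervised fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .learners import CVConfig, FittedModel, fit_logistic, fit_ridge, predict_prob


@dataclass
class SelfTrainConfig:
    tau: float = 0.8
    max_iter: int = 50
    base: str = "logistic"  # "logistic" | "ridge"
    lam: float | None = None  # fixed ridge penalty; None -> CV per refit
    cv: CVConfig = field(default_factory=CVConfig)

    def validate(self) -> None:
        if not 0.5 < self.tau <= 1.0:
            raise ValueError(
                f"confidence threshold tau={self.tau} must be in (0.5, 1]; at tau<=0.5 "
                "every row qualifies with an ambiguous label"
            )
        if self.base not in ("logistic", "ridge"):
            raise ValueError(f"unknown base learner {self.base!r}")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")


@dataclass
class IterationRecord:
    iteration: int
    added_ids: np.ndarray
    added_labels: np.ndarray
    confidences: np.ndarray
    remaining: int
    errors: int | None = None  # vs. supplied true labels, when available


@dataclass
class SelfTrainTrace:
    iterations: list[IterationRecord] = field(default_factory=list)
    stopping_reason: str = ""
    initial_unlabeled: int = 0

    @property
    def total_pseudolabels(self) -> int:
        return int(sum(len(r.added_ids) for r in self.iterations))

    @property
    def total_errors(self) -> int | None:
        errs = [r.errors for r in self.iterations]
        return None if any(e is None for e in errs) else int(sum(errs))

    @property
    def n_iterations(self) -> int:
        return len(self.iterations)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "iteration": r.iteration,
                    "added": len(r.added_ids),
                    "remaining": r.remaining,
                    "errors": r.errors,
                }
                for r in self.iterations
            ]
        )


def _fit_base(config: SelfTrainConfig, X, y, names, seed):
    if config.base == "logistic":
        return fit_logistic(X, y, names)
    return fit_ridge(X, y, lam=config.lam, cv=config.cv, seed=seed, term_names=names)


def self_train(
    X_labeled: np.ndarray,
    y_labeled: np.ndarray,
    X_unlabeled: np.ndarray,
    config: SelfTrainConfig,
    seed: int = 0,
    term_names: tuple[str, ...] | None = None,
    true_unlabeled: np.ndarray | None = None,
) -> tuple[FittedModel, SelfTrainTrace]:
    """Run self-training; returns the final refit model and the full trace.

    ``true_unlabeled`` (optional, from the synthetic generator) enables
    per-iteration pseudolabel-error accounting in the trace.  Ridge refits
    re-select their penalty each iteration with seed ``seed + iteration``.
    """
    config.validate()
    X_labeled = np.asarray(X_labeled, dtype=float)
    y_labeled = np.asarray(y_labeled, dtype=float)
    X_unlabeled = np.asarray(X_unlabeled, dtype=float)
    if len(X_labeled) == 0:
        raise ValueError("labeled set is empty")
    if y_labeled.min() == y_labeled.max():
        raise ValueError("labeled set must contain both classes")

    n_u = len(X_unlabeled)
    trace = SelfTrainTrace(initial_unlabeled=n_u)
    pool_X = [X_labeled]
    pool_y = [y_labeled]
    remaining = np.arange(n_u)

    model = _fit_base(config, X_labeled, y_labeled, term_names, seed)
    if n_u == 0:
        trace.stopping_reason = "no unlabeled data"
        return model, trace

    for it in range(1, config.max_iter + 1):
        p = predict_prob(model, X_unlabeled[remaining])
        conf = np.maximum(p, 1 - p)
        take = conf >= config.tau
        if not take.any():
            trace.stopping_reason = "no pseudolabels added"
            break
        ids = remaining[take]
        labels = (p[take] >= 0.5).astype(float)
        errors = None
        if true_unlabeled is not None:
            errors = int(np.sum(labels != np.asarray(true_unlabeled, float)[ids]))
        pool_X.append(X_unlabeled[ids])
        pool_y.append(labels)
        remaining = remaining[~take]
        trace.iterations.append(
            IterationRecord(
                iteration=it,
                added_ids=ids,
                added_labels=labels,
                confidences=conf[take],
                remaining=len(remaining),
                errors=errors,
            )
        )
        model = _fit_base(
            config, np.vstack(pool_X), np.concatenate(pool_y), term_names,
            (seed + it) % 2**31,
        )
        if len(remaining) == 0:
            trace.stopping_reason = "no unlabeled data left"
            break
    else:
        trace.stopping_reason = "max iterations reached"
    if not trace.stopping_reason:
        trace.stopping_reason = "no pseudolabels added"
    return model, trace
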