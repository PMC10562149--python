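"""Predictor encodings for the four NTCP outcomes.

The xerostomia models use 4 predictor columns (submandibular mean dose, a
single combined sqrt-parotid term, two baseline-xerostomia dummies); the
dysphagia models use 8 (four organ mean doses, two baseline-dysphagia
dummies, two tumor-location dummies).  Both baseline dummies enter every
model regardless of the modeled grade, and the grade>=2/>=3 variants of a
toxicity share the same predictor set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml

from .config import OUTCOMES

OUTCOME_COLUMNS = {
    "xer_g2": "out_xer_g2",
    "xer_g3": "out_xer_g3",
    "dys_g2": "out_dys_g2",
    "dys_g3": "out_dys_g3",
}


@dataclass(frozen=True)
class Term:
    """One design column.

    ``transform`` is one of ``identity`` (a single numeric field used as-is),
    ``sqrt_sum`` (sum of square roots of the source fields, for nonnegative
    Gy doses), or ``dummy`` (a 0/1 flag taken as-is).
    """

    name: str
    sources: tuple[str, ...]
    transform: str = "identity"

    def evaluate(self, cohort: pd.DataFrame) -> np.ndarray:
        cols = [np.asarray(cohort[s], dtype=float) for s in self.sources]
        if self.transform in ("identity", "dummy"):
            (x,) = cols
            return x
        if self.transform == "sqrt_sum":
            for s, x in zip(self.sources, cols):
                if np.nanmin(x) < 0:
                    raise ValueError(f"sqrt transform requires nonnegative {s}")
            return sum(np.sqrt(x) for x in cols)
        raise ValueError(f"unknown transform {self.transform!r}")


@dataclass(frozen=True)
class ModelSpec:
    """Ordered predictor set for one outcome."""

    outcome: str
    terms: tuple[Term, ...]

    @property
    def term_names(self) -> tuple[str, ...]:
        return tuple(t.name for t in self.terms)

    @property
    def n_columns(self) -> int:
        return len(self.terms)

    def to_yaml(self, path) -> None:
        d = {
            "outcome": self.outcome,
            "terms": [
                {"name": t.name, "sources": list(t.sources), "transform": t.transform}
                for t in self.terms
            ],
        }
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ModelSpec":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        terms = tuple(
            Term(t["name"], tuple(t["sources"]), t.get("transform", "identity"))
            for t in d["terms"]
        )
        return cls(outcome=d["outcome"], terms=terms)


def xerostomia_spec(grade: int) -> ModelSpec:
    """4-column predictor set for xerostomia grade >=2 or >=3."""
    if grade not in (2, 3):
        raise ValueError("grade must be 2 or 3")
    terms = (
        Term("dose_submandibular", ("dose_submandibular",)),
        Term("sqrt_parotid_sum", ("dose_parotid_ipsi", "dose_parotid_contra"), "sqrt_sum"),
        Term("base_xer_g2", ("base_xer_g2",), "dummy"),
        Term("base_xer_g3", ("base_xer_g3",), "dummy"),
    )
    return ModelSpec(outcome=f"xer_g{grade}", terms=terms)


def dysphagia_spec(grade: int) -> ModelSpec:
    """8-column predictor set for dysphagia grade >=2 or >=3."""
    if grade not in (2, 3):
        raise ValueError("grade must be 2 or 3")
    terms = (
        Term("dose_oral_cavity", ("dose_oral_cavity",)),
        Term("dose_pcm_superior", ("dose_pcm_superior",)),
        Term("dose_pcm_medius", ("dose_pcm_medius",)),
        Term("dose_pcm_inferior", ("dose_pcm_inferior",)),
        Term("base_dys_g2", ("base_dys_g2",), "dummy"),
        Term("base_dys_g3", ("base_dys_g3",), "dummy"),
        Term("loc_pharynx", ("loc_pharynx",), "dummy"),
        Term("loc_larynx", ("loc_larynx",), "dummy"),
    )
    return ModelSpec(outcome=f"dys_g{grade}", terms=terms)


def spec_for(outcome: str) -> ModelSpec:
    """ModelSpec for any of the four outcome ids."""
    if outcome not in OUTCOMES:
        raise ValueError(f"unknown outcome {outcome!r}; expected one of {OUTCOMES}")
    tox, grade = outcome.split("_g")
    return xerostomia_spec(int(grade)) if tox == "xer" else dysphagia_spec(int(grade))


def build_design(
    cohort: pd.DataFrame, spec: ModelSpec
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Design matrix, outcome vector and labeled mask for a cohort.

    Returns ``(X, y, labeled)`` where ``X`` is ``(n, p)`` float, ``y`` is the
    outcome with ``NaN`` wherever it is hidden (missing or unlabeled), and
    ``labeled`` flags rows whose outcome is observed and not masked.  Raises
    ``ValueError`` naming the first offending row/field if a required
    predictor source is missing.
    """
    n = len(cohort)
    p = spec.n_columns
    if n == 0:
        return np.empty((0, p)), np.empty(0), np.empty(0, dtype=bool)
    for term in spec.terms:
        for src in term.sources:
            col = np.asarray(cohort[src], dtype=float)
            if np.isnan(col).any():
                row = cohort.index[int(np.flatnonzero(np.isnan(col))[0])]
                raise ValueError(f"missing value in required field {src!r} at row {row}")
    X = np.column_stack([t.evaluate(cohort) for t in spec.terms])
    y = np.asarray(cohort[OUTCOME_COLUMNS[spec.outcome]], dtype=float)
    unlabeled = (
        np.asarray(cohort["unlabeled"], dtype=bool)
        if "unlabeled" in cohort.columns
        else np.zeros(n, dtype=bool)
    )
    y = y.copy()
    y[unlabeled] = np.nan
    labeled = ~np.isnan(y) & ~unlabeled
    return X, y, labeled
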