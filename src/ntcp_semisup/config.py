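"""Generator configuration for synthetic head-and-neck radiotherapy cohorts.

The generator emulates the statistical structure of the Dutch multi-center
NTCP cohorts used to model 6-month xerostomia and dysphagia: correlated mean
organ doses (Gy), binary patient covariates, baseline toxicity flags, and
6-month toxicity outcomes drawn from logistic dose-toxicity models whose
intercepts are calibrated to target marginal rates.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import yaml

#: Organ order used everywhere doses appear as a vector.
ORGANS = (
    "submandibular",
    "parotid_ipsi",
    "parotid_contra",
    "oral_cavity",
    "pcm_superior",
    "pcm_medius",
    "pcm_inferior",
)

#: The four modeled outcomes: toxicity dichotomized at grade >=2 and >=3.
OUTCOMES = ("xer_g2", "xer_g3", "dys_g2", "dys_g3")

#: Baseline toxicity flags (same dichotomization, pre-treatment).
BASELINE_FIELDS = ("base_xer_g2", "base_xer_g3", "base_dys_g2", "base_dys_g3")

#: Field groups that may carry missingness; each group blanks its two grade
#: flags jointly (missingness acts on the underlying toxicity grade).
MISSINGNESS_GROUPS = (
    "baseline_xerostomia",
    "baseline_dysphagia",
    "outcome_xerostomia",
    "outcome_dysphagia",
)

GROUP_COLUMNS = {
    "baseline_xerostomia": ("base_xer_g2", "base_xer_g3"),
    "baseline_dysphagia": ("base_dys_g2", "base_dys_g3"),
    "outcome_xerostomia": ("out_xer_g2", "out_xer_g3"),
    "outcome_dysphagia": ("out_dys_g2", "out_dys_g3"),
}

DOSE_TRUNCATION = (0.0, 80.0)  # physical mean-dose range in Gy


def default_dose_corr() -> np.ndarray:
    """Default correlation across organ mean doses.

    Anatomically adjacent organs share dose: 0.5 between the three pharyngeal
    constrictor muscles, 0.4 between the parotid pair, 0.2 elsewhere.
    """
    k = len(ORGANS)
    corr = np.full((k, k), 0.2)
    np.fill_diagonal(corr, 1.0)
    i_pi, i_pc = ORGANS.index("parotid_ipsi"), ORGANS.index("parotid_contra")
    corr[i_pi, i_pc] = corr[i_pc, i_pi] = 0.4
    pcm = [ORGANS.index(o) for o in ("pcm_superior", "pcm_medius", "pcm_inferior")]
    for a in pcm:
        for b in pcm:
            if a != b:
                corr[a, b] = 0.5
    return corr


# True slope vectors of the synthetic data-generating process, keyed by the
# design-term names of each outcome's predictor set.  Magnitudes were sized so
# the true model's large-sample AUC falls in 0.68-0.75; they are generator
# defaults, not estimates from any patient data.  Both grade dichotomizations
# of a toxicity share slopes, which (with calibrated intercepts) makes the
# grade>=3 risk nested below grade>=2 pointwise.
_XER_SLOPES = {
    "dose_submandibular": 0.022,
    "sqrt_parotid_sum": 0.13,
    "base_xer_g2": 0.9,
    "base_xer_g3": 0.5,
}
_DYS_SLOPES = {
    "dose_oral_cavity": 0.016,
    "dose_pcm_superior": 0.0176,
    "dose_pcm_medius": 0.0128,
    "dose_pcm_inferior": 0.0096,
    "base_dys_g2": 0.9,
    "base_dys_g3": 0.5,
    "loc_pharynx": 0.44,
    "loc_larynx": 0.20,
}

DEFAULT_TRUE_COEFFICIENTS = {
    "xer_g2": dict(_XER_SLOPES),
    "xer_g3": dict(_XER_SLOPES),
    "dys_g2": dict(_DYS_SLOPES),
    "dys_g3": dict(_DYS_SLOPES),
}


@dataclass
class GeneratorConfig:
    """All parameters of the synthetic cohort generator.

    Dose means/sds are in Gy per organ (:data:`ORGANS` order after conversion
    with :meth:`dose_mean_vector`); prevalences and missing rates are
    proportions in [0, 1].  ``center_dose_shifts`` / ``center_logit_shifts``
    are additive offsets per center on every organ's mean dose (Gy) and on the
    outcome-model intercepts (logit scale).
    """

    n: int = 750
    dose_means: dict[str, float] = field(default_factory=dict)
    dose_sds: dict[str, float] = field(default_factory=dict)
    dose_corr: np.ndarray = field(default_factory=default_dose_corr)
    covariate_prevalences: dict[str, float] = field(default_factory=dict)
    baseline_tox_prevalences: dict[str, float] = field(default_factory=dict)
    true_coefficients: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_TRUE_COEFFICIENTS.items()}
    )
    target_prevalences: dict[str, float] = field(default_factory=dict)
    missing_rates: dict[str, float] = field(default_factory=dict)
    centers: tuple[str, ...] = ("UMCG",)
    center_sizes: tuple[int, ...] | None = None
    center_dose_shifts: tuple[float, ...] = (0.0,)
    center_logit_shifts: tuple[float, ...] = (0.0,)
    age_mean: float = 63.1
    age_sd: float = 10.2
    calibration_n: int = 100_000
    seed: int = 0

    def validate(self) -> None:
        if len(self.dose_means) != len(ORGANS) or len(self.dose_sds) != len(ORGANS):
            raise ValueError("dose_means/dose_sds must cover all organs: %s" % (ORGANS,))
        if any(s <= 0 for s in self.dose_sds.values()):
            raise ValueError("dose_sds must be > 0")
        corr = np.asarray(self.dose_corr, dtype=float)
        if corr.shape != (len(ORGANS), len(ORGANS)):
            raise ValueError("dose_corr must be %dx%d" % (len(ORGANS), len(ORGANS)))
        if not np.allclose(corr, corr.T, atol=1e-10):
            raise ValueError("dose_corr must be symmetric")
        if not np.allclose(np.diag(corr), 1.0):
            raise ValueError("dose_corr must have unit diagonal")
        eigmin = float(np.linalg.eigvalsh(corr).min())
        if eigmin < -1e-8:
            raise ValueError(
                "dose_corr is not positive semi-definite (min eigenvalue %.3g)" % eigmin
            )
        for name, val in {
            **self.covariate_prevalences,
            **self.baseline_tox_prevalences,
            **self.missing_rates,
        }.items():
            if not 0.0 <= val <= 1.0:
                raise ValueError(f"proportion {name}={val} outside [0, 1]")
        for out, prev in self.target_prevalences.items():
            if not 0.0 < prev < 1.0:
                raise ValueError(
                    f"target prevalence for {out} must be strictly inside (0, 1), got {prev}"
                )
        sizes = self.resolved_center_sizes()
        if sum(sizes) != self.n:
            raise ValueError("center sizes must sum to n")
        if not (len(self.centers) == len(sizes) == len(self.center_dose_shifts)
                == len(self.center_logit_shifts)):
            raise ValueError("center arrays must have equal length")

    def resolved_center_sizes(self) -> tuple[int, ...]:
        if self.center_sizes is not None:
            return tuple(self.center_sizes)
        k = len(self.centers)
        base = self.n // k
        sizes = [base + (1 if i < self.n - base * k else 0) for i in range(k)]
        return tuple(sizes)

    def dose_mean_vector(self) -> np.ndarray:
        return np.array([self.dose_means[o] for o in ORGANS], dtype=float)

    def dose_sd_vector(self) -> np.ndarray:
        return np.array([self.dose_sds[o] for o in ORGANS], dtype=float)

    # ------------------------------------------------------------------ YAML
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["dose_corr"] = np.asarray(self.dose_corr).tolist()
        for key in ("centers", "center_sizes", "center_dose_shifts", "center_logit_shifts"):
            if d[key] is not None:
                d[key] = list(d[key])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        d = dict(d)
        if "dose_corr" in d:
            d["dose_corr"] = np.asarray(d["dose_corr"], dtype=float)
        for key in ("centers", "center_dose_shifts", "center_logit_shifts"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        if d.get("center_sizes") is not None:
            d["center_sizes"] = tuple(d["center_sizes"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def development_config(n: int = 750, seed: int = 0) -> GeneratorConfig:
    """Default single-center development cohort (n=750).

    Dose marginals, covariate prevalences, baseline/outcome toxicity rates and
    missing-data rates follow the published development-cohort description;
    the oral-cavity dose marginal and the ipsilateral/contralateral parotid
    split are generator defaults (the source table pools the parotid glands
    and omits the oral cavity).
    """
    return GeneratorConfig(
        n=n,
        dose_means={
            "submandibular": 48.5,
            "parotid_ipsi": 51.7,
            "parotid_contra": 51.7,
            "oral_cavity": 46.0,
            "pcm_superior": 42.9,
            "pcm_medius": 48.7,
            "pcm_inferior": 54.7,
        },
        dose_sds={
            "submandibular": 22.9,
            "parotid_ipsi": 32.0,
            "parotid_contra": 32.0,
            "oral_cavity": 21.0,
            "pcm_superior": 24.1,
            "pcm_medius": 20.3,
            "pcm_inferior": 13.0,
        },
        covariate_prevalences={
            "sex_male": 0.75,
            "stage_t34": 0.52,
            "loc_pharynx": 0.50,
            "loc_larynx": 0.45,
        },
        baseline_tox_prevalences={
            "base_xer_g2": 0.11,
            "base_xer_g3": 0.02,
            "base_dys_g2": 0.24,
            "base_dys_g3": 0.08,
        },
        target_prevalences={
            "xer_g2": 0.44,
            "xer_g3": 0.13,
            "dys_g2": 0.29,
            "dys_g3": 0.15,
        },
        missing_rates={
            "baseline_xerostomia": 0.11,
            "baseline_dysphagia": 0.02,
            "outcome_xerostomia": 0.21,
            "outcome_dysphagia": 0.16,
        },
        age_mean=63.1,
        age_sd=10.2,
        seed=seed,
    )


def validation_config(n: int = 395, seed: int = 0) -> GeneratorConfig:
    """Default three-center validation cohort (n=395).

    Marginals follow the published validation-cohort column; per-center
    composition is not published, so centers split the cohort in near-equal
    thirds with modest symmetric dose shifts (+-2 Gy) as default case-mix
    differences.
    """
    return GeneratorConfig(
        n=n,
        dose_means={
            "submandibular": 44.7,
            "parotid_ipsi": 51.7,
            "parotid_contra": 51.7,
            "oral_cavity": 44.0,
            "pcm_superior": 38.7,
            "pcm_medius": 49.4,
            "pcm_inferior": 53.0,
        },
        dose_sds={
            "submandibular": 20.7,
            "parotid_ipsi": 32.0,
            "parotid_contra": 32.0,
            "oral_cavity": 21.0,
            "pcm_superior": 23.0,
            "pcm_medius": 20.1,
            "pcm_inferior": 14.1,
        },
        covariate_prevalences={
            "sex_male": 0.73,
            "stage_t34": 0.51,
            "loc_pharynx": 0.52,
            "loc_larynx": 0.43,
        },
        baseline_tox_prevalences={
            "base_xer_g2": 0.18,
            "base_xer_g3": 0.07,
            "base_dys_g2": 0.22,
            "base_dys_g3": 0.05,
        },
        target_prevalences={
            "xer_g2": 0.48,
            "xer_g3": 0.15,
            "dys_g2": 0.19,
            "dys_g3": 0.06,
        },
        missing_rates={
            "baseline_xerostomia": 0.25,
            "baseline_dysphagia": 0.0,
            "outcome_xerostomia": 0.51,
            "outcome_dysphagia": 0.18,
        },
        centers=("UMCG", "Maastro", "RIF"),
        center_dose_shifts=(-2.0, 0.0, 2.0),
        center_logit_shifts=(0.0, 0.0, 0.0),
        age_mean=64.0,
        age_sd=9.4,
        seed=seed,
    )
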