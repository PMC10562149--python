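"""Synthetic cohort generation: correlated doses, covariates, outcomes, MAR
amputation and label masking.

Doses are drawn through a Gaussian copula whose marginals are normal
distributions truncated to [0, 80] Gy; pre-truncation parameters are adjusted
numerically so the post-truncation mean matches the configured target exactly
and the sd as closely as the truncated family allows.  Outcomes use a shared
latent uniform per toxicity so the grade>=3 flag is nested within grade>=2 by
construction.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .config import (
    DOSE_TRUNCATION,
    GROUP_COLUMNS,
    MISSINGNESS_GROUPS,
    ORGANS,
    OUTCOMES,
    GeneratorConfig,
)
from .design import spec_for

DOSE_COLUMNS = tuple(f"dose_{o}" for o in ORGANS)

#: Column order of a generated cohort table.
COHORT_COLUMNS = (
    ("id", "center", "age", "sex_male", "stage_t34", "loc_pharynx", "loc_larynx")
    + DOSE_COLUMNS
    + ("base_xer_g2", "base_xer_g3", "base_dys_g2", "base_dys_g3")
    + ("out_xer_g2", "out_xer_g3", "out_dys_g2", "out_dys_g3")
    + ("unlabeled",)
    + tuple(f"truth_out_{o}" for o in OUTCOMES)
    + tuple(f"ptrue_{o}" for o in OUTCOMES)
)


# --------------------------------------------------------------------------
# truncated-normal moment matching
# --------------------------------------------------------------------------

def _trunc_stats(mu: float, sigma: float) -> tuple[float, float]:
    lo, hi = DOSE_TRUNCATION
    a, b = (lo - mu) / sigma, (hi - mu) / sigma
    m, v = stats.truncnorm.stats(a, b, loc=mu, scale=sigma, moments="mv")
    return float(m), float(np.sqrt(v))


def _safe_trunc_mean(mu: float, sigma: float) -> float:
    lo, hi = DOSE_TRUNCATION
    m = _trunc_stats(mu, sigma)[0]
    if not np.isfinite(m):
        # far outside the window the truncated mass piles at the nearer bound
        return lo if mu < (lo + hi) / 2 else hi
    return m


def _mu_for_mean(target_mean: float, sigma: float) -> float:
    # truncated mean is strictly increasing in mu with range (lo, hi)
    lo, hi = DOSE_TRUNCATION
    half = 50.0 * sigma + 100.0
    return optimize.brentq(
        lambda mu: _safe_trunc_mean(mu, sigma) - target_mean,
        lo - half, hi + half, xtol=1e-8,
    )


@lru_cache(maxsize=256)
def truncnorm_match(target_mean: float, target_sd: float) -> tuple[float, float]:
    """Pre-truncation (mu, sigma) whose [0, 80]-truncated law has the target
    mean exactly and an sd as close as possible to ``target_sd``.

    Target sds above what a truncated normal on [0, 80] can reach (~23 Gy)
    are matched at the achievable maximum.
    """
    lo, hi = DOSE_TRUNCATION
    if not lo < target_mean < hi:
        raise ValueError(f"target mean {target_mean} outside truncation range {DOSE_TRUNCATION}")

    def sd_gap(log_sigma: float) -> float:
        sigma = float(np.exp(log_sigma))
        mu = _mu_for_mean(target_mean, sigma)
        return (_trunc_stats(mu, sigma)[1] - target_sd) ** 2

    res = optimize.minimize_scalar(
        sd_gap, bounds=(np.log(0.5), np.log(150.0)), method="bounded",
        options={"xatol": 1e-6},
    )
    sigma = float(np.exp(res.x))
    mu = _mu_for_mean(target_mean, sigma)
    return mu, sigma


def _sample_doses(
    rng: np.random.Generator,
    n: int,
    means: np.ndarray,
    sds: np.ndarray,
    corr: np.ndarray,
) -> np.ndarray:
    """Gaussian-copula draw of the organ-dose matrix (n x 7)."""
    lo, hi = DOSE_TRUNCATION
    chol = np.linalg.cholesky(corr + 1e-12 * np.eye(len(ORGANS)))
    z = rng.standard_normal((n, len(ORGANS))) @ chol.T
    u = special.ndtr(z)
    doses = np.empty_like(z)
    for j in range(len(ORGANS)):
        mu, sigma = truncnorm_match(round(float(means[j]), 6), round(float(sds[j]), 6))
        a, b = (lo - mu) / sigma, (hi - mu) / sigma
        doses[:, j] = stats.truncnorm.ppf(u[:, j], a, b, loc=mu, scale=sigma)
    return doses


# --------------------------------------------------------------------------
# covariates and intercept calibration
# --------------------------------------------------------------------------

def _sample_covariates(rng: np.random.Generator, config: GeneratorConfig) -> pd.DataFrame:
    """Covariates, doses and baseline toxicities for the full cohort."""
    config.validate()
    sizes = config.resolved_center_sizes()
    frames = []
    prev = config.covariate_prevalences
    p_pha, p_lar = prev["loc_pharynx"], prev["loc_larynx"]
    for center, size, dshift in zip(config.centers, sizes, config.center_dose_shifts):
        age = np.clip(rng.normal(config.age_mean, config.age_sd, size), 18.0, 95.0)
        sex = (rng.random(size) < prev["sex_male"]).astype(int)
        stage = (rng.random(size) < prev["stage_t34"]).astype(int)
        loc_u = rng.random(size)
        loc_pharynx = (loc_u < p_pha).astype(int)
        loc_larynx = ((loc_u >= p_pha) & (loc_u < p_pha + p_lar)).astype(int)
        means = np.clip(config.dose_mean_vector() + dshift, 1e-6, DOSE_TRUNCATION[1] - 1e-6)
        doses = _sample_doses(rng, size, means, config.dose_sd_vector(), np.asarray(config.dose_corr, float))
        frame = pd.DataFrame(
            {
                "center": center,
                "age": age,
                "sex_male": sex,
                "stage_t34": stage,
                "loc_pharynx": loc_pharynx,
                "loc_larynx": loc_larynx,
            }
        )
        for j, col in enumerate(DOSE_COLUMNS):
            frame[col] = doses[:, j]
        frames.append(frame)
    out = pd.concat(frames, ignore_index=True)

    # baseline toxicity via a shared latent uniform per toxicity: guarantees
    # grade>=3 => grade>=2
    base = config.baseline_tox_prevalences
    for tox in ("xer", "dys"):
        u = rng.random(len(out))
        p2, p3 = base[f"base_{tox}_g2"], base[f"base_{tox}_g3"]
        out[f"base_{tox}_g2"] = (u < max(p2, p3)).astype(int)
        out[f"base_{tox}_g3"] = (u < min(p2, p3)).astype(int)
    return out


def _linear_predictor(cov: pd.DataFrame, config: GeneratorConfig, outcome: str) -> np.ndarray:
    """Slope part of the true logistic model, including center logit shifts."""
    spec = spec_for(outcome)
    coefs = config.true_coefficients[outcome]
    X = np.column_stack([t.evaluate(cov) for t in spec.terms])
    beta = np.array([coefs[name] for name in spec.term_names])
    eta = X @ beta
    shift_by_center = dict(zip(config.centers, config.center_logit_shifts))
    eta = eta + np.asarray(cov["center"].map(shift_by_center), dtype=float)
    return eta


_calibration_cache: dict[tuple, float] = {}
_cal_sample_cache: dict[tuple, pd.DataFrame] = {}


def _config_key(config: GeneratorConfig) -> tuple:
    d = config.to_dict()
    d.pop("n"), d.pop("seed"), d.pop("missing_rates")

    def freeze(x):
        if isinstance(x, dict):
            return tuple(sorted((k, freeze(v)) for k, v in x.items()))
        if isinstance(x, (list, tuple)):
            return tuple(freeze(v) for v in x)
        return x

    return freeze(d)


def calibrate_intercept(
    config: GeneratorConfig, outcome: str, tolerance: float = 5e-3
) -> float:
    """Intercept beta0 making the marginal outcome rate match its target.

    The marginal rate ``E[expit(beta0 + X beta)]`` is estimated on a large
    Monte-Carlo covariate sample (``config.calibration_n`` patients, seed
    derived from ``config.seed``) and beta0 found by monotone root-finding.
    Raises ``ValueError`` when the target cannot be bracketed or the residual
    exceeds ``tolerance``.
    """
    if outcome not in OUTCOMES:
        raise ValueError(f"unknown outcome {outcome!r}")
    if tolerance <= 0:
        raise ValueError("tolerance must be > 0")
    target = config.target_prevalences[outcome]
    if not 0.0 < target < 1.0:
        raise ValueError(f"target prevalence for {outcome} must be in (0, 1)")

    ckey = _config_key(config)
    key = (ckey, outcome)
    if key in _calibration_cache:
        return _calibration_cache[key]

    if ckey not in _cal_sample_cache:
        # calibration sample keeps the center mix proportional at calibration_n
        cal_cfg = GeneratorConfig.from_dict(
            {**config.to_dict(), "n": config.calibration_n, "center_sizes": None}
        )
        rng = np.random.default_rng(
            np.random.SeedSequence([int(config.seed) % 2**31, 987_001])
        )
        _cal_sample_cache[ckey] = _sample_covariates(rng, cal_cfg)
        if len(_cal_sample_cache) > 8:  # bound memory across many configs
            _cal_sample_cache.pop(next(iter(_cal_sample_cache)))
    cov = _cal_sample_cache[ckey]
    eta = _linear_predictor(cov, config, outcome)

    def rate(b0: float) -> float:
        return float(np.mean(special.expit(b0 + eta)))

    lo, hi = -30.0, 30.0
    if not (rate(lo) - target) * (rate(hi) - target) < 0:
        raise ValueError(
            f"cannot bracket intercept for {outcome}: target {target} unreachable "
            f"given the configured slopes (rate range [{rate(lo):.4g}, {rate(hi):.4g}])"
        )
    b0 = optimize.brentq(lambda b: rate(b) - target, lo, hi, xtol=1e-10)
    if abs(rate(b0) - target) > tolerance:
        raise ValueError(f"intercept calibration for {outcome} missed tolerance {tolerance}")
    _calibration_cache[key] = float(b0)
    return float(b0)


# --------------------------------------------------------------------------
# cohort generation
# --------------------------------------------------------------------------

def generate_cohort(config: GeneratorConfig, seed: int | None = None) -> pd.DataFrame:
    """Complete synthetic cohort (no missing values, no label mask).

    Outcomes for the two grade levels of a toxicity are drawn from one shared
    uniform against their respective calibrated logistic risks, so the
    grade>=3 flag never exceeds grade>=2.  True outcome values and true risks
    are kept in ``truth_out_*`` / ``ptrue_*`` columns for downstream
    pseudolabel-correctness accounting.
    """
    config.validate()
    if seed is None:
        seed = config.seed
    intercepts = {o: calibrate_intercept(config, o) for o in OUTCOMES}

    rng = np.random.default_rng(np.random.SeedSequence([int(seed) % 2**31, 12_001]))
    cov = _sample_covariates(rng, config)
    n = len(cov)
    cov.insert(0, "id", np.arange(1, n + 1))

    p = {o: special.expit(intercepts[o] + _linear_predictor(cov, config, o)) for o in OUTCOMES}
    for tox in ("xer", "dys"):
        u = rng.random(n)
        p2, p3 = p[f"{tox}_g2"], p[f"{tox}_g3"]
        hi_p, lo_p = np.maximum(p2, p3), np.minimum(p2, p3)
        cov[f"out_{tox}_g2"] = (u < hi_p).astype(float)
        cov[f"out_{tox}_g3"] = (u < lo_p).astype(float)
    cov["unlabeled"] = 0
    for o in OUTCOMES:
        cov[f"truth_out_{o}"] = cov[f"out_{o}"].astype(float)
        cov[f"ptrue_{o}"] = p[o]
    return cov.loc[:, list(COHORT_COLUMNS)]


# --------------------------------------------------------------------------
# MAR amputation
# --------------------------------------------------------------------------

#: MAR score slopes on always-observed fields (per year of age, per stage
#: class, per standardized mean organ dose).
_MAR_SLOPES = {"age": 0.03, "stage": 0.5, "dose": 0.3}


def _mar_score(cohort: pd.DataFrame) -> np.ndarray:
    age = np.asarray(cohort["age"], dtype=float)
    stage = np.asarray(cohort["stage_t34"], dtype=float)
    mean_dose = np.asarray(cohort.loc[:, list(DOSE_COLUMNS)], dtype=float).mean(axis=1)
    z_dose = (mean_dose - mean_dose.mean()) / max(mean_dose.std(), 1e-12)
    return (
        _MAR_SLOPES["age"] * (age - age.mean())
        + _MAR_SLOPES["stage"] * stage
        + _MAR_SLOPES["dose"] * z_dose
    )


def ampute(
    cohort: pd.DataFrame, missing_rates: dict[str, float], seed: int
) -> pd.DataFrame:
    """Set baseline/outcome toxicity fields missing under a MAR mechanism.

    Missingness probability depends only on always-observed fields (age,
    stage, mean organ dose) through a logistic model whose intercept is
    calibrated so the realized rate matches the target.  Both grade flags of
    a toxicity/timepoint are blanked jointly.  Rates must be keyed by the
    four missingness groups; naming an always-observed field is an error.
    """
    bad = set(missing_rates) - set(MISSINGNESS_GROUPS)
    if bad:
        raise ValueError(
            f"missing rates allowed only for {MISSINGNESS_GROUPS}; got {sorted(bad)} "
            "(demographics and doses are always observed)"
        )
    out = cohort.copy()
    score = _mar_score(cohort)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed) % 2**31, 34_001]))
    for group in MISSINGNESS_GROUPS:
        rate = float(missing_rates.get(group, 0.0))
        if rate == 0.0:
            continue
        if not 0.0 < rate < 1.0:
            raise ValueError(f"missing rate for {group} must be in [0, 1)")
        a = optimize.brentq(
            lambda b: float(np.mean(special.expit(b + score))) - rate, -30, 30
        )
        miss = rng.random(len(out)) < special.expit(a + score)
        for col in GROUP_COLUMNS[group]:
            out.loc[miss, col] = np.nan
    return out


# --------------------------------------------------------------------------
# label masking
# --------------------------------------------------------------------------

OUTCOME_COLS = tuple(f"out_{o}" for o in OUTCOMES)
PREMASK_COLS = tuple(f"premask_out_{o}" for o in OUTCOMES)


def mask_labels(cohort: pd.DataFrame, k: int, seed: int) -> pd.DataFrame:
    """Flag exactly ``k`` uniformly chosen rows (with observed outcomes) as
    unlabeled; hide their outcomes but retain the pre-mask values in
    ``premask_out_*`` for bookkeeping."""
    if k < 0:
        raise ValueError("k must be nonnegative")
    out = cohort.copy()
    observed = ~out.loc[:, list(OUTCOME_COLS)].isna().any(axis=1)
    eligible = out.index[observed & (out["unlabeled"] == 0)]
    if k > len(eligible):
        raise ValueError(f"k={k} exceeds the {len(eligible)} rows with observed outcomes")
    for oc, pc in zip(OUTCOME_COLS, PREMASK_COLS):
        if pc not in out.columns:
            out[pc] = out[oc]
    if k == 0:
        return out
    rng = np.random.default_rng(np.random.SeedSequence([int(seed) % 2**31, 56_001]))
    chosen = rng.choice(np.asarray(eligible), size=k, replace=False)
    for oc, pc in zip(OUTCOME_COLS, PREMASK_COLS):
        out.loc[chosen, pc] = out.loc[chosen, oc]
        out.loc[chosen, oc] = np.nan
    out.loc[chosen, "unlabeled"] = 1
    return out


# --------------------------------------------------------------------------
# CSV round trip
# --------------------------------------------------------------------------

def write_cohort_csv(cohort: pd.DataFrame, path) -> None:
    """One row per patient; missing values as empty cells."""
    cohort.to_csv(path, index=False)


def read_cohort_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)
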