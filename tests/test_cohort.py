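"""Synthetic cohort generator: marginals, calibration, amputation, masking."""

import numpy as np
import pandas as pd
import pytest
from scipy import special

from ntcp_semisup.cohort import (
    DOSE_COLUMNS,
    ampute,
    calibrate_intercept,
    generate_cohort,
    mask_labels,
    truncnorm_match,
    _sample_covariates,
    _linear_predictor,
)
from ntcp_semisup.config import (
    ORGANS,
    OUTCOMES,
    GeneratorConfig,
    development_config,
    validation_config,
)


def _zero_slope_config(n=5000, target=0.5):
    cfg = development_config(n=n)
    for o in OUTCOMES:
        cfg.true_coefficients[o] = {k: 0.0 for k in cfg.true_coefficients[o]}
        cfg.target_prevalences[o] = target
    cfg.calibration_n = 20_000
    return cfg


class TestGeneration:
    def test_submandibular_dose_marginal_matches_target(self, dev_big):
        dose = dev_big["dose_submandibular"]
        assert abs(dose.mean() - 48.5) < 0.5
        # sd 22.9 is achievable inside [0, 80]; matched closely
        assert abs(dose.std() - 22.9) < 1.0

    def test_doses_physical(self, dev_big):
        doses = dev_big.loc[:, list(DOSE_COLUMNS)]
        assert float(doses.min().min()) >= 0.0
        assert float(doses.max().max()) <= 80.0

    def test_zero_slopes_gives_flat_half_rate(self):
        cfg = _zero_slope_config()
        coh = generate_cohort(cfg, seed=5)
        rate = coh["out_xer_g2"].mean()
        assert abs(rate - 0.5) < 0.03
        # outcome independent of dose when slopes are zero
        r = np.corrcoef(coh["dose_submandibular"], coh["out_xer_g2"])[0, 1]
        assert abs(r) < 0.04

    def test_seed_determinism(self, dev_config):
        a = generate_cohort(dev_config, seed=42)
        b = generate_cohort(dev_config, seed=42)
        pd.testing.assert_frame_equal(a, b, check_exact=True)

    def test_different_seeds_differ(self, dev_config):
        a = generate_cohort(dev_config, seed=1)
        b = generate_cohort(dev_config, seed=2)
        assert not a["dose_submandibular"].equals(b["dose_submandibular"])

    def test_grade_hierarchy_never_violated(self, dev_big):
        for tox in ("xer", "dys"):
            assert (dev_big[f"out_{tox}_g3"] <= dev_big[f"out_{tox}_g2"]).all()
            assert (dev_big[f"base_{tox}_g3"] <= dev_big[f"base_{tox}_g2"]).all()

    def test_intercept_recovery_all_outcomes(self, dev_big, dev_config):
        for o, target in dev_config.target_prevalences.items():
            assert abs(dev_big[f"out_{o}"].mean() - target) < 0.01

    def test_dose_correlation_recovery(self, dev_big, dev_config):
        sample = np.corrcoef(np.asarray(dev_big.loc[:, list(DOSE_COLUMNS)]).T)
        target = np.asarray(dev_config.dose_corr)
        assert np.max(np.abs(sample - target)) < 0.05

    def test_truth_columns_copy_outcomes(self, dev_cohort):
        for o in OUTCOMES:
            assert dev_cohort[f"truth_out_{o}"].equals(dev_cohort[f"out_{o}"])

    def test_nonpsd_correlation_rejected(self, dev_config):
        cfg = development_config()
        corr = np.asarray(cfg.dose_corr).copy()
        corr[0, 1] = corr[1, 0] = 0.99
        corr[0, 2] = corr[2, 0] = 0.99
        corr[1, 2] = corr[2, 1] = -0.99
        cfg.dose_corr = corr
        with pytest.raises(ValueError, match="positive semi-definite"):
            generate_cohort(cfg, seed=0)

    def test_degenerate_target_prevalence_rejected(self):
        cfg = development_config()
        cfg.target_prevalences["xer_g2"] = 1.0
        with pytest.raises(ValueError, match="\\(0, 1\\)"):
            generate_cohort(cfg, seed=0)


class TestTruncnormMatch:
    def test_mean_matched_exactly(self):
        from scipy import stats

        mu, sigma = truncnorm_match(22.0, 10.0)
        a, b = (0 - mu) / sigma, (80 - mu) / sigma
        m, v = stats.truncnorm.stats(a, b, loc=mu, scale=sigma, moments="mv")
        assert abs(float(m) - 22.0) < 1e-5
        assert abs(float(np.sqrt(v)) - 10.0) < 0.05

    def test_mean_matched_when_sd_infeasible(self):
        # at mean 48.5 the truncated-normal sd on [0, 80] tops out near 22.1;
        # the matcher still nails the mean and gets as close as the family allows
        from scipy import stats

        mu, sigma = truncnorm_match(48.5, 22.9)
        a, b = (0 - mu) / sigma, (80 - mu) / sigma
        m, v = stats.truncnorm.stats(a, b, loc=mu, scale=sigma, moments="mv")
        assert abs(float(m) - 48.5) < 1e-5
        assert 21.5 < float(np.sqrt(v)) < 23.0

    def test_unattainable_sd_hits_feasible_maximum(self):
        from scipy import stats

        mu, sigma = truncnorm_match(51.7, 32.0)
        a, b = (0 - mu) / sigma, (80 - mu) / sigma
        m, v = stats.truncnorm.stats(a, b, loc=mu, scale=sigma, moments="mv")
        assert abs(float(m) - 51.7) < 1e-5
        assert 20.0 < float(np.sqrt(v)) <= 23.5  # below the uniform-limit cap


class TestCalibrateIntercept:
    def test_closed_form_when_slopes_zero(self):
        cfg = _zero_slope_config(target=0.44)
        b0 = calibrate_intercept(cfg, "xer_g2")
        assert abs(b0 - np.log(0.44 / 0.56)) < 0.02

    def test_monte_carlo_oracle(self):
        """Independent fresh simulation reproduces the calibrated rate."""
        cfg = development_config()
        cfg.target_prevalences["dys_g2"] = 0.29
        b0 = calibrate_intercept(cfg, "dys_g2")
        oracle_cfg = GeneratorConfig.from_dict({**cfg.to_dict(), "n": 100_000})
        rng = np.random.default_rng(777)
        cov = _sample_covariates(rng, oracle_cfg)
        rate = special.expit(b0 + _linear_predictor(cov, cfg, "dys_g2")).mean()
        assert abs(rate - 0.29) < 0.01

    def test_rate_monotone_in_intercept(self):
        cfg = development_config()
        rng = np.random.default_rng(3)
        cov = _sample_covariates(rng, GeneratorConfig.from_dict({**cfg.to_dict(), "n": 2000}))
        eta = _linear_predictor(cov, cfg, "xer_g2")
        rates = [special.expit(b0 + eta).mean() for b0 in (-3, -1, 0, 1, 3)]
        assert np.all(np.diff(rates) > 0)

    def test_unreachable_target_errors(self):
        cfg = _zero_slope_config()
        cfg.target_prevalences["xer_g2"] = 1e-300
        with pytest.raises(ValueError):
            calibrate_intercept(cfg, "xer_g2")


class TestAmpute:
    def test_realized_rates_near_target(self):
        cfg = development_config(n=2000)
        coh = generate_cohort(cfg, seed=31)
        amp = ampute(coh, cfg.missing_rates, seed=32)
        targets = {
            "base_xer_g2": 0.11, "base_dys_g2": 0.02,
            "out_xer_g2": 0.21, "out_dys_g2": 0.16,
        }
        for col, rate in targets.items():
            assert abs(amp[col].isna().mean() - rate) < 0.03

    def test_grade_pair_blanked_jointly(self):
        cfg = development_config(n=1000)
        coh = generate_cohort(cfg, seed=33)
        amp = ampute(coh, cfg.missing_rates, seed=34)
        for g2, g3 in (("out_xer_g2", "out_xer_g3"), ("base_dys_g2", "base_dys_g3")):
            assert (amp[g2].isna() == amp[g3].isna()).all()

    def test_zero_rates_identity(self, dev_cohort):
        out = ampute(dev_cohort, {}, seed=0)
        pd.testing.assert_frame_equal(out, dev_cohort)

    def test_always_observed_field_rejected(self, dev_cohort):
        with pytest.raises(ValueError, match="always observed"):
            ampute(dev_cohort, {"dose_submandibular": 0.1}, seed=0)

    def test_missingness_exchangeable_given_observed(self):
        """MAR construction: conditional on the always-observed MAR score,
        missingness is independent of the latent outcome value."""
        import statsmodels.api as sm
        from ntcp_semisup.cohort import _mar_score

        cfg = development_config(n=20_000)
        coh = generate_cohort(cfg, seed=35)
        amp = ampute(coh, {"outcome_xerostomia": 0.21}, seed=36)
        miss = amp["out_xer_g2"].isna().to_numpy().astype(int)
        truth = coh["out_xer_g2"].to_numpy().astype(int)
        score = _mar_score(coh)
        strata = np.digitize(score, np.quantile(score, np.linspace(0.1, 0.9, 9)))
        tables = []
        for s in np.unique(strata):
            sel = strata == s
            t = np.array(
                [[np.sum(miss[sel] * truth[sel]), np.sum(miss[sel] * (1 - truth[sel]))],
                 [np.sum((1 - miss[sel]) * truth[sel]), np.sum((1 - miss[sel]) * (1 - truth[sel]))]]
            )
            tables.append(t)
        st = sm.stats.StratifiedTable(tables)
        assert st.test_null_odds().pvalue > 0.001


class TestMaskLabels:
    def test_40_of_750(self, dev_cohort):
        masked = mask_labels(dev_cohort, 40, seed=41)
        assert int(masked["unlabeled"].sum()) == 40
        assert int((masked["unlabeled"] == 0).sum()) == 710
        assert masked.loc[masked["unlabeled"] == 1, "out_xer_g2"].isna().all()

    def test_zero_is_identity(self, dev_cohort):
        masked = mask_labels(dev_cohort, 0, seed=41)
        for o in OUTCOMES:
            assert masked[f"out_{o}"].equals(dev_cohort[f"out_{o}"])
        assert int(masked["unlabeled"].sum()) == 0

    def test_premask_values_retained(self, dev_cohort):
        masked = mask_labels(dev_cohort, 40, seed=42)
        hidden = masked["unlabeled"] == 1
        for o in OUTCOMES:
            assert not masked.loc[hidden, f"premask_out_{o}"].isna().any()
            pd.testing.assert_series_equal(
                masked.loc[hidden, f"premask_out_{o}"],
                dev_cohort.loc[hidden, f"out_{o}"],
                check_names=False,
            )

    def test_invalid_k(self, dev_cohort):
        with pytest.raises(ValueError):
            mask_labels(dev_cohort, -1, seed=0)
        with pytest.raises(ValueError, match="exceeds"):
            mask_labels(dev_cohort, 100_000, seed=0)


class TestValidationCohort:
    def test_three_centers_sum_to_n(self, val_config):
        coh = generate_cohort(val_config, seed=51)
        sizes = coh["center"].value_counts()
        assert set(sizes.index) == {"UMCG", "Maastro", "RIF"}
        assert sizes.sum() == 395

    def test_center_dose_shifts_visible(self):
        cfg = validation_config(n=30_000)
        coh = generate_cohort(cfg, seed=52)
        by_center = coh.groupby("center")["dose_submandibular"].mean()
        # shifts are (-2, 0, +2) Gy for (UMCG, Maastro, RIF)
        assert by_center["RIF"] - by_center["UMCG"] > 2.0
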