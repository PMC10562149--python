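"""Validation metrics: AUC, calibration-in-the-large, slope, curve, pooling."""

import numpy as np
import pytest
from scipy import optimize, special

from ntcp_semisup.impute import ImputationSet
from ntcp_semisup.metrics import (
    auc,
    auc_bruteforce,
    calibration_curve,
    calibration_in_the_large,
    calibration_slope,
    single_dataset_metrics,
    validate,
)


class TestAUC:
    def test_perfect_separation(self):
        assert auc(np.array([0, 1]), np.array([0.2, 0.8])).value == 1.0

    def test_printed_four_point_case(self):
        est = auc(np.array([0, 0, 1, 1]), np.array([0.1, 0.6, 0.4, 0.8]))
        assert est.value == pytest.approx(0.75)

    def test_constant_predictions_half(self):
        est = auc(np.array([0, 1, 0, 1]), np.full(4, 0.3))
        assert est.value == pytest.approx(0.5)

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            auc(np.ones(4), np.linspace(0, 1, 4))

    def test_fast_equals_bruteforce_on_random_instances(self, rng):
        """Rank-based AUC equals the exhaustive all-pairs count, including
        ties, on 200 random small instances; also matches sklearn."""
        from sklearn.metrics import roc_auc_score

        for _ in range(200):
            n = rng.integers(4, 30)
            y = rng.integers(0, 2, n)
            if y.min() == y.max():
                y[0] = 1 - y[0]
            p = np.round(rng.random(n), 1)  # coarse grid to force ties
            est = auc(y, p)
            assert est.value == pytest.approx(auc_bruteforce(y, p), abs=1e-12)
            assert est.value == pytest.approx(roc_auc_score(y, p), abs=1e-12)

    def test_delong_se_sane(self, rng):
        y = rng.integers(0, 2, 400)
        y[:2] = [0, 1]
        p = np.clip(rng.random(400) * 0.5 + y * 0.3, 0.01, 0.99)
        est = auc(y, p)
        assert 0.0 < est.se < 0.1

    def test_row_order_invariance(self, rng):
        y = rng.integers(0, 2, 100)
        y[:2] = [0, 1]
        p = rng.random(100)
        perm = rng.permutation(100)
        a1, a2 = auc(y, p), auc(y[perm], p[perm])
        assert a1.value == pytest.approx(a2.value)
        assert a1.se == pytest.approx(a2.se)


class TestCalibrationInTheLarge:
    def test_mean_difference_arithmetic(self):
        md, _ = calibration_in_the_large(np.array([0, 1, 1, 1]), np.full(4, 0.5))
        assert md.value == pytest.approx(0.5 - 0.75)

    def test_perfectly_calibrated_limit(self, rng):
        p = rng.random(100_000) * 0.6 + 0.1
        y = (rng.random(100_000) < p).astype(float)
        md, lg = calibration_in_the_large(y, p)
        assert abs(md.value) < 0.01
        assert abs(lg.value) < 0.05

    def test_logit_version_matches_bruteforce_optimizer(self, rng):
        y = np.array([0, 1, 0, 0, 1, 1, 0, 1, 0, 0, 1, 0, 1, 1, 0, 0, 1, 0, 1, 1], float)
        p = np.linspace(0.1, 0.9, 20)
        _, lg = calibration_in_the_large(y, p)
        off = special.logit(p)

        def nll(a):
            eta = a + off
            return -(y @ eta - np.logaddexp(0, eta).sum())

        res = optimize.minimize_scalar(nll, bounds=(-5, 5), method="bounded",
                                       options={"xatol": 1e-10})
        assert lg.value == pytest.approx(res.x, abs=1e-5)

    def test_boundary_probabilities_clipped_with_warning(self):
        y = np.array([0.0, 1.0, 1.0, 0.0])
        with pytest.warns(UserWarning, match="clipped"):
            calibration_in_the_large(y, np.array([0.0, 1.0, 0.5, 0.5]))


class TestCalibrationSlope:
    def test_self_consistent_simulation_recovers_unit_slope(self, rng):
        eta = rng.normal(-0.5, 1.2, 100_000)
        p = special.expit(eta)
        y = (rng.random(100_000) < p).astype(float)
        sl = calibration_slope(y, p)
        assert sl.value == pytest.approx(1.0, abs=0.03)

    def test_doubled_linear_predictor_halves_slope(self, rng):
        eta = rng.normal(0.0, 1.0, 50_000)
        y = (rng.random(50_000) < special.expit(eta)).astype(float)
        overconfident = special.expit(2.0 * eta)
        sl = calibration_slope(y, overconfident)
        assert sl.value == pytest.approx(0.5, abs=0.03)

    def test_matches_bruteforce_optimizer(self, rng):
        y = (rng.random(30) < 0.4).astype(float)
        y[:2] = [0, 1]
        p = np.clip(rng.random(30), 0.05, 0.95)
        sl = calibration_slope(y, p)
        lp = special.logit(p)

        def nll(b):
            eta = b[0] + b[1] * lp
            return -(y @ eta - np.logaddexp(0, eta).sum())

        res = optimize.minimize(nll, np.zeros(2), method="Nelder-Mead",
                                options={"xatol": 1e-10, "fatol": 1e-12})
        assert sl.value == pytest.approx(res.x[1], abs=1e-4)

    def test_constant_predictions_error(self):
        with pytest.raises(ValueError, match="constant"):
            calibration_slope(np.array([0, 1, 0, 1]), np.full(4, 0.4))


class TestCalibrationCurve:
    def test_calibrated_curve_near_diagonal(self, rng):
        p = rng.random(50_000) * 0.8 + 0.1
        y = (rng.random(50_000) < p).astype(float)
        curve = calibration_curve(y, p)
        assert np.max(np.abs(curve[:, 1] - curve[:, 0])) < 0.05

    def test_constant_outcome_curve_at_one(self, rng):
        p = rng.random(200) * 0.5 + 0.25
        curve = calibration_curve(np.ones(200), p)
        assert np.allclose(curve[:, 1], 1.0, atol=1e-6)

    def test_binned_version_matches_hand_binning(self, rng):
        p = rng.random(100)
        y = (rng.random(100) < p).astype(float)
        curve = calibration_curve(y, p, method="bins")
        edges = np.linspace(p.min(), p.max() + 1e-12, 11)
        idx = np.digitize(p, edges) - 1
        for row_p, row_y in curve:
            b = int(np.digitize(row_p, edges) - 1)
            sel = idx == b
            assert row_y == pytest.approx(y[sel].mean())

    def test_small_n_rejected(self):
        with pytest.raises(ValueError, match="n >= 20"):
            calibration_curve(np.ones(5), np.full(5, 0.5))


class TestValidatePooling:
    def _imp_set(self, dfs):
        return ImputationSet(m=len(dfs), cohorts=dfs)

    def _fake_validation(self, rng, n=300):
        import pandas as pd
        from ntcp_semisup.cohort import generate_cohort
        from ntcp_semisup.config import validation_config

        return generate_cohort(validation_config(n=n), seed=int(rng.integers(2**31)))

    def _model(self, rng):
        from ntcp_semisup.design import build_design, xerostomia_spec
        from ntcp_semisup.learners import fit_logistic

        coh = self._fake_validation(rng)
        X, y, lab = build_design(coh, xerostomia_spec(2))
        return fit_logistic(X[lab], y[lab], xerostomia_spec(2).term_names)

    def test_m1_identical_to_single_dataset(self, rng):
        from ntcp_semisup.design import build_design, xerostomia_spec
        from ntcp_semisup.learners import predict_prob

        model = self._model(rng)
        coh = self._fake_validation(rng)
        vm = validate(model, self._imp_set([coh]), xerostomia_spec(2))
        X, y, lab = build_design(coh, xerostomia_spec(2))
        single = single_dataset_metrics(y[lab], predict_prob(model, X[lab]))
        assert vm.auc.value == pytest.approx(single.auc.value)
        assert vm.slope.value == pytest.approx(single.slope.value)
        assert vm.auc.se == pytest.approx(single.auc.se)

    def test_identical_imputations_zero_between_variance(self, rng):
        from ntcp_semisup.design import xerostomia_spec

        model = self._model(rng)
        coh = self._fake_validation(rng)
        vm1 = validate(model, self._imp_set([coh]), xerostomia_spec(2))
        vm10 = validate(model, self._imp_set([coh.copy() for _ in range(10)]),
                        xerostomia_spec(2))
        assert vm10.auc.value == pytest.approx(vm1.auc.value)
        assert vm10.auc.se == pytest.approx(vm1.auc.se, rel=1e-6)

    def test_pooled_se_at_least_mean_within_se(self, rng):
        import pandas as pd
        from ntcp_semisup.design import build_design, xerostomia_spec
        from ntcp_semisup.learners import predict_prob

        model = self._model(rng)
        base = self._fake_validation(rng)
        dfs = []
        for k in range(5):
            df = base.copy()
            flip = np.asarray(rng.random(len(df)) < 0.05)
            df.loc[flip, "out_xer_g2"] = 1 - df.loc[flip, "out_xer_g2"]
            df["out_xer_g3"] = np.minimum(df["out_xer_g3"], df["out_xer_g2"])
            dfs.append(df)
        vm = validate(model, self._imp_set(dfs), xerostomia_spec(2))
        per_se = []
        for df in dfs:
            X, y, lab = build_design(df, xerostomia_spec(2))
            per_se.append(single_dataset_metrics(y[lab], predict_prob(model, X[lab])).auc.se)
        assert vm.auc.se >= np.mean(per_se) - 1e-12


class TestScoreEquationCITL:
    def test_refit_model_has_zero_mean_difference(self, rng):
        """A maximum-likelihood logistic model evaluated on its own training
        data has mean predicted probability equal to the event rate."""
        from ntcp_semisup.design import build_design, xerostomia_spec
        from ntcp_semisup.learners import fit_logistic, predict_prob
        from ntcp_semisup.cohort import generate_cohort
        from ntcp_semisup.config import development_config

        coh = generate_cohort(development_config(n=400), seed=81)
        X, y, lab = build_design(coh, xerostomia_spec(2))
        m = fit_logistic(X, y)
        md, _ = calibration_in_the_large(y, predict_prob(m, X))
        assert abs(md.value) < 1e-8
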