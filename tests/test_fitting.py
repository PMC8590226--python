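"""Tests for individual curve fitting, the transform and the WHF."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from qepsgrowth.fitting import (
    DegeneratePredictionError,
    DegenerateTransformError,
    FitOptions,
    InsufficientCoverageError,
    Measurement,
    TransformCoefficients,
    estimate_transform,
    fit_height,
    fit_whf,
    predict_weight,
)
from qepsgrowth.qeps_model import DEFAULT_SHAPE, QEPSParams, eval_components

SHAPE = DEFAULT_SHAPE["F"]
AGES_25 = np.concatenate([np.array([0.5, 1.0, 2.0]),
                          np.arange(3.0, 10.0),
                          np.arange(10.0, 17.5, 0.5)])


def true_params(**kw) -> QEPSParams:
    base = dict(c_Q=98.0, c_E=52.0, c_P=17.0, c_S=0.5, theta_P=11.2,
                sigma_P=0.95)
    base.update(kw)
    return QEPSParams(**base)


def series(p: QEPSParams, ages=AGES_25, noise=0.0, seed=0):
    y = eval_components(p, SHAPE, ages).total
    if noise:
        y = y + np.random.default_rng(seed).normal(0, noise, ages.size)
    return [Measurement("s", "F", a, height=h) for a, h in zip(ages, y)]


class TestFitHeight:
    def test_noiseless_recovery(self):
        ages = np.linspace(0.25, 20, 25)
        p = true_params()
        fit = fit_height(series(p, ages), SHAPE)
        assert fit.converged
        assert fit.rmse < 1e-6
        for name in ("c_Q", "c_E", "c_P", "theta_P", "sigma_P"):
            assert getattr(fit.params, name) == pytest.approx(
                getattr(p, name), rel=1e-4), name
        assert fit.params.c_S == pytest.approx(p.c_S, abs=1e-3)

    def test_fixed_point_of_own_output(self):
        noisy = fit_height(series(true_params(), noise=0.5, seed=3), SHAPE)
        refit = fit_height(series(noisy.params), SHAPE)
        ages = np.linspace(2, 20, 50)
        a = eval_components(noisy.params, SHAPE, ages).total
        b = eval_components(refit.params, SHAPE, ages).total
        assert np.max(np.abs(a - b)) < 1e-6

    def test_too_few_points(self):
        p = true_params()
        with pytest.raises(InsufficientCoverageError):
            fit_height(series(p, np.array([3.0, 8.0, 14.0, 16.5])), SHAPE)

    def test_missing_late_measurements(self):
        with pytest.raises(InsufficientCoverageError):
            fit_height(series(true_params(), np.linspace(0.5, 12.5, 10)),
                       SHAPE)

    def test_outlier_downweighted(self):
        ms = series(true_params(), noise=0.3, seed=9)
        bad = ms[12]
        ms[12] = Measurement(bad.subject_id, bad.sex, bad.age,
                             height=bad.height + 25.0)
        fit = fit_height(ms, SHAPE)
        assert fit.params.theta_P == pytest.approx(11.2, abs=0.3)
        assert fit.rmse < 1.0

    def test_noisy_timing_recovery_small_sample(self):
        errs = []
        for seed in range(20):
            theta = 10.0 + 0.15 * seed
            p = true_params(theta_P=theta)
            fit = fit_height(series(p, noise=0.5, seed=seed), SHAPE)
            errs.append(abs(fit.params.theta_P - theta))
        assert np.median(errs) < 0.2


def make_transform_subjects(alphas, n=35, seed=1):
    """Subjects whose sqrt-weights are exactly the transformed heights."""
    rng = np.random.default_rng(seed)
    subjects = []
    for _ in range(n):
        p = true_params(c_Q=rng.uniform(80, 110), c_E=rng.uniform(45, 60),
                        c_P=rng.uniform(10, 25), c_S=rng.uniform(0.3, 0.8),
                        theta_P=rng.uniform(9.5, 13), sigma_P=rng.uniform(0.7, 1.2))
        wp = predict_weight(p, alphas)
        sw = eval_components(wp, SHAPE, AGES_25).total
        subjects.append((p, list(zip(AGES_25, sw**2))))
    return subjects


class TestEstimateTransform:
    @pytest.mark.parametrize("alphas", [
        TransformCoefficients(0.30, 0.30, 0.30, 0.30),
        TransformCoefficients(0.25, 0.35, 0.30, 0.30),
    ])
    def test_construction_oracle(self, alphas):
        est = estimate_transform(make_transform_subjects(alphas), SHAPE)
        for name in ("alpha_Q", "alpha_E", "alpha_P", "alpha_S"):
            assert getattr(est, name) == pytest.approx(
                getattr(alphas, name), abs=1e-6), name

    def test_no_pubertal_signal_degenerate(self):
        alphas = TransformCoefficients(0.3, 0.3, 0.3, 0.3)
        subjects = [(p, w) for p, w in make_transform_subjects(alphas)]
        flat = [(QEPSParams(c_Q=p.c_Q, c_E=p.c_E, c_P=0.0, c_S=0.0,
                            theta_P=p.theta_P, sigma_P=p.sigma_P), w)
                for p, w in subjects]
        with pytest.raises(DegenerateTransformError):
            estimate_transform(flat, SHAPE)

    def test_single_subject_warns(self):
        alphas = TransformCoefficients(0.3, 0.3, 0.3, 0.3)
        one = make_transform_subjects(alphas, n=1)
        with pytest.warns(UserWarning, match="wide variance"):
            estimate_transform(one, SHAPE)


class TestPredictWeight:
    def test_linear_map(self):
        coefs = TransformCoefficients(0.2, 0.25, 0.30, 0.1)
        p = true_params(c_P=15.0)
        wp = predict_weight(p, coefs)
        assert wp.c_P == pytest.approx(4.5)
        assert wp.trait == "weight"
        assert wp.theta_P == p.theta_P and wp.sigma_P == p.sigma_P

    def test_zero_maps_to_zero(self):
        coefs = TransformCoefficients(0.2, 0.25, 0.30, 0.1)
        p = QEPSParams(c_Q=0, c_E=0, c_P=0, c_S=0, theta_P=11, sigma_P=1)
        wp = predict_weight(p, coefs)
        assert (wp.c_Q, wp.c_E, wp.c_P, wp.c_S) == (0, 0, 0, 0)


class TestFitWHF:
    def setup_method(self):
        self.alphas = TransformCoefficients(0.0409, 0.0450, 0.0824, 0.05)
        self.wp = predict_weight(true_params(), self.alphas)
        self.sw = eval_components(self.wp, SHAPE, AGES_25).total

    def obs(self, factor=1.0):
        return list(zip(AGES_25, (factor * self.sw) ** 2))

    @pytest.mark.parametrize("factor,expected", [
        (1.0, 0.0), (1.1, 0.10), (0.9, -0.10)])
    def test_multiplicative_construction(self, factor, expected):
        res = fit_whf(self.obs(factor), self.wp, SHAPE)
        assert res.whf == pytest.approx(expected, abs=1e-12)
        assert res.rmse == pytest.approx(0.0, abs=1e-10)

    @given(st.floats(0.5, 1.5))
    def test_scale_equivariance(self, k):
        base = fit_whf(self.obs(1.05), self.wp, SHAPE).whf
        scaled = fit_whf([(a, (k**2) * w) for a, w in self.obs(1.05)],
                         self.wp, SHAPE).whf
        assert scaled == pytest.approx(k * (1 + base) - 1, rel=1e-9)

    def test_too_few_points(self):
        with pytest.raises(InsufficientCoverageError):
            fit_whf(self.obs()[:3], self.wp, SHAPE)

    def test_zero_prediction_degenerate(self):
        zero = QEPSParams(c_Q=0, c_E=0, c_P=0, c_S=0, theta_P=11,
                          sigma_P=1, trait="weight")
        with pytest.raises(DegeneratePredictionError):
            fit_whf(self.obs(), zero, SHAPE)


def test_weight_relative_error_exceeds_height(small_pipeline, small_cohort):
    """Residual variation is relatively larger for weight than for height.

    Weight carries both a larger noise floor (in kg^0.5) and population-level
    transform misfit that a single constitutional factor cannot absorb.
    """
    cohort, _ = small_cohort
    res = small_pipeline
    rel_h, rel_w = [], []
    mean_h = cohort.groupby("subject_id")["height_cm"].mean()
    mean_sw = np.sqrt(cohort.groupby("subject_id")["weight_kg"].mean())
    for sid, fit in res.height_fits.items():
        rel_h.append(fit.rmse / mean_h[sid])
        rel_w.append(res.whf[sid].rmse / mean_sw[sid])
    assert np.median(rel_w) > np.median(rel_h)
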