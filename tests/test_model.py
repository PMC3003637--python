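"""OLS retention model: fitting, statistics, prediction, residuals."""

import numpy as np
import pytest
from scipy import stats as sps

from peprt.descriptors import DescriptorPair
from peprt.model import (
    REFERENCE_MODEL,
    FittingError,
    QsrrModel,
    delta_rt,
    evaluate_test_set,
    fit_mlr,
    load_model,
    predict_rt,
    save_model,
)


def _pairs(log_sum, clogp):
    return [DescriptorPair(a, b) for a, b in zip(log_sum, clogp)]


def calibration_rows(table):
    return [
        (DescriptorPair(float(r.log_sum_k1), float(r.clogp)), float(r.t_r_exp))
        for r in table.itertuples()
    ]


class TestFit:
    def test_noiseless_linear_data_recovered_exactly(self):
        rng = np.random.default_rng(3)
        x1, x2 = rng.uniform(0, 2, 20), rng.normal(0, 1, 20)
        y = 2 + 3 * x1 - 1 * x2
        model, fs = fit_mlr(zip(_pairs(x1, x2), y))
        assert (model.k1, model.k2, model.k3) == pytest.approx((2, 3, -1), abs=1e-9)
        assert fs.R == pytest.approx(1.0) and fs.s == pytest.approx(0.0, abs=1e-9)

    def test_calibration_statistics(self, calibration):
        model, fs = fit_mlr(calibration_rows(calibration))
        assert fs.n == 50
        assert fs.R == pytest.approx(0.974, abs=0.005)
        assert fs.s == pytest.approx(1.45, abs=0.05)
        assert fs.F == pytest.approx(431, rel=0.05)
        assert fs.p_overall < 1e-20
        assert all(p < 1e-3 for p in fs.p_coef.values())

    def test_statistics_match_independent_linear_algebra(self, calibration):
        """Dual route: statsmodels-backed fit vs plain normal equations."""
        rows = calibration_rows(calibration)
        model, fs = fit_mlr(rows)
        X = np.column_stack(
            [np.ones(50), [d.log_sum_k1 for d, _ in rows], [d.clogp for d, _ in rows]]
        )
        y = np.array([t for _, t in rows])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        assert (model.k1, model.k2, model.k3) == pytest.approx(tuple(beta), abs=1e-8)
        sse = float(((y - X @ beta) ** 2).sum())
        sst = float(((y - y.mean()) ** 2).sum())
        r2 = 1 - sse / sst
        assert fs.R == pytest.approx(np.sqrt(r2), abs=1e-12)
        assert fs.s == pytest.approx(np.sqrt(sse / 47), abs=1e-12)
        assert fs.F == pytest.approx((r2 / 2) / ((1 - r2) / 47), abs=1e-8)

    def test_R_equals_corr_of_fitted_and_observed(self, calibration):
        rows = calibration_rows(calibration)
        model, fs = fit_mlr(rows)
        fitted = [model.predict(d.log_sum_k1, d.clogp) for d, _ in rows]
        observed = [t for _, t in rows]
        assert fs.R == pytest.approx(np.corrcoef(fitted, observed)[0, 1], abs=1e-12)

    def test_residuals_orthogonal_to_design(self, calibration):
        rows = calibration_rows(calibration)
        model, _ = fit_mlr(rows)
        resid = np.array(
            [t - model.predict(d.log_sum_k1, d.clogp) for d, t in rows]
        )
        scale = max(abs(t) for _, t in rows)
        assert abs(resid.sum()) / scale < 1e-8
        for col in (
            [d.log_sum_k1 for d, _ in rows],
            [d.clogp for d, _ in rows],
        ):
            c = np.asarray(col)
            assert abs(resid @ (c / np.abs(c).max())) / scale < 1e-8

    def test_refit_on_own_predictions_is_idempotent(self, calibration):
        rows = calibration_rows(calibration)
        model, _ = fit_mlr(rows)
        refit_rows = [
            (d, model.predict(d.log_sum_k1, d.clogp)) for d, _ in rows
        ]
        refit, fs = fit_mlr(refit_rows)
        assert (refit.k1, refit.k2, refit.k3) == pytest.approx(
            (model.k1, model.k2, model.k3), abs=1e-8
        )

    def test_too_few_rows_rejected(self):
        with pytest.raises(FittingError, match="more than 3"):
            fit_mlr(zip(_pairs([1, 2, 3], [1, 2, 3]), [1.0, 2.0, 3.0]))

    def test_constant_descriptor_rejected(self):
        with pytest.raises(FittingError, match="degenerate"):
            fit_mlr(zip(_pairs([1, 1, 1, 1], [0, 1, 2, 3]), [1.0, 2.0, 3.0, 4.0]))

    def test_coefficient_recovery_within_three_se(self):
        """Gaussian-noise simulation at the calibration scale (n=50, s=1.45):
        all three estimates stay within 3 standard errors at the rate the
        t distribution predicts (P(|t_47| <= 3) per coefficient ~ 0.9957,
        so ~0.987 jointly; assert a 3-sigma lower binomial bound)."""
        rng = np.random.default_rng(2024)
        true = np.array([-17.6, 32.2, 0.76])
        tcrit = 3.0
        hits = 0
        n_rep = 300
        for _ in range(n_rep):
            ls = rng.uniform(0.8, 1.9, 50)
            cp = rng.normal(-4, 2.5, 50)
            y = true[0] + true[1] * ls + true[2] * cp + rng.normal(0, 1.45, 50)
            model, fs = fit_mlr(zip(_pairs(ls, cp), y))
            est = np.array([model.k1, model.k2, model.k3])
            se = np.array([fs.se_coef[k] for k in ("k1", "k2", "k3")])
            hits += bool(np.all(np.abs(est - true) <= tcrit * se))
        assert hits / n_rep >= 0.965


class TestPredict:
    def test_intercept_identity_on_reference_coefficients(self):
        assert predict_rt(REFERENCE_MODEL, DescriptorPair(0, 0)).t_r_pred == -25.07

    def test_reference_model_arithmetic(self):
        assert predict_rt(
            REFERENCE_MODEL, DescriptorPair(1.0, 0.0)
        ).t_r_pred == pytest.approx(8.09)

    def test_fitted_model_near_printed_prediction(self, calibration):
        model, _ = fit_mlr(calibration_rows(calibration))
        pred = predict_rt(model, DescriptorPair(1.3542, -1.74)).t_r_pred
        assert pred == pytest.approx(25.13, abs=0.5)

    def test_reference_model_documented_inconsistency(self):
        # the reference coefficients undershoot the distributed t_r_pred column
        pred = REFERENCE_MODEL.predict(1.3542, -1.74)
        assert pred == pytest.approx(18.8, abs=0.1)
        assert abs(pred - 25.13) > 5


class TestDelta:
    @pytest.mark.parametrize(
        "exp,pred,signed,mag",
        [(25.12, 25.13, -0.01, 0.01), (7.5, 7.5, 0.0, 0.0), (91.35, 10.80, 80.55, 80.55)],
    )
    def test_examples(self, exp, pred, signed, mag):
        assert delta_rt(exp, pred) == (
            pytest.approx(signed, abs=1e-9),
            pytest.approx(mag, abs=1e-9),
        )

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            delta_rt(float("nan"), 1.0)


class TestEvaluate:
    def test_mean_signed_residual_zero_on_calibration(self, calibration):
        rows = calibration_rows(calibration)
        model, _ = fit_mlr(rows)
        _, summary = evaluate_test_set(model, rows)
        assert summary["mean_delta_t_r"] == pytest.approx(0.0, abs=1e-9)
        assert summary["n"] == 50

    def test_printed_predictions_give_printed_deltas(self, pooled_sasp):
        """Using the distributed t_r_pred as the reference model output
        reproduces the distributed signed delta column to 0.01 min."""
        for r in pooled_sasp.itertuples():
            signed, _ = delta_rt(float(r.t_r_exp), float(r.t_r_pred))
            assert signed == pytest.approx(float(r.delta_t_r), abs=0.011)

    def test_empty_input(self):
        preds, summary = evaluate_test_set(REFERENCE_MODEL, [])
        assert preds == [] and summary == {}


class TestSerialization:
    def test_round_trip(self, tmp_path, calibration):
        model, fs = fit_mlr(calibration_rows(calibration))
        path = tmp_path / "model.txt"
        save_model(model, path, stats=fs, provenance="calibration")
        loaded = load_model(path)
        assert (loaded.k1, loaded.k2, loaded.k3) == (model.k1, model.k2, model.k3)
        text = path.read_text()
        assert "n=50" in text and "calibration" in text

    def test_missing_coefficient(self, tmp_path):
        path = tmp_path / "bad.txt"
        path.write_text("k1=1.0\nk2=2.0\n")
        with pytest.raises(ValueError, match="k3"):
            load_model(path)

    def test_nonfinite_coefficients_rejected(self):
        with pytest.raises(ValueError):
            QsrrModel(float("inf"), 0.0, 0.0)


def test_empirical_coverage_of_confidence_intervals():
    """95% CIs from the calibration-scale simulation cover the generating
    coefficients at close to the nominal rate."""
    rng = np.random.default_rng(99)
    true = np.array([-17.6, 32.2, 0.76])
    tcrit = sps.t.ppf(0.975, 47)
    n_rep = 400
    covered = np.zeros(3)
    for _ in range(n_rep):
        ls = rng.uniform(0.8, 1.9, 50)
        cp = rng.normal(-4, 2.5, 50)
        y = true[0] + true[1] * ls + true[2] * cp + rng.normal(0, 1.45, 50)
        model, fs = fit_mlr(zip(_pairs(ls, cp), y))
        est = np.array([model.k1, model.k2, model.k3])
        se = np.array([fs.se_coef[k] for k in ("k1", "k2", "k3")])
        covered += np.abs(est - true) <= tcrit * se
    rates = covered / n_rep
    assert np.all(rates >= 0.90) and np.all(rates <= 0.99)
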