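"""Calibration models: univariate OLS, MPF fusion, PTT baselines."""

import numpy as np
import pandas as pd
import pytest

from pulsebp.errors import DegenerateFeatureError, ParameterError
from pulsebp.features import FEATURE_NAMES
from pulsebp.models import (
    MPFRegressor,
    PTTRegressor,
    SubjectModels,
    fit_subject,
    fit_univariate,
    mpf_predict,
)
from pulsebp.synthetic import CohortSpec, generate_cohort


def brute_force_mpf(preds, gamma):
    """Independent oracle: sort, trim, average, subtract sample SD."""
    preds = sorted(preds)
    n = len(preds)
    g = int(np.floor(gamma * n))
    kept = preds[g : n - g]
    mean = sum(kept) / len(kept)
    mu = sum(preds) / n
    sd = (sum((p - mu) ** 2 for p in preds) / (n - 1)) ** 0.5
    return mean - sd


class TestFitUnivariate:
    def test_exact_line(self):
        x = np.array([0.0, 1.0, 2.0, 5.0])
        slope, intercept = fit_univariate(x, 2 * x + 1)
        assert slope == pytest.approx(2.0) and intercept == pytest.approx(1.0)

    def test_noisy_slope_within_sampling_bounds(self, rng):
        x = rng.uniform(0, 10, 16)
        y = 0.8 * x + rng.normal(0, 1.0, 16)
        slope, _ = fit_univariate(x, y)
        se = 1.0 / np.sqrt(np.sum((x - x.mean()) ** 2))
        assert abs(slope - 0.8) < 3 * se

    def test_constant_x_degenerate(self):
        with pytest.raises(DegenerateFeatureError):
            fit_univariate(np.ones(5), np.arange(5.0))

    def test_too_few_points(self):
        with pytest.raises(ParameterError):
            fit_univariate(np.array([1.0]), np.array([2.0]))


class TestMPFPredict:
    def test_all_equal_is_identity(self):
        for gamma in (0.0, 0.1, 0.2):
            assert mpf_predict(np.full(21, 115.0), gamma) == pytest.approx(115.0)

    def test_worked_example_1_to_21(self):
        preds = np.arange(1.0, 22.0)
        got = mpf_predict(preds, gamma=0.1)
        # g = 2: mean of 3..19 = 11; minus sample SD of 1..21
        assert got == pytest.approx(11.0 - np.std(preds, ddof=1))
        assert got == pytest.approx(brute_force_mpf(list(preds), 0.1))

    @pytest.mark.parametrize("gamma", [0.0, 0.05, 0.1, 0.2, 0.45])
    def test_matches_brute_force_oracle(self, gamma, rng):
        for _ in range(200):
            preds = rng.normal(120, 10, 21)
            assert mpf_predict(preds, gamma) == pytest.approx(
                brute_force_mpf(list(preds), gamma), rel=1e-12
            )

    def test_gamma_zero_is_mean_minus_sd(self, rng):
        preds = rng.normal(100, 5, 21)
        assert mpf_predict(preds, 0.0) == pytest.approx(
            preds.mean() - preds.std(ddof=1)
        )

    def test_permutation_invariance(self, rng):
        preds = rng.normal(120, 8, 21)
        base = mpf_predict(preds, 0.1)
        for _ in range(10):
            assert mpf_predict(rng.permutation(preds), 0.1) == pytest.approx(base)

    def test_shift_equivariance(self, rng):
        preds = rng.normal(120, 8, 21)
        delta = 7.3
        assert mpf_predict(preds + delta, 0.1) == pytest.approx(
            mpf_predict(preds, 0.1) + delta
        )

    def test_trimmed_mean_breakdown_robustness(self, rng):
        preds = rng.normal(120, 3, 21)
        clean_tm = np.sort(preds)[2:-2].mean()
        spoiled = preds.copy()
        spoiled[:2] = [500.0, -400.0]  # two wild outliers
        spoiled_tm = np.sort(spoiled)[2:-2].mean()
        # trimmed mean ignores both; the plain mean does not
        assert spoiled_tm == pytest.approx(
            np.sort(preds)[2:-2].mean(), abs=2.0
        )
        assert abs(spoiled.mean() - preds.mean()) > 5.0
        assert abs(spoiled_tm - clean_tm) < 1.0

    @pytest.mark.parametrize(
        "bad, exc",
        [
            (np.full(20, 1.0), ParameterError),          # wrong length
            (np.r_[np.full(20, 1.0), np.nan], ParameterError),  # non-finite
        ],
    )
    def test_invalid_inputs(self, bad, exc):
        with pytest.raises(exc):
            mpf_predict(bad, 0.1)

    def test_gamma_out_of_range(self):
        with pytest.raises(ParameterError):
            mpf_predict(np.ones(21), 0.5)


class TestMPFRegressor:
    def _table(self, n=16, seed=0):
        rng = np.random.default_rng(seed)
        sbp = rng.uniform(105, 135, n)
        data = {name: 0.3 + (j + 1) * 1e-3 * sbp for j, name in enumerate(FEATURE_NAMES)}
        df = pd.DataFrame(data)
        return df, sbp

    def test_exact_linear_recovery(self):
        df, sbp = self._table()
        model = MPFRegressor(gamma=0.1).fit(df, sbp)
        pred = model.predict(df)
        np.testing.assert_allclose(pred, sbp, atol=1e-8)

    def test_sklearn_protocol(self):
        from sklearn.base import clone

        model = MPFRegressor(gamma=0.2)
        assert clone(model).get_params()["gamma"] == 0.2
        df, sbp = self._table()
        model.fit(df, sbp)
        assert model.coef_.shape == (21,)
        assert model.n_features_in_ == 21
        assert model.predict_ensemble(df).shape == (16, 21)

    def test_missing_column_raises(self):
        df, sbp = self._table()
        with pytest.raises(ParameterError):
            MPFRegressor().fit(df.drop(columns=["K"]), sbp)

    def test_constant_feature_named_in_error(self):
        df, sbp = self._table()
        df["PIR"] = 1.0
        with pytest.raises(DegenerateFeatureError, match="PIR"):
            MPFRegressor().fit(df, sbp)


class TestPTTRegressor:
    def test_inverse_variant_arithmetic(self):
        model = PTTRegressor(variant="inverse_PTT")
        model.coef_ = np.array([10.0])
        model.intercept_ = 70.0
        model.n_features_in_ = 1
        assert model.predict([0.2])[0] == pytest.approx(120.0)

    @pytest.mark.parametrize("variant", ["linear_PTT", "inverse_PTT", "log_inv_sq"])
    def test_fit_recovers_generating_law(self, variant, rng):
        ptt = rng.uniform(0.15, 0.35, 50)
        if variant == "linear_PTT":
            y = -200.0 * ptt + 170.0
        elif variant == "inverse_PTT":
            y = 10.0 / ptt + 70.0
        else:
            y = -30.0 * np.log(1.0 / ptt) + 0.5 / ptt**2 + 90.0
        model = PTTRegressor(variant=variant).fit(ptt, y)
        np.testing.assert_allclose(model.predict(ptt), y, atol=1e-6)

    def test_unknown_variant(self):
        with pytest.raises(ParameterError):
            PTTRegressor(variant="cubic").fit([0.2, 0.3], [120, 110])


class TestFitSubject:
    def _cohort(self):
        spec = CohortSpec(n_subjects=2, mode="analytic", ref_noise_sd=0.0)
        return generate_cohort(spec, seed=3)

    def test_full_model_set(self):
        coh = self._cohort()
        rows = coh.train[coh.train.subject_id == "S000"]
        models = fit_subject(rows, gamma=0.1, subject_id="S000")
        assert set(models.mpf) == {"sbp", "dbp"}
        assert models.mpf["sbp"].coef_.shape == (21,)
        assert models.ptt is not None
        assert set(models.ptt["sbp"]) == {"linear_PTT", "inverse_PTT", "log_inv_sq"}

    def test_rows_without_ptt_skip_baselines(self):
        coh = self._cohort()
        rows = coh.train[coh.train.subject_id == "S000"].drop(columns=["PTT"])
        models = fit_subject(rows, gamma=0.1)
        assert models.ptt is None and set(models.mpf) == {"sbp", "dbp"}

    def test_single_row_rejected(self):
        coh = self._cohort()
        with pytest.raises(ParameterError):
            fit_subject(coh.train.iloc[:1], gamma=0.1)

    def test_json_round_trip(self, tmp_path):
        coh = self._cohort()
        rows = coh.train[coh.train.subject_id == "S000"]
        models = fit_subject(rows, gamma=0.1, subject_id="S000")
        path = tmp_path / "model.json"
        models.save(path)
        back = SubjectModels.load(path)
        test = coh.test[coh.test.subject_id == "S000"]
        for target in ("sbp", "dbp"):
            np.testing.assert_allclose(
                back.mpf[target].predict(test), models.mpf[target].predict(test)
            )
            ptt = test["PTT"].to_numpy(dtype=float)
            for variant, m in models.ptt[target].items():
                np.testing.assert_allclose(
                    back.ptt[target][variant].predict(ptt), m.predict(ptt)
                )
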