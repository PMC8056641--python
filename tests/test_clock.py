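"""Clock training, application, and the estimator interface."""

import numpy as np
import pandas as pd
import pytest
from sklearn.base import clone

from gaclock.clock import (
    GestationalAgeClock,
    TrainConfig,
    predict_ga,
    split_train_test,
    train_clock,
)
from gaclock.io import BetaMatrix, ClockModel, SampleRecord, SampleSheet, ValidationError
from gaclock.simulate import SimConfig, simulate_cohort


class TestSplitTrainTest:
    def test_forced_arithmetic(self):
        train, test = split_train_test([f"s{i}" for i in range(10)], 0.8, 0)
        assert len(train) == 8 and len(test) == 2
        assert set(train) | set(test) == {f"s{i}" for i in range(10)}
        assert not set(train) & set(test)

    def test_same_seed_same_split(self):
        ids = [f"s{i}" for i in range(37)]
        assert split_train_test(ids, 0.8, 5) == split_train_test(ids, 0.8, 5)

    def test_train_membership_frequency(self):
        """Across seeds every sample lands in the training split ~80% of
        the time."""
        ids = [f"s{i}" for i in range(1000)]
        counts = pd.Series(0, index=ids)
        n_seeds = 100
        for seed in range(n_seeds):
            train, _ = split_train_test(ids, 0.8, seed)
            counts[train] += 1
        freqs = counts / n_seeds
        assert freqs.mean() == pytest.approx(0.8, abs=1e-9)
        assert freqs.between(0.65, 0.95).all()

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            split_train_test(["only"], 0.8, 0)


def _sheet_from_ga(ga: pd.Series) -> SampleSheet:
    return SampleSheet(
        [SampleRecord(s, int(g)) for s, g in ga.items()]
    )


class TestTrainClock:
    def test_noise_free_single_active_probe_recovered(self):
        cfg = SimConfig(n_samples=80, n_probes=40, n_active=1, effect_sd=0.02,
                        noise_sd=1e-4, seed=17)
        bm, sheet, truth = simulate_cohort(cfg)
        clock = train_clock(bm, sheet, TrainConfig(seed=0))
        assert truth.active_probe_ids[0] in clock.probe_ids

    def test_reproducible_coefficients(self, small_cohort):
        _, bm, sheet, _ = small_cohort
        a = train_clock(bm, sheet, TrainConfig(seed=3))
        b = train_clock(bm, sheet, TrainConfig(seed=3))
        assert a.coefficients == b.coefficients
        assert a.intercept == b.intercept
        assert a.lam == b.lam

    def test_etd_source_on_non_art_samples_is_error(self):
        cfg = SimConfig(n_samples=30, n_probes=20, n_active=2, seed=2,
                        art_fraction=0.0)
        bm, sheet, _ = simulate_cohort(cfg)
        with pytest.raises(ValidationError, match="without etd GA"):
            train_clock(bm, sheet, TrainConfig(seed=0), ga_source="etd")

    def test_training_medians_cover_selected_probes(self, small_cohort):
        _, bm, sheet, _ = small_cohort
        clock = train_clock(bm, sheet, TrainConfig(seed=1))
        assert set(clock.training_medians) == set(clock.coefficients)


class TestPredictGa:
    def test_linear_form_by_hand(self):
        clock = ClockModel(280.0, {"cg1": 10.0, "cg2": -5.0})
        bm = BetaMatrix(pd.DataFrame({"S1": [0.5, 0.2]}, index=["cg1", "cg2"]))
        pred = predict_ga(bm, clock)
        assert pred["S1"] == pytest.approx(284.0)

    def test_empty_clock_predicts_intercept(self, random_beta_matrix):
        clock = ClockModel(281.0, {})
        pred = predict_ga(random_beta_matrix(), clock)
        assert (pred == 281.0).all()

    def test_matches_per_sample_dot_product(self, random_beta_matrix):
        rng = np.random.default_rng(23)
        bm = random_beta_matrix(n_probes=30, n_samples=10, seed=23)
        probes = rng.choice(bm.probe_ids, size=12, replace=False)
        clock = ClockModel(
            275.0, {p: float(c) for p, c in zip(probes, rng.normal(0, 20, 12))}
        )
        pred = predict_ga(bm, clock)
        for s in bm.sample_ids:
            expected = clock.intercept + sum(
                clock.coefficients[p] * bm.values.loc[p, s] for p in probes
            )
            assert pred[s] == pytest.approx(expected, abs=1e-12)

    def test_invariant_to_probe_and_sample_order(self, random_beta_matrix):
        rng = np.random.default_rng(29)
        bm = random_beta_matrix(n_probes=15, n_samples=6, seed=29)
        clock = ClockModel(
            280.0,
            {p: float(c) for p, c in zip(bm.probe_ids[:8], rng.normal(size=8))},
        )
        base = predict_ga(bm, clock)
        perm = BetaMatrix(
            bm.values.iloc[rng.permutation(15), rng.permutation(6)]
        )
        shuffled = predict_ga(perm, clock)
        for s in bm.sample_ids:
            assert shuffled[s] == pytest.approx(base[s], abs=1e-12)

    def test_absent_probe_uses_training_median(self):
        clock = ClockModel(
            280.0, {"cg1": 10.0, "cg2": -5.0}, training_medians={"cg1": 0.5, "cg2": 0.3}
        )
        bm = BetaMatrix(pd.DataFrame({"S1": [0.4]}, index=["cg1"]))
        pred, rep = predict_ga(bm, clock, with_report=True)
        assert pred["S1"] == pytest.approx(280.0 + 10 * 0.4 - 5 * 0.3)
        assert rep.n_absent == 1 and rep.n_excluded == 0

    def test_absent_probe_without_median_excluded(self):
        clock = ClockModel(280.0, {"cg1": 10.0, "cg2": -5.0})
        bm = BetaMatrix(pd.DataFrame({"S1": [0.4]}, index=["cg1"]))
        pred, rep = predict_ga(bm, clock, with_report=True)
        assert pred["S1"] == pytest.approx(280.0 + 10 * 0.4)
        assert rep.n_excluded == 1 and rep.excluded_probe_ids == ["cg2"]

    def test_missing_cells_imputed_from_dataset_median(self):
        clock = ClockModel(280.0, {"cg1": 10.0})
        vals = pd.DataFrame(
            {"S1": [0.2], "S2": [np.nan], "S3": [0.6]}, index=["cg1"]
        )
        pred = predict_ga(BetaMatrix(vals), clock)
        assert pred["S2"] == pytest.approx(280.0 + 10 * 0.4)

    def test_no_clock_probes_present_is_error(self, random_beta_matrix):
        clock = ClockModel(280.0, {"cgZZ": 1.0})
        with pytest.raises(ValidationError, match="none of the clock"):
            predict_ga(random_beta_matrix(), clock)


class TestEstimatorInterface:
    def test_sklearn_contract(self):
        est = GestationalAgeClock(n_folds=3, random_state=1)
        cloned = clone(est)
        assert cloned.get_params() == est.get_params()

    def test_fit_predict_on_dataframe(self, small_cohort):
        _, bm, sheet, truth = small_cohort
        X = bm.to_samples_by_probes()
        y = sheet.ga("ultrasound").to_numpy()
        est = GestationalAgeClock(n_folds=5, random_state=0).fit(X, y)
        pred = est.predict(X)
        assert pred.shape == y.shape
        # a strong-signal fit explains most in-sample variance
        assert np.corrcoef(pred, y)[0, 1] ** 2 > 0.6
        model = est.to_clock_model()
        assert len(model) == len(est.selected_probes_)

    def test_fixed_lambda_skips_cv(self):
        rng = np.random.default_rng(0)
        X = rng.uniform(0, 1, (40, 10))
        y = X[:, 0] * 20 + rng.normal(280, 2, 40)
        est = GestationalAgeClock(lam=0.05).fit(X, y)
        assert est.cv_result_ is None
        assert est.lambda_ == 0.05


class TestTrainConfig:
    def test_invalid_settings_rejected(self):
        with pytest.raises(ValueError, match="alpha"):
            TrainConfig(alpha=0.5)
        with pytest.raises(ValueError, match="n_folds"):
            TrainConfig(n_folds=1)
        with pytest.raises(ValueError, match="train_fraction"):
            TrainConfig(train_fraction=1.0)
        with pytest.raises(ValueError, match="decreasing"):
            TrainConfig(lambda_grid=[0.1, 0.5])
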