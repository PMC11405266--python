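"""Split/fit/out-of-fold mechanics, gap arithmetic and baselines."""

import numpy as np
import pandas as pd
import pytest

from protclock.clock import (
    Hyperparams,
    ProteomicAgeClock,
    benchmark_baselines,
    compute_gap,
    evaluate_predictions,
    fit_clock,
    oof_protage,
    split_cohort,
    summarize_gap,
    tune_gbm,
)


class TestSplit:
    def test_counts(self):
        train, test = split_cohort([f"s{i}" for i in range(10)], 0.7, seed=0)
        assert len(train) == 7 and len(test) == 3

    def test_reproducible_and_partition(self):
        ids = [f"s{i}" for i in range(53)]
        a = split_cohort(ids, seed=4)
        b = split_cohort(ids, seed=4)
        assert a == b
        train, test = a
        assert set(train) | set(test) == set(ids)
        assert set(train) & set(test) == set()

    def test_rejects_bad_fraction(self):
        with pytest.raises(ValueError, match="train_fraction"):
            split_cohort(list(range(20)), 1.2)


class TestEvaluate:
    def test_perfect(self):
        m = evaluate_predictions(np.array([1.0, 2, 3]), np.array([1.0, 2, 3]))
        assert m.pearson_r == pytest.approx(1.0)
        assert m.r_squared == pytest.approx(1.0)
        assert (m.rmse, m.mae) == (0.0, 0.0)

    def test_constant_prediction_r2_zero(self):
        actual = np.array([1.0, 2, 3, 4])
        m = evaluate_predictions(np.full(4, actual.mean()), actual)
        assert m.r_squared == pytest.approx(0.0)
        assert m.flagged is not None

    def test_hand_values(self):
        m = evaluate_predictions(np.array([1.0, 2, 3]), np.array([1.0, 2, 4]))
        assert m.rmse == pytest.approx(np.sqrt(1 / 3))
        assert m.mae == pytest.approx(1 / 3)

    def test_zero_variance_actual_flagged(self):
        m = evaluate_predictions(np.array([1.0, 2.0]), np.array([3.0, 3.0]))
        assert np.isnan(m.pearson_r) and m.flagged is not None

    def test_rmse_at_least_mae(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            m = evaluate_predictions(rng.normal(size=30), rng.normal(size=30))
            assert m.rmse >= m.mae >= 0


class TestGap:
    def test_arithmetic(self):
        gap = compute_gap(
            pd.Series([56.3], index=["a"]), pd.Series([50.0], index=["a"])
        )
        assert gap.loc["a", "gap"] == pytest.approx(6.3)

    def test_identity(self):
        age = pd.Series([40.0, 50.0], index=["a", "b"])
        assert (compute_gap(age.copy(), age)["gap"] == 0).all()

    def test_id_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            compute_gap(pd.Series([1.0], index=["a"]), pd.Series([1.0], index=["b"]))

    def test_mean_gap_conservation(self):
        rng = np.random.default_rng(1)
        protage = pd.Series(rng.normal(55, 5, 100), index=range(100))
        age = pd.Series(rng.uniform(39, 71, 100), index=range(100))
        gap = compute_gap(protage, age)
        assert gap["gap"].mean() == pytest.approx(protage.mean() - age.mean())


class TestSummarizeGap:
    def test_brute_force_bands(self):
        rng = np.random.default_rng(2)
        gap = pd.Series(rng.normal(0, 3, 20), index=[f"s{i}" for i in range(20)])
        table = pd.DataFrame({"protage": gap + 50, "age": 50.0, "gap": gap})
        out = summarize_gap(table)
        ordered = gap.sort_values()
        assert out.loc["bottom_5pct", "mean_gap"] == pytest.approx(ordered.iloc[0])
        assert out.loc["top_5pct", "mean_gap"] == pytest.approx(ordered.iloc[-1])
        for d in range(10):
            assert out.loc[f"decile_{d + 1}", "mean_gap"] == pytest.approx(
                ordered.iloc[2 * d: 2 * d + 2].mean()
            )

    def test_all_equal(self):
        table = pd.DataFrame({"protage": 50.0, "age": 45.0, "gap": 5.0},
                             index=range(40))
        out = summarize_gap(table)
        assert (out["mean_gap"].drop("top_minus_bottom") == 5.0).all()
        assert out.loc["top_minus_bottom", "mean_gap"] == 0.0

    def test_overlapping_bands_rejected(self):
        table = pd.DataFrame({"protage": [1.0], "age": [1.0], "gap": [0.0]})
        with pytest.raises(ValueError, match="percentile"):
            summarize_gap(table, percentiles=(60, 40))


class TestFitAndOOF:
    def test_refit_identical(self, small_cohort):
        normalized, phen, _ = small_cohort
        train, test = split_cohort(normalized.index, seed=1)
        args = (normalized.loc[train], phen["age"].loc[train],
                Hyperparams(seed=1), normalized.loc[test], phen["age"].loc[test])
        pred_a = fit_clock(*args).predict(normalized.loc[test])
        pred_b = fit_clock(*args).predict(normalized.loc[test])
        pd.testing.assert_series_equal(pred_a, pred_b)

    def test_protein_mismatch_rejected(self, small_cohort):
        normalized, phen, _ = small_cohort
        train, test = split_cohort(normalized.index, seed=1)
        with pytest.raises(ValueError, match="protein"):
            fit_clock(normalized.loc[train], phen["age"].loc[train],
                      Hyperparams(), normalized.loc[test].iloc[:, :-1],
                      phen["age"].loc[test])

    def test_overlap_rejected(self, small_cohort):
        normalized, phen, _ = small_cohort
        with pytest.raises(ValueError, match="disjoint"):
            fit_clock(normalized, phen["age"], Hyperparams(),
                      normalized.iloc[:5], phen["age"].iloc[:5])

    def test_pure_noise_r2_near_zero(self):
        from protclock.synthdata import SynthConfig, generate_cohort
        from protclock.preprocess import normalize_npx

        cfg = SynthConfig(n_samples=600, n_proteins=30, n_aging_proteins=0, seed=13)
        proteins, phen, _ = generate_cohort(cfg)
        normalized, _ = normalize_npx(proteins)
        train, test = split_cohort(normalized.index, seed=13)
        model = fit_clock(normalized.loc[train], phen["age"].loc[train],
                          Hyperparams(seed=13), normalized.loc[test],
                          phen["age"].loc[test])
        m = evaluate_predictions(model.predict(normalized.loc[test]),
                                 phen["age"].loc[test])
        assert m.r_squared <= 0.05

    def test_oof_partition_and_consistency(self, small_cohort):
        normalized, phen, _ = small_cohort
        table = oof_protage(normalized, phen["age"], Hyperparams(seed=3), k=5, seed=3)
        assert set(table.index) == set(normalized.index)
        assert not table["protage"].isna().any()
        assert sorted(table["fold_id"].unique()) == [0, 1, 2, 3, 4]
        assert np.allclose(table["gap"], table["protage"] - table["age"])

    def test_oof_rejects_small_k(self, small_cohort):
        normalized, phen, _ = small_cohort
        with pytest.raises(ValueError, match="k"):
            oof_protage(normalized, phen["age"], Hyperparams(), k=1)


class TestTune:
    def test_single_trial_inside_space(self, small_cohort):
        normalized, phen, _ = small_cohort
        hp = tune_gbm(normalized.iloc[:200], phen["age"].iloc[:200],
                      trials=1, k=3, seed=5)
        assert 0.01 <= hp.learning_rate <= 0.2
        assert 8 <= hp.num_leaves <= 128
        assert 0.5 <= hp.subsample <= 1.0
        assert hp.n_estimators == 5000 and hp.early_stopping_rounds == 20

    def test_deterministic(self, small_cohort):
        normalized, phen, _ = small_cohort
        a = tune_gbm(normalized.iloc[:150], phen["age"].iloc[:150], trials=2, k=3, seed=6)
        b = tune_gbm(normalized.iloc[:150], phen["age"].iloc[:150], trials=2, k=3, seed=6)
        assert a == b

    def test_rejects_zero_trials(self, small_cohort):
        normalized, phen, _ = small_cohort
        with pytest.raises(ValueError, match="trials"):
            tune_gbm(normalized, phen["age"], trials=0)


class TestBenchmark:
    def test_shape_and_heavy_shrinkage(self, small_cohort):
        normalized, phen, _ = small_cohort
        train, test = split_cohort(normalized.index, seed=2)
        out = benchmark_baselines(
            normalized.loc[train], phen["age"].loc[train],
            normalized.loc[test], phen["age"].loc[test],
            external_sets={"ext": (normalized.loc[test], phen["age"].loc[test])},
        )
        assert len(out) == 3 * 2  # 3 models x (test + 1 external)
        assert set(out["model"]) == {"lasso", "elastic_net", "gbm"}

    def test_lasso_alpha_100_near_intercept(self):
        from sklearn.linear_model import Lasso
        from protclock.synthdata import SynthConfig, generate_cohort
        from protclock.preprocess import normalize_npx

        cfg = SynthConfig(n_samples=400, n_proteins=20, n_aging_proteins=10,
                          slope_scale=0.05, seed=3)
        proteins, phen, _ = generate_cohort(cfg)
        normalized, _ = normalize_npx(proteins)
        std = (normalized - normalized.mean()) / normalized.std()
        train, test = split_cohort(std.index, seed=3)
        model = Lasso(alpha=100.0).fit(std.loc[train], phen["age"].loc[train])
        m = evaluate_predictions(model.predict(std.loc[test]), phen["age"].loc[test])
        assert m.r_squared <= 0.05

    def test_boosting_beats_lasso_on_interactions(self):
        """Multiplicative protein-pair effects favour trees over LASSO."""
        rng = np.random.default_rng(7)
        n = 800
        age = rng.uniform(39, 71, n)
        a = (age - 55) / 10 + rng.normal(0, 0.4, n)
        b = rng.choice([-1.0, 1.0], n)
        x = pd.DataFrame(
            {"pa": a * b, "pb": b, "p3": rng.normal(size=n), "p4": rng.normal(size=n)},
            index=[f"s{i}" for i in range(n)],
        )
        agev = pd.Series(age, index=x.index)
        train, test = split_cohort(x.index, seed=7)
        out = benchmark_baselines(x.loc[train], agev.loc[train],
                                  x.loc[test], agev.loc[test],
                                  hyperparams=Hyperparams(seed=7))
        r2 = out.set_index("model")["r_squared"]
        assert r2["gbm"] >= r2["lasso"]


def test_model_results_summary(small_cohort):
    normalized, phen, truth = small_cohort
    clock = ProteomicAgeClock(normalized, phen["age"], seed=11)
    res = clock.fit()
    text = res.summary()
    assert "holdout" in text and "Proteomic age clock" in text
    m = res.metrics["holdout"]
    assert m.pearson_r > 0.8  # strong planted signal
    # summary numbers come from the metrics themselves
    assert f"{m.pearson_r:>10.3f}".strip() in text
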