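"""Association scans, Cox models, Kaplan-Meier incidence and fold risks."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from protclock.epi import (
    association_scan,
    bh_fdr,
    cox_hazard,
    fold_risk,
    km_incidence_by_decile,
    multimorbidity_trend,
)
from protclock.synthdata import (
    OutcomeSpec,
    SynthConfig,
    generate_cohort,
    simulate_survival,
)

from oracles import brute_bh, hand_km_incidence


class TestBH:
    def test_hand_example(self):
        assert np.allclose(bh_fdr([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_and_ones(self):
        assert bh_fdr([0.2]) == pytest.approx([0.2])
        assert np.allclose(bh_fdr([1.0, 1.0]), [1.0, 1.0])

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])

    def test_matches_brute_force_on_random_vectors(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            m = rng.integers(1, 12)
            p = rng.random(m) ** rng.uniform(0.5, 3)
            assert np.allclose(bh_fdr(p), brute_bh(p), atol=1e-12)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=20))
    def test_monotone_in_p_rank(self, ps):
        q = bh_fdr(ps)
        order = np.argsort(ps, kind="stable")
        assert (np.diff(q[order]) >= -1e-12).all()
        assert (q >= np.asarray(ps) - 1e-12).all() and (q <= 1.0).all()


@pytest.fixture(scope="module")
def survival_cohort():
    cfg = SynthConfig(
        n_samples=4000, n_proteins=2, n_aging_proteins=0, aging_rate_sd=3.0,
        seed=21,
        outcome_specs=(OutcomeSpec("d", 0.02, 0.2, 0.1, 14.0),),
    )
    _, phen, truth = generate_cohort(cfg)
    out = simulate_survival(truth, phen, cfg.outcome_specs[0], seed=21)
    return phen, truth, out


class TestAssociationScan:
    def test_recovers_planted_effect(self):
        rng = np.random.default_rng(1)
        n = 5000
        idx = pd.Index([f"s{i}" for i in range(n)], name="sample_id")
        gap = pd.Series(rng.normal(0, 3, n), index=idx)
        cov = pd.DataFrame({
            "age": rng.uniform(39, 71, n), "sex": rng.integers(0, 2, n),
            "deprivation": rng.normal(size=n), "center": rng.integers(0, 3, n),
            "activity": rng.integers(0, 3, n), "smoking": rng.integers(0, 3, n),
        }, index=idx)
        phen = pd.DataFrame({"trait": 0.5 * gap + rng.normal(0, 1, n)}, index=idx)
        out = association_scan(gap, phen, cov, phenotype_cols=["trait"])
        row = out.iloc[0]
        assert row["family"] == "linear"
        assert row["beta"] == pytest.approx(0.5, abs=0.05)
        assert row["q"] < 0.05

    def test_permutation_null_calibrated(self):
        """~5% of raw p-values below 0.05 under a permuted null."""
        rng = np.random.default_rng(2)
        n, m = 400, 200
        idx = pd.Index([f"s{i}" for i in range(n)])
        gap = pd.Series(rng.normal(0, 3, n), index=idx)
        cov = pd.DataFrame({"age": rng.uniform(39, 71, n),
                            "sex": rng.integers(0, 2, n)}, index=idx)
        phen = pd.DataFrame(rng.normal(size=(n, m)),
                            columns=[f"t{j}" for j in range(m)], index=idx)
        out = association_scan(gap, phen, cov, adjust_for=["age", "sex"])
        frac = (out["p"] < 0.05).mean()
        half = 1.96 * np.sqrt(0.05 * 0.95 / m)
        assert abs(frac - 0.05) <= half

    def test_constant_gap_flagged(self):
        idx = pd.Index([f"s{i}" for i in range(50)])
        gap = pd.Series(1.0, index=idx)
        rng = np.random.default_rng(3)
        cov = pd.DataFrame({"age": rng.uniform(39, 71, 50),
                            "sex": rng.integers(0, 2, 50)}, index=idx)
        phen = pd.DataFrame({"t": rng.normal(size=50)}, index=idx)
        out = association_scan(gap, phen, cov, adjust_for=["age", "sex"])
        assert out.iloc[0]["flag"] == "zero-variance exposure"

    def test_single_class_binary_skipped(self):
        idx = pd.Index([f"s{i}" for i in range(50)])
        rng = np.random.default_rng(4)
        gap = pd.Series(rng.normal(size=50), index=idx)
        cov = pd.DataFrame({"age": rng.uniform(39, 71, 50),
                            "sex": rng.integers(0, 2, 50)}, index=idx)
        phen = pd.DataFrame({"t": np.zeros(50)}, index=idx)
        out = association_scan(gap, phen, cov, adjust_for=["age", "sex"])
        assert len(out) == 0


class TestCox:
    def test_prevalent_exclusion_arithmetic(self):
        idx = [f"s{i}" for i in range(10)]
        rng = np.random.default_rng(5)
        out = pd.DataFrame({
            "sample_id": idx, "endpoint": "d",
            "prevalent": [1, 1, 1] + [0] * 7,
            "event": [0] * 3 + [1, 0, 1, 0, 1, 0, 1],
            "time": rng.uniform(1, 10, 10),
        })
        gap = pd.Series(rng.normal(size=10), index=idx)
        cov = pd.DataFrame({"age": rng.uniform(39, 71, 10),
                            "sex": rng.integers(0, 2, 10)}, index=idx)
        res = cox_hazard(gap, out, cov, tier=1)
        assert res.iloc[0]["n"] == 7
        assert res.iloc[0]["events"] == 4
        assert res.iloc[0]["flag"] is not None  # low power flag

    def test_recovers_gamma(self, survival_cohort):
        phen, truth, out = survival_cohort
        res = cox_hazard(truth.delta, out, phen, tier=3)
        assert res.iloc[0]["hr"] == pytest.approx(np.exp(0.2), rel=0.05)
        assert res.iloc[0]["ci_low"] < res.iloc[0]["hr"] < res.iloc[0]["ci_high"]

    def test_rejects_bad_tier(self, survival_cohort):
        phen, truth, out = survival_cohort
        with pytest.raises(ValueError, match="tier"):
            cox_hazard(truth.delta, out, phen, tier=4)


class TestKM:
    def test_all_censored_zero_incidence(self):
        idx = ["a", "b", "c", "d", "e"]
        out = pd.DataFrame({"sample_id": idx, "endpoint": "d",
                            "prevalent": 0, "event": 0,
                            "time": [1.0, 2, 3, 4, 5]})
        gap = pd.Series([0.0, 1, 2, 3, 4], index=idx)
        km = km_incidence_by_decile(gap, out, deciles=("all",), axis="time")
        assert (km["incidence"] == 0.0).all()

    def test_hand_product_limit_two_records(self):
        out = pd.DataFrame({"sample_id": ["a", "b"], "endpoint": "d",
                            "prevalent": 0, "event": [1, 0],
                            "time": [1.0, 2.0]})
        gap = pd.Series([0.0, 1.0], index=["a", "b"])
        km = km_incidence_by_decile(gap, out, deciles=("all",), axis="time")
        grp = km[km["group"] == "all"].set_index("grid")
        assert grp.loc[1.0, "incidence"] == pytest.approx(0.5)

    def test_matches_hand_km_on_small_fixtures(self):
        """Product-limit oracle on every <=5-record fixture pattern."""
        rng = np.random.default_rng(6)
        for _ in range(30):
            n = rng.integers(2, 6)
            times = np.round(rng.uniform(0.5, 5.0, n), 1)
            events = rng.integers(0, 2, n)
            if events.sum() == 0:
                events[0] = 1
            idx = [f"s{i}" for i in range(n)]
            out = pd.DataFrame({"sample_id": idx, "endpoint": "d",
                                "prevalent": 0, "event": events,
                                "time": times})
            gap = pd.Series(np.zeros(n), index=idx)
            km = km_incidence_by_decile(gap, out, deciles=("all",), axis="time")
            got = km.set_index("grid")["incidence"]
            for t, inc in hand_km_incidence(times, events):
                assert got.loc[t] == pytest.approx(inc, abs=1e-12)

    def test_gradient_orders_deciles(self, survival_cohort):
        phen, truth, out = survival_cohort
        km = km_incidence_by_decile(truth.delta, out, phen,
                                    deciles=("bottom", "top"), axis="time")
        top = km[km.group == "top"].set_index("grid")["incidence"]
        bottom = km[km.group == "bottom"].set_index("grid")["incidence"]
        grid = np.linspace(0.5, 13.5, 20)
        top_i = np.interp(grid, top.index, top.to_numpy())
        bot_i = np.interp(grid, bottom.index, bottom.to_numpy())
        assert (top_i >= bot_i - 1e-9).all()

    def test_age_axis_monotone_nondecreasing(self, survival_cohort):
        phen, truth, out = survival_cohort
        km = km_incidence_by_decile(truth.delta, out, phen,
                                    deciles=("top",), axis="age")
        inc = km[km.group == "top"]["incidence"].to_numpy()
        assert (np.diff(inc) >= -1e-12).all()
        assert ((km["incidence"] >= 0) & (km["incidence"] <= 1)).all()


class TestFoldRisk:
    def test_study_worked_example(self):
        assert round(fold_risk(1.10, 6.3), 1) == 1.8

    def test_zero_exponent(self):
        assert fold_risk(1.5, 0.0) == 1.0

    def test_direct_exponentiation(self):
        assert fold_risk(1.16, 6.3) == pytest.approx(1.16**6.3)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.floats(min_value=0.5, max_value=2.0),
           st.floats(min_value=-10, max_value=10),
           st.floats(min_value=-10, max_value=10))
    def test_multiplicative(self, hr, a, b):
        assert fold_risk(hr, a + b) == pytest.approx(
            fold_risk(hr, a) * fold_risk(hr, b), rel=1e-12
        )

    def test_rejects_nonpositive_hr(self):
        with pytest.raises(ValueError):
            fold_risk(0.0, 1.0)


class TestMultimorbidity:
    def test_all_zero_counts_single_category(self):
        idx = [f"s{i}" for i in range(20)]
        gap = pd.Series(np.arange(20.0), index=idx)
        counts = pd.Series(0, index=idx)
        out = multimorbidity_trend(gap, counts)
        assert out["category"].tolist() == ["0"]
        assert out.iloc[0]["n"] == 20

    def test_brute_force_category_means(self):
        rng = np.random.default_rng(7)
        idx = [f"s{i}" for i in range(15)]
        gap = pd.Series(rng.normal(size=15), index=idx)
        counts = pd.Series([0, 0, 1, 1, 2, 2, 3, 3, 4, 5, 6, 0, 1, 2, 4],
                           index=idx)
        out = multimorbidity_trend(gap, counts).set_index("category")
        pooled = counts.clip(upper=4)
        for cat, code in [("0", 0), ("1", 1), ("2", 2), ("3", 3), ("4+", 4)]:
            members = gap[pooled == code]
            assert out.loc[cat, "mean_gap"] == pytest.approx(members.mean())
            assert out.loc[cat, "n"] == len(members)

    def test_trend_rises_with_hazard_driven_counts(self):
        """Disease hazards rising with the latent deviation produce a
        non-decreasing mean-gap trend across diagnosis counts."""
        rises = 0
        for seed in range(5):
            cfg = SynthConfig(
                n_samples=3000, n_proteins=2, n_aging_proteins=0,
                aging_rate_sd=3.0, seed=seed,
                outcome_specs=tuple(
                    OutcomeSpec(f"d{j}", 0.02, 0.25, 0.0, 14.0) for j in range(4)
                ),
            )
            _, phen, truth = generate_cohort(cfg)
            from protclock.synthdata import diagnosis_counts, simulate_all_outcomes

            outs = simulate_all_outcomes(truth, phen, cfg.outcome_specs, seed=seed)
            trend = multimorbidity_trend(truth.delta, diagnosis_counts(outs))
            means = trend["mean_gap"].to_numpy()
            rises += (np.diff(means) >= -0.05).all()
        assert rises >= 4

    def test_rejects_negative_counts(self):
        gap = pd.Series([1.0], index=["a"])
        with pytest.raises(ValueError):
            multimorbidity_trend(gap, pd.Series([-1], index=["a"]))
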