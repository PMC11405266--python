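import lightgbm as lgb
import numpy as np
import pandas as pd
import pytest

from protclock.clock import ClockModel, Hyperparams
from protclock.preprocess import normalize_npx
from protclock.synthdata import SynthConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A small planted-signal cohort: 10 strong agers among 30 proteins."""
    cfg = SynthConfig(
        n_samples=500, n_proteins=30, n_aging_proteins=10,
        slope_scale=0.05, slope_dist="fixed", noise_sd=0.2, seed=11,
    )
    proteins, phen, truth = generate_cohort(cfg)
    normalized, _ = normalize_npx(proteins)
    return normalized, phen, truth


@pytest.fixture(scope="session")
def small_clock(small_cohort):
    """A fitted clock on the small cohort (fast, deterministic)."""
    from protclock.clock import fit_clock, split_cohort

    normalized, phen, _ = small_cohort
    train, test = split_cohort(normalized.index, seed=11)
    model = fit_clock(
        normalized.loc[train], phen["age"].loc[train],
        Hyperparams(seed=11), normalized.loc[test], phen["age"].loc[test],
    )
    return model, normalized, phen


def train_toy_booster(n=300, p=3, num_leaves=4, rounds=3, seed=1, interaction=True):
    """A deliberately tiny booster for exact attribution checks."""
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    y = X[:, 0] * (X[:, 1] if interaction else 1.0) + 0.5 * X[:, -1]
    y = y + rng.normal(0, 0.05, n)
    booster = lgb.train(
        dict(objective="regression", num_leaves=num_leaves, learning_rate=0.5,
             verbosity=-1, deterministic=True, force_row_wise=True,
             num_threads=1, seed=seed, min_data_in_leaf=5),
        lgb.Dataset(X, label=y),
        num_boost_round=rounds,
    )
    return booster, X


def as_clock_model(booster, n_features, seed=0) -> ClockModel:
    proteins = [f"P{i}" for i in range(n_features)]
    return ClockModel(
        booster=booster, proteins=proteins, hyperparams=Hyperparams(seed=seed),
        train_ids=[], seed=seed, best_iteration=booster.current_iteration(),
    )


def frame(X, prefix="P") -> pd.DataFrame:
    return pd.DataFrame(X, columns=[f"{prefix}{i}" for i in range(X.shape[1])])
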