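"""The proteomic age clock: boosted-tree age prediction and the age gap.

The clock is a gradient-boosted tree regressor (LightGBM) trained to
predict chronological age from normalized protein expression, with a
5,000-estimator cap and 20-round early stopping on holdout R^2.  The
cohort-wide predicted age ("protein-predicted age", here ``protage``)
is computed out-of-fold: each sample is predicted by a model whose
training folds exclude it.  The proteomic age gap is ``protage`` minus
chronological age; positive values indicate accelerated aging.

The module follows a model/results organisation: build a
:class:`ProteomicAgeClock` from a matrix and ages, call ``tune`` /
``fit`` / ``fit_oof``, and read estimates off the returned
:class:`ClockResults`.  The underlying operations (``split_cohort``,
``fit_clock``, ``oof_protage``, ...) are plain functions usable on
their own.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, replace
from pathlib import Path

import lightgbm as lgb
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import ElasticNetCV, LassoCV
from sklearn.model_selection import KFold

__all__ = [
    "Hyperparams",
    "ClockModel",
    "EvalMetrics",
    "ProteomicAgeClock",
    "ClockResults",
    "split_cohort",
    "tune_gbm",
    "fit_clock",
    "oof_protage",
    "compute_gap",
    "summarize_gap",
    "evaluate_predictions",
    "benchmark_baselines",
    "DEFAULT_SEARCH_SPACE",
    "PAPER_ALPHA_GRID",
    "PAPER_L1_RATIO_GRID",
]

#: alpha grid used to tune the linear baselines by cross-validation
PAPER_ALPHA_GRID = (
    1e-15, 1e-10, 1e-8, 1e-5, 1e-4, 1e-3, 1e-2, 1.0, 5.0, 10.0, 50.0, 100.0
)
PAPER_L1_RATIO_GRID = (0.1, 0.5, 0.7, 0.9, 0.95, 0.99, 1.0)

#: random-search space for ``tune_gbm`` (log-scale bounds where noted)
DEFAULT_SEARCH_SPACE: dict[str, tuple] = {
    "learning_rate": ("log", 0.01, 0.2),
    "num_leaves": ("int", 8, 128),
    "max_depth": ("int", 3, 12),
    "subsample": ("uniform", 0.5, 1.0),
    "colsample": ("uniform", 0.2, 1.0),
    "reg_alpha": ("log", 1e-8, 10.0),
    "reg_lambda": ("log", 1e-8, 10.0),
    "min_child_samples": ("int", 5, 100),
}


@dataclass(frozen=True)
class Hyperparams:
    """Boosted-tree settings; the estimator cap and early-stopping
    patience are fixed study-wide unless explicitly overridden."""

    learning_rate: float = 0.05
    num_leaves: int = 31
    max_depth: int = -1
    subsample: float = 1.0  # row (bagging) fraction
    colsample: float = 0.8  # feature fraction per tree
    reg_alpha: float = 0.0
    reg_lambda: float = 0.0
    min_child_samples: int = 20
    n_estimators: int = 5000
    early_stopping_rounds: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("subsample", "colsample"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must lie in (0, 1], got {v}")

    def lgb_params(self) -> dict:
        return {
            "objective": "regression",
            "metric": "None",
            "learning_rate": self.learning_rate,
            "num_leaves": self.num_leaves,
            "max_depth": self.max_depth,
            "bagging_fraction": self.subsample,
            "bagging_freq": 1 if self.subsample < 1.0 else 0,
            "feature_fraction": self.colsample,
            "lambda_l1": self.reg_alpha,
            "lambda_l2": self.reg_lambda,
            "min_data_in_leaf": self.min_child_samples,
            "seed": self.seed,
            "deterministic": True,
            "force_row_wise": True,
            "num_threads": 1,
            "verbosity": -1,
        }


def _r2_feval(preds: np.ndarray, dataset: lgb.Dataset) -> tuple[str, float, bool]:
    """Coefficient of determination as a LightGBM evaluation metric."""
    y = dataset.get_label()
    ss_res = float(np.sum((y - preds) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    return "r2", 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0, True


@dataclass
class ClockModel:
    """A fitted clock: booster, protein order and training provenance."""

    booster: lgb.Booster
    proteins: list[str]
    hyperparams: Hyperparams
    train_ids: list[str]
    seed: int
    best_iteration: int

    def _check(self, matrix: pd.DataFrame) -> pd.DataFrame:
        if set(matrix.columns) != set(self.proteins):
            raise ValueError(
                "protein set mismatch: model expects exactly its stored protein list"
            )
        return matrix[self.proteins]

    def predict(self, matrix: pd.DataFrame) -> pd.Series:
        x = self._check(matrix)
        pred = self.booster.predict(
            x.to_numpy(dtype=float), num_iteration=self.best_iteration
        )
        return pd.Series(pred, index=matrix.index, name="protage")

    def save(self, path: str | Path) -> None:
        path = Path(path)
        self.booster.save_model(str(path), num_iteration=self.best_iteration)
        path.with_suffix(".proteins.txt").write_text("\n".join(self.proteins) + "\n")


@dataclass(frozen=True)
class EvalMetrics:
    pearson_r: float
    r_squared: float
    rmse: float
    mae: float
    flagged: str | None = None

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


def split_cohort(
    samples: pd.Index | list, train_fraction: float = 0.70, seed: int = 0
) -> tuple[list, list]:
    """Disjoint, exhaustive, seed-reproducible train/test id split."""
    if not 0.0 < train_fraction < 1.0:
        raise ValueError(f"train_fraction must lie in (0, 1), got {train_fraction}")
    ids = list(samples)
    if len(ids) < 10:
        raise ValueError("need at least 10 samples to split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    n_train = int(round(train_fraction * len(ids)))
    train = [ids[i] for i in sorted(order[:n_train])]
    test = [ids[i] for i in sorted(order[n_train:])]
    return train, test


def fit_clock(
    train: pd.DataFrame,
    train_age: pd.Series,
    hyperparams: Hyperparams,
    eval_holdout: pd.DataFrame,
    holdout_age: pd.Series,
) -> ClockModel:
    """Fit the boosted-tree clock with early stopping on holdout R^2."""
    if list(train.columns) != list(eval_holdout.columns):
        raise ValueError("protein mismatch between train and holdout matrices")
    if set(train.index) & set(eval_holdout.index):
        raise ValueError("holdout must be disjoint from training samples")
    dtrain = lgb.Dataset(train.to_numpy(dtype=float), label=train_age.to_numpy(dtype=float))
    dvalid = lgb.Dataset(
        eval_holdout.to_numpy(dtype=float),
        label=holdout_age.to_numpy(dtype=float),
        reference=dtrain,
    )
    booster = lgb.train(
        hyperparams.lgb_params(),
        dtrain,
        num_boost_round=hyperparams.n_estimators,
        valid_sets=[dvalid],
        feval=_r2_feval,
        callbacks=[
            lgb.early_stopping(hyperparams.early_stopping_rounds, verbose=False)
        ],
    )
    return ClockModel(
        booster=booster,
        proteins=list(train.columns),
        hyperparams=hyperparams,
        train_ids=list(train.index),
        seed=hyperparams.seed,
        best_iteration=booster.best_iteration,
    )


def _sample_hyperparams(rng: np.random.Generator, space: dict, seed: int) -> Hyperparams:
    draw: dict = {}
    for name, (kind, lo, hi) in space.items():
        if kind == "log":
            draw[name] = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        elif kind == "uniform":
            draw[name] = float(rng.uniform(lo, hi))
        elif kind == "int":
            draw[name] = int(rng.integers(lo, hi + 1))
        else:  # pragma: no cover - config error
            raise ValueError(f"unknown search-space kind {kind!r} for {name}")
    return Hyperparams(seed=seed, **draw)


def cv_r2(
    matrix: pd.DataFrame,
    age: pd.Series,
    hyperparams: Hyperparams,
    k: int = 5,
    seed: int = 0,
) -> float:
    """Mean k-fold R^2; each fold's held-out part doubles as the
    early-stopping set of that fold's model."""
    kf = KFold(n_splits=k, shuffle=True, random_state=seed)
    scores = []
    x = matrix.to_numpy(dtype=float)
    y = age.to_numpy(dtype=float)
    for tr, va in kf.split(x):
        model = fit_clock(
            matrix.iloc[tr], age.iloc[tr], hyperparams, matrix.iloc[va], age.iloc[va]
        )
        pred = model.booster.predict(x[va], num_iteration=model.best_iteration)
        ss_res = float(np.sum((y[va] - pred) ** 2))
        ss_tot = float(np.sum((y[va] - np.mean(y[va])) ** 2))
        scores.append(1.0 - ss_res / ss_tot)
    return float(np.mean(scores))


def tune_gbm(
    matrix: pd.DataFrame,
    age: pd.Series,
    trials: int = 200,
    k: int = 5,
    seed: int = 0,
    space: dict | None = None,
) -> Hyperparams:
    """Seeded random search maximising mean k-fold R^2.

    Returns the best candidate of ``trials`` draws from ``space``
    (``DEFAULT_SEARCH_SPACE`` by default); deterministic under ``seed``.
    """
    if trials < 1:
        raise ValueError("trials must be >= 1")
    if len(matrix) < k:
        raise ValueError("need at least k samples for k-fold tuning")
    space = DEFAULT_SEARCH_SPACE if space is None else space
    rng = np.random.default_rng(seed)
    best: tuple[float, Hyperparams] | None = None
    for _ in range(trials):
        cand = _sample_hyperparams(rng, space, seed=seed)
        score = cv_r2(matrix, age, cand, k=k, seed=seed)
        if best is None or score > best[0]:
            best = (score, cand)
    return best[1]


def oof_protage(
    matrix: pd.DataFrame,
    age: pd.Series,
    hyperparams: Hyperparams,
    k: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Out-of-fold predicted age for the whole cohort.

    Every sample is predicted exactly once, by the model of the single
    fold that held it out; the fold's held-out part is also that
    model's early-stopping set.  Returns a gap table with columns
    ``protage, age, gap, fold_id``.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    kf = KFold(n_splits=k, shuffle=True, random_state=seed)
    protage = pd.Series(index=matrix.index, dtype=float, name="protage")
    fold_id = pd.Series(index=matrix.index, dtype=int, name="fold_id")
    for f, (tr, va) in enumerate(kf.split(matrix.to_numpy())):
        model = fit_clock(
            matrix.iloc[tr], age.iloc[tr], hyperparams, matrix.iloc[va], age.iloc[va]
        )
        protage.iloc[va] = model.predict(matrix.iloc[va]).to_numpy()
        fold_id.iloc[va] = f
    table = compute_gap(protage, age)
    table["fold_id"] = fold_id
    return table


def compute_gap(protage: pd.Series, age: pd.Series) -> pd.DataFrame:
    """Gap table: ``gap = protage - age`` elementwise on aligned ids."""
    if set(protage.index) != set(age.index):
        raise ValueError("sample id mismatch between predicted and chronological age")
    age = age.reindex(protage.index)
    return pd.DataFrame(
        {"protage": protage, "age": age, "gap": protage - age},
        index=protage.index,
    ).rename_axis("sample_id")


def summarize_gap(
    gap_table: pd.DataFrame, percentiles: tuple[float, float] = (5.0, 95.0)
) -> pd.DataFrame:
    """Mean gap per decile and per extreme percentile band.

    Returns a table with rows ``decile_1`` ... ``decile_10``,
    ``bottom_<p>pct``, ``top_<p>pct`` and ``top_minus_bottom`` (the
    difference of the extreme-band means), columns ``mean_gap, n``.
    """
    if gap_table.empty:
        raise ValueError("empty gap table")
    lo, hi = percentiles
    if not 0 < lo < hi < 100:
        raise ValueError(f"percentile bands overlap or are out of range: {percentiles}")
    gap = gap_table["gap"]
    rows: dict[str, tuple[float, int]] = {}
    ranks = gap.rank(method="first", pct=True)
    for d in range(10):
        sel = (ranks > d / 10) & (ranks <= (d + 1) / 10)
        rows[f"decile_{d + 1}"] = (float(gap[sel].mean()), int(sel.sum()))
    bottom = ranks <= lo / 100
    top = ranks > hi / 100
    rows[f"bottom_{lo:g}pct"] = (float(gap[bottom].mean()), int(bottom.sum()))
    rows[f"top_{100 - hi:g}pct"] = (float(gap[top].mean()), int(top.sum()))
    diff = rows[f"top_{100 - hi:g}pct"][0] - rows[f"bottom_{lo:g}pct"][0]
    rows["top_minus_bottom"] = (float(diff), int(top.sum() + bottom.sum()))
    out = pd.DataFrame.from_dict(rows, orient="index", columns=["mean_gap", "n"])
    return out.rename_axis("band")


def evaluate_predictions(pred: pd.Series | np.ndarray, actual: pd.Series | np.ndarray) -> EvalMetrics:
    """Pearson r, coefficient of determination, RMSE and MAE."""
    pred = np.asarray(pred, dtype=float)
    actual = np.asarray(actual, dtype=float)
    if pred.shape != actual.shape or pred.ndim != 1 or len(pred) < 2:
        raise ValueError("pred and actual must be equal-length vectors, n >= 2")
    resid = actual - pred
    rmse = float(np.sqrt(np.mean(resid**2)))
    mae = float(np.mean(np.abs(resid)))
    ss_tot = float(np.sum((actual - actual.mean()) ** 2))
    flagged = None
    if ss_tot == 0:
        r = float("nan")
        r2 = float("nan")
        flagged = "zero variance in actual; correlation undefined"
    else:
        r2 = 1.0 - float(np.sum(resid**2)) / ss_tot
        if np.std(pred) == 0:
            r = float("nan")
            flagged = "constant predictions; correlation undefined"
        else:
            r = float(stats.pearsonr(pred, actual)[0])
    return EvalMetrics(pearson_r=r, r_squared=r2, rmse=rmse, mae=mae, flagged=flagged)


def benchmark_baselines(
    train: pd.DataFrame,
    train_age: pd.Series,
    test: pd.DataFrame,
    test_age: pd.Series,
    external_sets: dict[str, tuple[pd.DataFrame, pd.Series]] | None = None,
    hyperparams: Hyperparams | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Compare LASSO, elastic net and the boosted-tree clock.

    Linear baselines are tuned by fivefold cross-validation over the
    study's alpha grid (and L1-ratio grid for the elastic net).  Each
    model is evaluated on the test set and on any external sets; one
    row per (model, evaluation set).
    """
    sets = {"test": (test, test_age)}
    sets.update(external_sets or {})
    for name, (x, _) in list(sets.items()) + [("train", (train, train_age))]:
        if x.isna().to_numpy().any():
            raise ValueError(f"missing values in evaluation set {name!r}")
        if list(x.columns) != list(train.columns):
            raise ValueError(f"protein mismatch in evaluation set {name!r}")
    hyperparams = hyperparams or Hyperparams(seed=seed)

    xt = train.to_numpy(dtype=float)
    yt = train_age.to_numpy(dtype=float)
    lasso = LassoCV(alphas=list(PAPER_ALPHA_GRID), cv=5, random_state=seed, max_iter=5000)
    lasso.fit(xt, yt)
    enet = ElasticNetCV(
        alphas=list(PAPER_ALPHA_GRID), l1_ratio=list(PAPER_L1_RATIO_GRID),
        cv=5, random_state=seed, max_iter=5000,
    )
    enet.fit(xt, yt)
    gbm = fit_clock(train, train_age, hyperparams, test, test_age)

    rows = []
    for set_name, (x, y) in sets.items():
        preds = {
            "lasso": lasso.predict(x.to_numpy(dtype=float)),
            "elastic_net": enet.predict(x.to_numpy(dtype=float)),
            "gbm": gbm.predict(x).to_numpy(),
        }
        for model_name, pred in preds.items():
            m = evaluate_predictions(pred, y.to_numpy(dtype=float))
            rows.append({"model": model_name, "eval_set": set_name, **m.as_dict()})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# model / results interface


class ProteomicAgeClock:
    """Proteomic age clock model bound to a cohort.

    Parameters
    ----------
    proteins : complete, normalized samples-by-proteins matrix.
    age : chronological age (years), indexed like ``proteins``.
    hyperparams : boosted-tree settings; defaults used when omitted.
    seed : governs the train/test split, folds and booster seeds.
    """

    def __init__(
        self,
        proteins: pd.DataFrame,
        age: pd.Series,
        hyperparams: Hyperparams | None = None,
        seed: int = 0,
    ):
        if proteins.isna().to_numpy().any():
            raise ValueError("protein matrix must be complete (impute first)")
        if not proteins.index.equals(age.index):
            age = age.reindex(proteins.index)
            if age.isna().any():
                raise ValueError("age missing for some samples")
        self.proteins = proteins
        self.age = age
        self.seed = seed
        self.hyperparams = hyperparams or Hyperparams(seed=seed)

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        age_col: str = "age",
        protein_cols: list[str] | None = None,
        **kwargs,
    ) -> "ProteomicAgeClock":
        """Build from one table holding age and protein columns."""
        if protein_cols is None:
            protein_cols = [c for c in df.columns if c != age_col]
        return cls(df[protein_cols], df[age_col], **kwargs)

    def tune(self, trials: int = 200, k: int = 5, train_ids: list | None = None) -> Hyperparams:
        ids = train_ids if train_ids is not None else split_cohort(
            self.proteins.index, seed=self.seed
        )[0]
        self.hyperparams = replace(
            tune_gbm(
                self.proteins.loc[ids], self.age.loc[ids],
                trials=trials, k=k, seed=self.seed,
            ),
            seed=self.seed,
        )
        return self.hyperparams

    def fit(
        self,
        train_fraction: float = 0.70,
        feature_subset: list[str] | None = None,
    ) -> "ClockResults":
        """Train on a 70:30 split with early stopping on the holdout."""
        train_ids, test_ids = split_cohort(
            self.proteins.index, train_fraction=train_fraction, seed=self.seed
        )
        x = self.proteins if feature_subset is None else self.proteins[feature_subset]
        model = fit_clock(
            x.loc[train_ids], self.age.loc[train_ids],
            self.hyperparams, x.loc[test_ids], self.age.loc[test_ids],
        )
        holdout_pred = model.predict(x.loc[test_ids])
        metrics = {
            "holdout": evaluate_predictions(holdout_pred, self.age.loc[test_ids])
        }
        gap = compute_gap(holdout_pred, self.age.loc[test_ids])
        return ClockResults(
            model=model, gap_table=gap, metrics=metrics,
            train_ids=train_ids, holdout_ids=test_ids, kind="holdout",
        )

    def fit_oof(self, k: int = 5, feature_subset: list[str] | None = None) -> "ClockResults":
        """Out-of-fold predicted age for the whole cohort, k folds."""
        x = self.proteins if feature_subset is None else self.proteins[feature_subset]
        gap = oof_protage(x, self.age, self.hyperparams, k=k, seed=self.seed)
        metrics = {"oof": evaluate_predictions(gap["protage"], gap["age"])}
        train_ids, test_ids = split_cohort(self.proteins.index, seed=self.seed)
        model = fit_clock(
            x.loc[train_ids], self.age.loc[train_ids],
            self.hyperparams, x.loc[test_ids], self.age.loc[test_ids],
        )
        return ClockResults(
            model=model, gap_table=gap, metrics=metrics,
            train_ids=list(x.index), holdout_ids=[], kind="oof",
        )


@dataclass
class ClockResults:
    """Results of a clock fit: fitted model, gap table and metrics."""

    model: ClockModel
    gap_table: pd.DataFrame
    metrics: dict[str, EvalMetrics]
    train_ids: list
    holdout_ids: list
    kind: str = "holdout"

    def predict(self, matrix: pd.DataFrame) -> pd.Series:
        return self.model.predict(matrix)

    def gap_summary(self, percentiles: tuple[float, float] = (5.0, 95.0)) -> pd.DataFrame:
        return summarize_gap(self.gap_table, percentiles)

    def summary(self) -> str:
        lines = [
            "Proteomic age clock results",
            "===========================",
            f"kind:              {self.kind}",
            f"proteins:          {len(self.model.proteins)}",
            f"training samples:  {len(self.train_ids)}",
            f"boosting rounds:   {self.model.best_iteration}",
            "",
            f"{'set':<10}{'pearson_r':>10}{'R2':>8}{'RMSE':>8}{'MAE':>8}",
        ]
        for name, m in self.metrics.items():
            lines.append(
                f"{name:<10}{m.pearson_r:>10.3f}{m.r_squared:>8.3f}"
                f"{m.rmse:>8.3f}{m.mae:>8.3f}"
            )
        gap = self.gap_table["gap"]
        lines += [
            "",
            f"gap mean: {gap.mean():+.3f} y   sd: {gap.std():.3f} y   n: {len(gap)}",
        ]
        return "\n".join(lines)
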