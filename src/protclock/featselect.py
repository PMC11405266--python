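"""Shadow-feature (Boruta) selection and SHAP-driven recursive elimination.

Boruta decides which proteins carry real age signal by pitting each
surviving feature against permuted "shadow" copies of all features:
within an iteration the model is refitted over a number of trials with
freshly drawn shadows, feature importance is the mean absolute Shapley
attribution, and a feature survives only if its importance (averaged
over the iteration's trials) beats the threshold-quantile of the shadow
importances (the shadow maximum at the default 100% threshold).  The
procedure repeats until no surviving feature fails.

Recursive feature elimination then ranks the selected panel: at each
step a k-fold cross-validated model is fitted, per-fold mean-|SHAP|
importances are computed, and the least important protein is removed
(when folds disagree about the minimum, the protein ranked lowest in
the greatest number of folds goes; residual ties break
lexicographically), down to a terminal five-protein panel.  The
smallest panel retaining 95% of the full panel's age-prediction
performance is the reduced clock.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold

from protclock.clock import ClockModel, Hyperparams, fit_clock, split_cohort

log = logging.getLogger(__name__)

__all__ = [
    "BorutaResult",
    "RFECurve",
    "shap_importance",
    "boruta_select",
    "shap_rfe",
    "select_reduced_panel",
]


def shap_importance(model: ClockModel, data: pd.DataFrame) -> pd.Series:
    """Mean absolute Shapley attribution per protein over ``data``.

    Attributions are exact path-dependent tree Shapley values from the
    booster; for every sample the base value plus the attribution row
    sums to the model prediction.
    """
    x = model._check(data)
    contrib = model.booster.predict(
        x.to_numpy(dtype=float),
        pred_contrib=True,
        num_iteration=model.best_iteration,
    )
    imp = np.abs(contrib[:, :-1]).mean(axis=0)
    return pd.Series(imp, index=model.proteins, name="importance")


@dataclass
class BorutaResult:
    """Outcome of shadow-feature selection."""

    selected: list[str]
    dropped_per_iteration: list[list[str]]
    shadow_max_per_trial: list[float]
    trials: int
    threshold: float

    @property
    def dropped(self) -> list[str]:
        return [p for it in self.dropped_per_iteration for p in it]

    def frame(self) -> pd.DataFrame:
        rows = [(p, "selected", -1) for p in self.selected]
        for it, plist in enumerate(self.dropped_per_iteration):
            rows += [(p, "dropped", it) for p in plist]
        return pd.DataFrame(rows, columns=["protein", "decision", "iteration"])


def _fit_with_internal_holdout(
    x: pd.DataFrame, y: pd.Series, hyperparams: Hyperparams, seed: int
) -> ClockModel:
    """Fit with early stopping on an internal 15% split (seeded)."""
    tr, va = split_cohort(x.index, train_fraction=0.85, seed=seed)
    return fit_clock(x.loc[tr], y.loc[tr], hyperparams, x.loc[va], y.loc[va])


def boruta_select(
    train: pd.DataFrame,
    age: pd.Series,
    hyperparams: Hyperparams,
    trials: int = 200,
    threshold: float = 1.0,
    seed: int = 0,
    max_iterations: int = 50,
) -> BorutaResult:
    """Iterative shadow-feature selection driven by Shapley importance.

    Per trial, a permuted shadow copy of every surviving feature is
    appended, the clock is refitted on the augmented matrix, and
    mean-|SHAP| importances are computed on the training samples.
    Features whose trial-averaged importance does not exceed the
    trial-averaged threshold-quantile of shadow importances (the
    maximum at ``threshold = 1.0``) are dropped; iteration stops when
    nothing fails.  Fully reproducible under ``seed``.
    """
    if trials < 1:
        raise ValueError("trials must be >= 1")
    if train.isna().to_numpy().any():
        raise ValueError("boruta requires a complete matrix")
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    surviving = list(train.columns)
    dropped_per_iteration: list[list[str]] = []
    shadow_max_per_trial: list[float] = []

    for _ in range(max_iterations):
        if not surviving:
            break
        real = train[surviving]
        imp_sum = pd.Series(0.0, index=surviving)
        cut_sum = 0.0
        for _t in range(trials):
            shadows = pd.DataFrame(
                {f"shadow__{c}": rng.permutation(real[c].to_numpy()) for c in surviving},
                index=real.index,
            )
            augmented = pd.concat([real, shadows], axis=1)
            fit_seed = int(rng.integers(2**31))
            model = _fit_with_internal_holdout(
                augmented, age, hyperparams, seed=fit_seed
            )
            imp = shap_importance(model, augmented)
            shadow_imp = imp[[c for c in imp.index if c.startswith("shadow__")]]
            cut = float(shadow_imp.quantile(threshold))
            shadow_max_per_trial.append(float(shadow_imp.max()))
            cut_sum += cut
            imp_sum += imp[surviving]
        mean_imp = imp_sum / trials
        mean_cut = cut_sum / trials
        failing = [c for c in surviving if mean_imp[c] <= mean_cut]
        if not failing:
            break
        dropped_per_iteration.append(failing)
        surviving = [c for c in surviving if c not in set(failing)]
    if not surviving:
        log.warning("boruta dropped every feature; returning empty selection")
    return BorutaResult(
        selected=surviving,
        dropped_per_iteration=dropped_per_iteration,
        shadow_max_per_trial=shadow_max_per_trial,
        trials=trials,
        threshold=threshold,
    )


@dataclass
class RFECurve:
    """Elimination order and cross-validated performance per panel size."""

    steps: pd.DataFrame = field(default_factory=pd.DataFrame)
    # columns: panel_size, removed (protein removed AFTER scoring this
    # size; empty at the terminal size), mean_cv_pearson_r, mean_cv_r2
    panels: dict[int, list[str]] = field(default_factory=dict)

    def frame(self) -> pd.DataFrame:
        return self.steps.copy()


def _cv_importance_and_performance(
    x: pd.DataFrame, y: pd.Series, hyperparams: Hyperparams, k: int, seed: int
) -> tuple[pd.DataFrame, float, float]:
    """Per-fold importances (folds x proteins) and mean CV r / R^2."""
    from protclock.clock import evaluate_predictions

    kf = KFold(n_splits=k, shuffle=True, random_state=seed)
    imps, rs, r2s = [], [], []
    for tr, va in kf.split(x.to_numpy()):
        model = fit_clock(x.iloc[tr], y.iloc[tr], hyperparams, x.iloc[va], y.iloc[va])
        imps.append(shap_importance(model, x.iloc[tr]))
        m = evaluate_predictions(model.predict(x.iloc[va]), y.iloc[va])
        rs.append(m.pearson_r)
        r2s.append(m.r_squared)
    return pd.DataFrame(imps), float(np.mean(rs)), float(np.mean(r2s))


def _protein_to_remove(fold_imp: pd.DataFrame) -> str:
    """The study's tie-break: per-fold minima vote; lexicographic last."""
    per_fold_min = fold_imp.idxmin(axis=1)
    if per_fold_min.nunique() == 1:
        return per_fold_min.iloc[0]
    votes = per_fold_min.value_counts()
    top = votes[votes == votes.max()].index
    return sorted(top)[0]


def shap_rfe(
    train: pd.DataFrame,
    age: pd.Series,
    selected: list[str],
    hyperparams: Hyperparams,
    k: int = 5,
    seed: int = 0,
    min_panel: int = 5,
) -> RFECurve:
    """Recursive elimination from the selected panel down to five proteins."""
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(selected) < min_panel + 1:
        raise ValueError(f"need more than {min_panel} selected proteins")
    panel = list(selected)
    rows = []
    panels: dict[int, list[str]] = {}
    while True:
        fold_imp, mean_r, mean_r2 = _cv_importance_and_performance(
            train[panel], age, hyperparams, k=k, seed=seed
        )
        panels[len(panel)] = list(panel)
        if len(panel) == min_panel:
            rows.append((len(panel), "", mean_r, mean_r2))
            break
        victim = _protein_to_remove(fold_imp)
        rows.append((len(panel), victim, mean_r, mean_r2))
        panel.remove(victim)
    steps = pd.DataFrame(
        rows, columns=["panel_size", "removed", "mean_cv_pearson_r", "mean_cv_r2"]
    )
    return RFECurve(steps=steps, panels=panels)


def select_reduced_panel(
    curve: RFECurve, retain: float = 0.95, metric: str = "mean_cv_pearson_r"
) -> list[str]:
    """Smallest panel keeping ``retain`` of the full panel's metric."""
    if not 0.0 < retain <= 1.0:
        raise ValueError("retain must lie in (0, 1]")
    if curve.steps.empty:
        raise ValueError("empty elimination curve")
    steps = curve.steps.sort_values("panel_size")
    full = steps[metric].iloc[-1]
    target = retain * full
    passing = steps[steps[metric] >= target]
    if passing.empty:
        size = int(steps["panel_size"].iloc[-1])
    else:
        size = int(passing["panel_size"].min())
    return curve.panels[size]
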