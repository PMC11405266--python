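"""Protein filtering, imputation and normalization.

Brings NPX-like matrices from one or more cohorts onto a common scale
before clock training: proteins missing in more than 10% of the
reference cohort, or not shared by every cohort, are dropped; remaining
missing values are imputed (chained regression, at most five rounds, or
per-protein median); values are then min-max rescaled to [0, 1] per
protein and centred on the median.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.linear_model import Ridge

log = logging.getLogger(__name__)

__all__ = [
    "NormalizationParams",
    "filter_proteins",
    "impute_proteins",
    "normalize_npx",
]


@dataclass
class NormalizationParams:
    """Per-protein min/max and post-rescale median, plus fit provenance."""

    minimum: pd.Series
    maximum: pd.Series
    median: pd.Series  # median of the rescaled values, in [0, 1]
    fit_subset: str = "all"

    def __post_init__(self) -> None:
        if (self.maximum < self.minimum).any():
            raise ValueError("normalization maximum below minimum for some protein")

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"min": self.minimum, "max": self.maximum, "median": self.median}
        ).rename_axis("protein")

    def to_csv(self, path: str | Path) -> None:
        self.frame().to_csv(path)

    @classmethod
    def from_csv(cls, path: str | Path, fit_subset: str = "stored") -> "NormalizationParams":
        df = pd.read_csv(path, index_col="protein")
        return cls(df["min"], df["max"], df["median"], fit_subset=fit_subset)


def filter_proteins(
    matrices: list[pd.DataFrame] | pd.DataFrame,
    max_missing: float = 0.10,
    reference: int = 0,
) -> tuple[list[pd.DataFrame], pd.DataFrame]:
    """Drop proteins not shared across cohorts or too often missing.

    A protein is retained iff it is present in every matrix and its
    missing fraction in the reference matrix is *not over* ``max_missing``
    (strict ``>`` excludes, so exactly 10% missing is retained).

    Returns the filtered matrices (same order) and an exclusion report
    with one row per dropped protein: columns ``protein, reason,
    missing_fraction``.
    """
    if isinstance(matrices, pd.DataFrame):
        matrices = [matrices]
    if not matrices:
        raise ValueError("at least one protein matrix required")
    ref = matrices[reference]

    shared = set(matrices[0].columns)
    for m in matrices[1:]:
        shared &= set(m.columns)

    records = []
    all_proteins = sorted(set().union(*(m.columns for m in matrices)))
    miss_frac = ref.isna().mean()
    keep = []
    for prot in all_proteins:
        if prot not in shared:
            records.append((prot, "not shared", np.nan))
        elif miss_frac[prot] > max_missing:
            records.append((prot, "missing over threshold", float(miss_frac[prot])))
        else:
            keep.append(prot)
    if not keep:
        raise ValueError(
            "no proteins survive filtering: shared set is empty or all exceed "
            f"the {max_missing:.0%} missingness threshold"
        )
    # preserve the reference matrix's column order for the retained set
    keep = [p for p in ref.columns if p in set(keep)]
    report = pd.DataFrame(records, columns=["protein", "reason", "missing_fraction"])
    return [m[keep] for m in matrices], report


def impute_proteins(
    matrix: pd.DataFrame,
    max_iterations: int = 5,
    method: str = "chained_model",
    predictor_max_missing: float = 0.30,
    seed: int = 0,
) -> pd.DataFrame:
    """Fill missing protein values; observed cells are never altered.

    ``median`` fills each protein with its observed median.
    ``chained_model`` initialises with medians, then cycles over
    incomplete proteins fitting a ridge regression of each on the other
    eligible proteins (those missing in at most ``predictor_max_missing``
    of samples) and overwrites only the missing cells, for up to
    ``max_iterations`` rounds or until the imputed values stabilise.
    """
    if matrix.isna().all(axis=0).any():
        bad = matrix.columns[matrix.isna().all(axis=0)].tolist()
        raise ValueError(f"proteins with zero observed values: {bad}")
    observed = ~matrix.isna()
    medians = matrix.median(axis=0)
    filled = matrix.fillna(medians)
    if method == "median" or not (~observed).to_numpy().any():
        return filled
    if method != "chained_model":
        raise ValueError(f"unknown imputation method: {method!r}")

    miss_frac = (~observed).mean()
    predictors = [c for c in matrix.columns if miss_frac[c] <= predictor_max_missing]
    targets = [c for c in matrix.columns if (~observed[c]).any()]
    x = filled.to_numpy(dtype=float, copy=True)
    col_of = {c: i for i, c in enumerate(matrix.columns)}
    pred_idx_all = np.array([col_of[c] for c in predictors], dtype=int)

    for _ in range(max_iterations):
        prev = x.copy()
        for target in targets:
            j = col_of[target]
            mask = observed[target].to_numpy()
            pred_idx = pred_idx_all[pred_idx_all != j]
            model = Ridge(alpha=1.0, random_state=seed)
            model.fit(x[mask][:, pred_idx], x[mask, j])
            x[~mask, j] = model.predict(x[~mask][:, pred_idx])
        if np.max(np.abs(x - prev)) < 1e-6:
            break
    out = pd.DataFrame(x, index=matrix.index, columns=matrix.columns)
    out[observed] = matrix[observed]  # exact equality on observed cells
    return out


def normalize_npx(
    matrix: pd.DataFrame,
    params: NormalizationParams | None = None,
    fit_subset: pd.Index | list | None = None,
    fit_subset_label: str | None = None,
) -> tuple[pd.DataFrame, NormalizationParams]:
    """Min-max rescale each protein to [0, 1], then centre on its median.

    When ``params`` is given they are applied unchanged (cross-cohort
    mode).  Otherwise parameters are fitted on ``fit_subset`` rows (all
    rows by default) and applied to the full matrix: values map through
    ``(x - min) / (max - min)`` and are then shifted by the median of
    the rescaled fit values, so the fit rows have per-protein median 0
    and range within [-1, 1].  A constant protein maps to 0, with a
    logged warning.
    """
    if matrix.isna().to_numpy().any():
        raise ValueError("normalize_npx requires a complete (imputed) matrix")
    if params is None:
        fit = matrix if fit_subset is None else matrix.loc[fit_subset]
        mn, mx = fit.min(axis=0), fit.max(axis=0)
        span = mx - mn
        constant = span == 0
        if constant.any():
            log.warning(
                "constant proteins set to 0 during normalization: %s",
                matrix.columns[constant].tolist(),
            )
        safe_span = span.where(~constant, 1.0)
        med = ((fit - mn) / safe_span).median(axis=0).where(~constant, 0.0)
        params = NormalizationParams(
            mn, mx, med,
            fit_subset=fit_subset_label or ("all" if fit_subset is None else "subset"),
        )
    else:
        missing = matrix.columns.difference(params.minimum.index)
        if len(missing):
            raise ValueError(f"no stored normalization for proteins: {list(missing)}")
    span = (params.maximum - params.minimum).reindex(matrix.columns)
    constant = span == 0
    safe_span = span.where(~constant, 1.0)
    scaled = (matrix - params.minimum.reindex(matrix.columns)) / safe_span
    out = scaled - params.median.reindex(matrix.columns)
    if constant.any():
        out.loc[:, constant[constant].index] = 0.0
    return out, params
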