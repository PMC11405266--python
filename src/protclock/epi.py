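"""Age-gap epidemiology: association scans, Cox hazards, Kaplan-Meier
incidence by gap decile, fold risks and multimorbidity trends.

The exposure throughout is the proteomic age gap in years.  Association
scans regress each aging phenotype on the gap with covariate
adjustment and Benjamini-Hochberg FDR over the scan family.  Survival
analyses exclude prevalent cases, fit tiered Cox proportional hazards
models (tier 1: age + sex; tier 2: + deprivation, assessment-centre
analogue, activity, smoking; tier 3: + BMI, hypertension) and report
hazard ratios per gap-year.  Cumulative incidence for gap deciles is
one minus the Kaplan-Meier survival function, plotted against age at
recruitment by convention.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from lifelines import CoxPHFitter, KaplanMeierFitter
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)

__all__ = [
    "bh_fdr",
    "association_scan",
    "cox_hazard",
    "km_incidence_by_decile",
    "fold_risk",
    "multimorbidity_trend",
    "TIER_COVARIATES",
]

#: covariates added at each Cox adjustment tier
TIER_COVARIATES = {
    1: ["age", "sex"],
    2: ["age", "sex", "deprivation", "center", "activity", "smoking"],
    3: ["age", "sex", "deprivation", "center", "activity", "smoking", "bmi",
        "hypertension"],
}
CATEGORICAL_COVARIATES = ("center", "activity", "smoking")


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _design(covariates: pd.DataFrame, columns: list[str]) -> pd.DataFrame:
    """Covariate design matrix with categorical columns dummy-coded."""
    cols = []
    for c in columns:
        if c in CATEGORICAL_COVARIATES:
            d = pd.get_dummies(covariates[c].astype("category"), prefix=c,
                               drop_first=True, dtype=float)
            cols.append(d)
        else:
            cols.append(covariates[[c]].astype(float))
    return pd.concat(cols, axis=1)


def association_scan(
    gap: pd.Series,
    phenotypes: pd.DataFrame,
    covariates: pd.DataFrame,
    phenotype_cols: list[str] | None = None,
    adjust_for: list[str] | None = None,
    subset: pd.Series | None = None,
    subset_label: str = "all",
) -> pd.DataFrame:
    """Regress each phenotype on the age gap with covariate adjustment.

    Continuous phenotypes use linear regression, binary ones logistic;
    ``beta`` is the gap coefficient.  BH-FDR is applied across the scan
    (one family).  ``subset`` restricts the analysis sample, supporting
    disease-free / never-smoker / normal-BMI style sensitivity scans.
    """
    adjust_for = adjust_for if adjust_for is not None else TIER_COVARIATES[2]
    if phenotype_cols is None:
        phenotype_cols = [c for c in phenotypes.columns if c not in covariates.columns]
    idx = gap.index
    if subset is not None:
        idx = idx[subset.reindex(idx).fillna(False).astype(bool)]
    design = _design(covariates.loc[idx], adjust_for)
    x = pd.concat([gap.loc[idx].rename("gap"), design], axis=1)
    x = sm.add_constant(x, has_constant="add")

    rows = []
    for name in phenotype_cols:
        y = phenotypes.loc[idx, name].astype(float)
        uniq = y.dropna().unique()
        binary = set(np.unique(uniq)).issubset({0.0, 1.0})
        if gap.loc[idx].nunique() <= 1:
            rows.append((name, "linear" if not binary else "logistic",
                         np.nan, np.nan, np.nan, len(idx),
                         "zero-variance exposure"))
            continue
        if binary and len(uniq) < 2:
            log.warning("phenotype %s has a single class; skipped", name)
            continue
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                if binary:
                    fit = sm.Logit(y, x.astype(float)).fit(disp=0, maxiter=200)
                    family = "logistic"
                else:
                    fit = sm.OLS(y, x.astype(float)).fit()
                    family = "linear"
            rows.append((name, family, float(fit.params["gap"]),
                         float(fit.bse["gap"]), float(fit.pvalues["gap"]),
                         int(fit.nobs), None))
        except Exception as exc:  # singular designs on degenerate input
            rows.append((name, "logistic" if binary else "linear",
                         np.nan, np.nan, np.nan, len(idx), str(exc)))
    out = pd.DataFrame(
        rows, columns=["phenotype", "family", "beta", "se", "p", "n", "flag"]
    )
    out["q"] = np.nan
    ok = out["p"].notna()
    if ok.any():
        out.loc[ok, "q"] = bh_fdr(out.loc[ok, "p"].to_numpy())
    out["subset"] = subset_label
    return out


def cox_hazard(
    gap: pd.Series,
    outcomes: pd.DataFrame,
    covariates: pd.DataFrame,
    tier: int = 1,
) -> pd.DataFrame:
    """Tiered Cox models of each endpoint on the age gap.

    Prevalent cases are excluded per endpoint before fitting.  Hazard
    ratios are per one-year increase in the gap, with 95% CI, Wald p
    and BH-FDR across the endpoints of the tier.  Endpoints with fewer
    than 10 events are fitted anyway and flagged low-power.
    """
    if tier not in TIER_COVARIATES:
        raise ValueError(f"tier must be one of {sorted(TIER_COVARIATES)}")
    rows = []
    for endpoint, grp in outcomes.groupby("endpoint", sort=True):
        grp = grp[grp["prevalent"].astype(bool) == False]  # noqa: E712
        ids = grp["sample_id"]
        df = pd.DataFrame(
            {
                "time": grp["time"].to_numpy(),
                "event": grp["event"].astype(int).to_numpy(),
                "gap": gap.reindex(ids).to_numpy(),
            }
        )
        design = _design(covariates.loc[ids], TIER_COVARIATES[tier])
        df = pd.concat([df, design.reset_index(drop=True)], axis=1)
        n_events = int(df["event"].sum())
        flag = "low-power (<10 events)" if n_events < 10 else None
        try:
            cph = CoxPHFitter()
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cph.fit(df, duration_col="time", event_col="event")
            hr = float(np.exp(cph.params_["gap"]))
            lo, hi = np.exp(
                cph.confidence_intervals_.loc["gap"].to_numpy(dtype=float)
            )
            p = float(cph.summary.loc["gap", "p"])
        except Exception as exc:
            hr, lo, hi, p = np.nan, np.nan, np.nan, np.nan
            flag = str(exc)
        rows.append(
            {"endpoint": endpoint, "tier": tier, "hr": hr, "ci_low": lo,
             "ci_high": hi, "p": p, "events": n_events, "n": len(df),
             "flag": flag}
        )
    out = pd.DataFrame(rows)
    out["q"] = np.nan
    ok = out["p"].notna()
    if ok.any():
        out.loc[ok, "q"] = bh_fdr(out.loc[ok, "p"].to_numpy())
    return out


def _decile_groups(gap: pd.Series, which: tuple = ("bottom", "median", "top")) -> dict[str, pd.Index]:
    """Sample ids of the requested gap deciles.

    ``median`` is the 5th decile (40th-50th percentile band); integers
    select explicit deciles 1-10.
    """
    ranks = gap.rank(method="first", pct=True)
    def band(d: int) -> pd.Index:
        return gap.index[(ranks > (d - 1) / 10) & (ranks <= d / 10)]
    groups = {}
    for w in which:
        if w == "all":
            groups["all"] = gap.index
        elif w == "bottom":
            groups["bottom"] = band(1)
        elif w == "top":
            groups["top"] = band(10)
        elif w == "median":
            groups["median"] = band(5)
        elif isinstance(w, int) and 1 <= w <= 10:
            groups[f"decile_{w}"] = band(w)
        else:
            raise ValueError(f"unknown decile selector: {w!r}")
    return groups


def km_incidence_by_decile(
    gap: pd.Series,
    outcomes: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    deciles: tuple = ("bottom", "median", "top"),
    axis: str = "age",
) -> pd.DataFrame:
    """Kaplan-Meier cumulative incidence for gap deciles, per endpoint.

    Prevalent cases are excluded, deciles are computed on the remaining
    analysis sample per endpoint, and cumulative incidence is
    ``1 - S(t)`` with 95% CI.  With ``axis="age"`` the curve is indexed
    by age at recruitment (the study's plotting convention, requiring
    ``covariates['age']``); ``axis="time"`` uses follow-up time.

    Returns a long-format table: ``endpoint, group, grid, incidence,
    ci_low, ci_high, events``.
    """
    if axis not in ("age", "time"):
        raise ValueError("axis must be 'age' or 'time'")
    if axis == "age" and (covariates is None or "age" not in covariates):
        raise ValueError("axis='age' requires covariates with an 'age' column")
    frames = []
    for endpoint, grp in outcomes.groupby("endpoint", sort=True):
        grp = grp[grp["prevalent"].astype(bool) == False]  # noqa: E712
        grp = grp.set_index("sample_id")
        g = gap.reindex(grp.index).dropna()
        groups = _decile_groups(g, deciles)
        for label, ids in groups.items():
            sub = grp.loc[ids]
            durations = (
                covariates.loc[ids, "age"] if axis == "age" else sub["time"]
            ).to_numpy(dtype=float)
            events = sub["event"].astype(int).to_numpy()
            n_events = int(events.sum())
            if n_events == 0:
                log.warning("endpoint %s group %s has zero events", endpoint, label)
            kmf = KaplanMeierFitter()
            kmf.fit(durations, event_observed=events)
            surv = kmf.survival_function_.iloc[:, 0]
            ci = kmf.confidence_interval_
            frames.append(
                pd.DataFrame(
                    {
                        "endpoint": endpoint,
                        "group": label,
                        "grid": surv.index.to_numpy(dtype=float),
                        "incidence": 1.0 - surv.to_numpy(),
                        "ci_low": 1.0 - ci.iloc[:, 1].to_numpy(),
                        "ci_high": 1.0 - ci.iloc[:, 0].to_numpy(),
                        "events": n_events,
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)


def fold_risk(hr_per_year: float, delta_years: float) -> float:
    """Fold change in risk for a gap of ``delta_years``: ``hr ** delta``."""
    if not hr_per_year > 0:
        raise ValueError(f"hazard ratio must be > 0, got {hr_per_year}")
    return float(hr_per_year**delta_years)


def multimorbidity_trend(
    gap: pd.Series,
    diagnosis_counts: pd.Series,
    age: pd.Series | None = None,
    age_strata: list[tuple[float, float]] | None = None,
) -> pd.DataFrame:
    """Mean gap by lifetime-diagnosis-count category (0, 1, 2, 3, 4+).

    Counts of four or more pool into "4+".  With ``age_strata`` (list
    of ``[lo, hi)`` bounds) the trend is reported per age stratum; the
    95% CI is the t-interval of the category mean.  Empty strata are
    omitted with a warning.
    """
    counts = diagnosis_counts.reindex(gap.index).fillna(0).astype(int)
    if (counts < 0).any():
        raise ValueError("diagnosis counts must be >= 0")
    category = counts.clip(upper=4).map(
        {0: "0", 1: "1", 2: "2", 3: "3", 4: "4+"}
    )
    if age_strata is None or age is None:
        strata = {"all": pd.Series(True, index=gap.index)}
    else:
        strata = {
            f"{lo:g}-{hi:g}": (age >= lo) & (age < hi) for lo, hi in age_strata
        }
    rows = []
    from scipy import stats as sps

    for stratum, mask in strata.items():
        if not mask.any():
            log.warning("empty age stratum %s omitted", stratum)
            continue
        for cat in ["0", "1", "2", "3", "4+"]:
            sel = mask & (category == cat)
            n = int(sel.sum())
            if n == 0:
                continue
            vals = gap[sel]
            mean = float(vals.mean())
            if n > 1 and vals.std(ddof=1) > 0:
                half = sps.t.ppf(0.975, n - 1) * vals.std(ddof=1) / np.sqrt(n)
            else:
                half = 0.0
            rows.append(
                {"age_stratum": stratum, "category": cat, "mean_gap": mean,
                 "ci_low": mean - half, "ci_high": mean + half, "n": n}
            )
    return pd.DataFrame(rows)
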