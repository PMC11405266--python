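"""End-to-end orchestration: simulate, preprocess, train, select,
epidemiology and network stages from one declarative config.

A single user-facing seed is fanned out to per-stage seeds by a stable
hash (CRC32 of the stage name mixed with the run seed), so each stage
is individually reproducible and the whole run is deterministic in
single-threaded mode.  Every stage writes delimited tables under the
run directory; a RunBundle records paths, a metrics summary and
provenance (config hash, seed, library versions), and the report can
be regenerated byte-identically from the bundle alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from protclock import clock as clockmod
from protclock import epi as epimod
from protclock import featselect as fsmod
from protclock import network as netmod
from protclock import preprocess as premod
from protclock import synthdata

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "RunBundle", "run_pipeline", "write_report", "stage_seed"]

STAGE_ORDER = ["simulate", "preprocess", "clock", "select", "epi", "network"]
STAGE_DEPS = {
    "preprocess": ["simulate"],
    "clock": ["preprocess"],
    "select": ["clock"],
    "epi": ["clock"],
    "network": ["select"],
}


def stage_seed(base_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    return (base_seed * 1000003 + zlib.crc32(stage.encode())) % (2**31)


@dataclass
class RunConfig:
    """Declarative configuration of a full run."""

    out_dir: str = "run"
    seed: int = 0
    stages: list[str] = field(default_factory=lambda: list(STAGE_ORDER))
    synth: dict = field(default_factory=dict)
    paper_mode: bool = False  # fit normalization on the full cohort
    train_fraction: float = 0.70
    folds: int = 5
    tune_trials: int = 0  # 0 skips tuning and uses default hyperparams
    boruta_trials: int = 20
    boruta_threshold: float = 1.0
    run_rfe: bool = True
    retain: float = 0.95
    tiers: list[int] = field(default_factory=lambda: [1, 2, 3])
    deciles: list = field(default_factory=lambda: ["bottom", "median", "top"])
    network_threshold: float | None = None  # None: auto-match size
    network_target_nodes: int | None = None
    interaction_samples: int = 200

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown run config fields: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class RunBundle:
    """Outputs and provenance of one run."""

    out_dir: Path
    paths: dict[str, str]
    metrics: dict
    provenance: dict

    def save(self) -> Path:
        payload = {
            "paths": self.paths,
            "metrics": self.metrics,
            "provenance": self.provenance,
        }
        path = Path(self.out_dir) / "bundle.json"
        path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
        return path

    @classmethod
    def load(cls, out_dir: str | Path) -> "RunBundle":
        out_dir = Path(out_dir)
        payload = json.loads((out_dir / "bundle.json").read_text())
        return cls(out_dir=out_dir, **payload)


def _versions() -> dict[str, str]:
    import lifelines
    import lightgbm
    import sklearn

    import protclock

    return {
        "protclock": protclock.__version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "lightgbm": lightgbm.__version__,
        "scikit-learn": sklearn.__version__,
        "lifelines": lifelines.__version__,
    }


def run_pipeline(config: RunConfig) -> RunBundle:
    """Execute the enabled stages in dependency order."""
    enabled = [s for s in STAGE_ORDER if s in config.stages]
    for s in enabled:
        for dep in STAGE_DEPS.get(s, []):
            if dep not in enabled:
                raise ValueError(f"stage {s!r} requires stage {dep!r}")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}
    metrics: dict = {}
    state: dict = {}

    for stage in enabled:
        try:
            _STAGE_FUNCS[stage](config, state, paths, metrics, out)
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    bundle = RunBundle(
        out_dir=out,
        paths=paths,
        metrics=metrics,
        provenance={
            "config": config.to_dict(),
            "config_hash": config.hash(),
            "seed": config.seed,
            "stage_seeds": {s: stage_seed(config.seed, s) for s in enabled},
            "versions": _versions(),
        },
    )
    bundle.save()
    return bundle


def _stage_simulate(config, state, paths, metrics, out):
    seed = stage_seed(config.seed, "simulate")
    synth_cfg = synthdata.config_from_dict({**config.synth, "seed": seed})
    proteins, phen, truth = synthdata.generate_cohort(synth_cfg)
    outcomes = synthdata.simulate_all_outcomes(
        truth, phen, synth_cfg.outcome_specs, seed=seed
    )
    written = synthdata.write_cohort(out / "cohort", proteins, phen, truth, outcomes)
    paths.update({f"simulate.{k}": str(v) for k, v in written.items()})
    metrics["simulate"] = {
        "n_samples": int(proteins.shape[0]),
        "n_proteins": int(proteins.shape[1]),
        "missing_fraction": float(proteins.isna().to_numpy().mean()),
    }
    state.update(proteins=proteins, phenotypes=phen, truth=truth,
                 outcomes=outcomes, synth_cfg=synth_cfg)


def _stage_preprocess(config, state, paths, metrics, out):
    seed = stage_seed(config.seed, "preprocess")
    filtered, report = premod.filter_proteins([state["proteins"]])
    imputed = premod.impute_proteins(filtered[0], seed=seed)
    if config.paper_mode:
        normalized, params = premod.normalize_npx(imputed)
    else:
        train_ids, _ = clockmod.split_cohort(
            imputed.index, config.train_fraction, seed=stage_seed(config.seed, "clock")
        )
        normalized, params = premod.normalize_npx(
            imputed, fit_subset=train_ids, fit_subset_label="train"
        )
    pdir = out / "preprocess"
    pdir.mkdir(exist_ok=True)
    report.to_csv(pdir / "exclusions.csv", index=False)
    params.to_csv(pdir / "normalization.csv")
    normalized.to_csv(pdir / "normalized.csv")
    paths.update({
        "preprocess.exclusions": str(pdir / "exclusions.csv"),
        "preprocess.normalization": str(pdir / "normalization.csv"),
        "preprocess.normalized": str(pdir / "normalized.csv"),
    })
    metrics["preprocess"] = {
        "proteins_retained": int(normalized.shape[1]),
        "proteins_excluded": int(len(report)),
    }
    state["normalized"] = normalized


def _stage_clock(config, state, paths, metrics, out):
    seed = stage_seed(config.seed, "clock")
    age = state["phenotypes"]["age"]
    model = clockmod.ProteomicAgeClock(
        state["normalized"], age, seed=seed
    )
    if config.tune_trials > 0:
        model.tune(trials=config.tune_trials, k=config.folds)
    holdout = model.fit(train_fraction=config.train_fraction)
    oof = model.fit_oof(k=config.folds)
    cdir = out / "clock"
    cdir.mkdir(exist_ok=True)
    oof.gap_table.to_csv(cdir / "gap_table.csv")
    oof.gap_summary().to_csv(cdir / "gap_summary.csv")
    oof.model.save(cdir / "model.txt")
    mtab = pd.DataFrame(
        [
            {"set": "holdout", **holdout.metrics["holdout"].as_dict()},
            {"set": "oof", **oof.metrics["oof"].as_dict()},
        ]
    )
    mtab.to_csv(cdir / "metrics.csv", index=False)
    paths.update({
        "clock.gap_table": str(cdir / "gap_table.csv"),
        "clock.gap_summary": str(cdir / "gap_summary.csv"),
        "clock.metrics": str(cdir / "metrics.csv"),
        "clock.model": str(cdir / "model.txt"),
    })
    metrics["clock"] = {
        "holdout_pearson_r": holdout.metrics["holdout"].pearson_r,
        "holdout_r2": holdout.metrics["holdout"].r_squared,
        "oof_pearson_r": oof.metrics["oof"].pearson_r,
        "hyperparams": dataclasses.asdict(model.hyperparams),
    }
    state.update(clock_model=model, clock_results=oof, holdout_results=holdout)


def _stage_select(config, state, paths, metrics, out):
    seed = stage_seed(config.seed, "select")
    model: clockmod.ProteomicAgeClock = state["clock_model"]
    train_ids, _ = clockmod.split_cohort(
        model.proteins.index, config.train_fraction, seed=model.seed
    )
    x = model.proteins.loc[train_ids]
    y = model.age.loc[train_ids]
    boruta = fsmod.boruta_select(
        x, y, model.hyperparams,
        trials=config.boruta_trials, threshold=config.boruta_threshold, seed=seed,
    )
    sdir = out / "select"
    sdir.mkdir(exist_ok=True)
    boruta.frame().to_csv(sdir / "boruta.csv", index=False)
    (sdir / "selected_panel.txt").write_text("\n".join(boruta.selected) + "\n")
    paths.update({
        "select.boruta": str(sdir / "boruta.csv"),
        "select.panel": str(sdir / "selected_panel.txt"),
    })
    metrics["select"] = {"boruta_selected": len(boruta.selected)}
    state["boruta"] = boruta
    panel = boruta.selected
    if config.run_rfe and len(panel) > 6:
        curve = fsmod.shap_rfe(
            x, y, panel, model.hyperparams, k=config.folds, seed=seed
        )
        reduced = fsmod.select_reduced_panel(curve, retain=config.retain)
        curve.frame().to_csv(sdir / "rfe_curve.csv", index=False)
        (sdir / "reduced_panel.txt").write_text("\n".join(reduced) + "\n")
        paths.update({
            "select.rfe_curve": str(sdir / "rfe_curve.csv"),
            "select.reduced_panel": str(sdir / "reduced_panel.txt"),
        })
        metrics["select"]["reduced_panel"] = len(reduced)
        state["reduced_panel"] = reduced
    state["panel"] = panel


def _stage_epi(config, state, paths, metrics, out):
    gap = state["clock_results"].gap_table["gap"]
    phen = state["phenotypes"]
    synth_cfg = state["synth_cfg"]
    phenotype_cols = [s.name for s in synth_cfg.phenotype_specs]
    edir = out / "epi"
    edir.mkdir(exist_ok=True)
    assoc = epimod.association_scan(gap, phen, phen, phenotype_cols=phenotype_cols)
    assoc.to_csv(edir / "associations.csv", index=False)
    cox = pd.concat(
        [epimod.cox_hazard(gap, state["outcomes"], phen, tier=t) for t in config.tiers],
        ignore_index=True,
    )
    cox.to_csv(edir / "cox.csv", index=False)
    km = epimod.km_incidence_by_decile(
        gap, state["outcomes"], phen, deciles=tuple(config.deciles)
    )
    km.to_csv(edir / "km.csv", index=False)
    counts = synthdata.diagnosis_counts(state["outcomes"])
    trend = epimod.multimorbidity_trend(gap, counts, age=phen["age"])
    trend.to_csv(edir / "multimorbidity.csv", index=False)
    paths.update({
        "epi.associations": str(edir / "associations.csv"),
        "epi.cox": str(edir / "cox.csv"),
        "epi.km": str(edir / "km.csv"),
        "epi.multimorbidity": str(edir / "multimorbidity.csv"),
    })
    sig = cox[cox["q"] < 0.05] if cox["q"].notna().any() else cox.iloc[0:0]
    metrics["epi"] = {
        "phenotypes_tested": int(len(assoc)),
        "cox_models": int(len(cox)),
        "cox_significant": int(len(sig)),
    }


def _stage_network(config, state, paths, metrics, out):
    seed = stage_seed(config.seed, "network")
    model: clockmod.ProteomicAgeClock = state["clock_model"]
    panel = state.get("reduced_panel") or state["panel"]
    if len(panel) < 2:
        raise ValueError("network stage needs a panel of at least 2 proteins")
    train_ids, test_ids = clockmod.split_cohort(
        model.proteins.index, config.train_fraction, seed=model.seed
    )
    fitted = clockmod.fit_clock(
        model.proteins.loc[train_ids, panel], model.age.loc[train_ids],
        model.hyperparams, model.proteins.loc[test_ids, panel],
        model.age.loc[test_ids],
    )
    rng = np.random.default_rng(seed)
    n_eval = min(config.interaction_samples, len(train_ids))
    sample_ids = list(np.array(train_ids)[rng.choice(len(train_ids), n_eval, replace=False)])
    inter = netmod.shap_interaction_matrix(fitted, model.proteins.loc[sample_ids, panel])
    if config.network_threshold is not None:
        net = netmod.build_interaction_network(inter, threshold=config.network_threshold)
    else:
        target = config.network_target_nodes or max(2, len(panel) // 2)
        net = netmod.build_interaction_network(inter, target_n_nodes=target)
    ndir = out / "network"
    ndir.mkdir(exist_ok=True)
    inter.to_csv(ndir / "interaction_matrix.csv")
    net.edge_table().to_csv(ndir / "edges.csv", index=False)
    net.degree_table().to_csv(ndir / "degrees.csv")
    paths.update({
        "network.interactions": str(ndir / "interaction_matrix.csv"),
        "network.edges": str(ndir / "edges.csv"),
        "network.degrees": str(ndir / "degrees.csv"),
    })
    metrics["network"] = {
        "nodes": int(net.graph.number_of_nodes()),
        "edges": int(net.graph.number_of_edges()),
        "threshold": float(net.threshold),
    }


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "preprocess": _stage_preprocess,
    "clock": _stage_clock,
    "select": _stage_select,
    "epi": _stage_epi,
    "network": _stage_network,
}


def write_report(bundle: RunBundle) -> Path:
    """Render a human-readable run summary from the bundle alone.

    The report is a deterministic function of the bundle contents, so
    regenerating it from a stored bundle is byte-identical.
    """
    lines = [
        "# Proteomic age clock run report",
        "",
        f"- config hash: `{bundle.provenance['config_hash']}`",
        f"- seed: {bundle.provenance['seed']}",
        "",
    ]
    metrics = bundle.metrics
    missing = [s for s in STAGE_ORDER if s not in metrics]
    if missing:
        lines += [f"> stages not run: {', '.join(missing)}", ""]
    for stage in STAGE_ORDER:
        if stage not in metrics:
            continue
        lines.append(f"## {stage}")
        lines.append("")
        for key, val in sorted(metrics[stage].items()):
            if isinstance(val, float):
                lines.append(f"- {key}: {val:.6g}")
            elif isinstance(val, dict):
                lines.append(f"- {key}: " + json.dumps(val, sort_keys=True))
            else:
                lines.append(f"- {key}: {val}")
        lines.append("")
    for key in ("epi.cox", "network.degrees", "clock.gap_summary"):
        path = bundle.paths.get(key)
        if path and Path(path).exists():
            lines.append(f"## table: {key}")
            lines.append("")
            lines.append("```")
            lines.append(Path(path).read_text().strip())
            lines.append("```")
            lines.append("")
    out = Path(bundle.out_dir) / "report.md"
    out.write_text("\n".join(lines))
    return out
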