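"""SHAP-interaction protein networks and reference-edge comparison.

The trained clock's pairwise Shapley interaction values, aggregated as
the mean absolute value over a sample set, define a data-driven
protein-protein network: proteins are nodes and pairs whose mean
absolute interaction reaches a threshold are edges.  The module also
filters reference coexpression edge lists (confidence strictly above
0.7, then iterative pruning to nodes with at least two connections)
and computes node/edge overlap statistics between networks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from protclock.clock import ClockModel
from protclock.treeshap import TreeEnsemble, shap_interaction_values

log = logging.getLogger(__name__)

__all__ = [
    "ProteinNetwork",
    "shap_interaction_matrix",
    "build_interaction_network",
    "filter_reference_edges",
    "network_overlap",
    "read_reference_edges",
]


def shap_interaction_matrix(
    model: ClockModel, data: pd.DataFrame
) -> pd.DataFrame:
    """Mean absolute pairwise Shapley interaction values over ``data``.

    Returns a symmetric proteins-by-proteins matrix; the diagonal holds
    the mean absolute main-effect attributions.  A model with no trees
    yields an all-zero matrix with a warning.
    """
    x = model._check(data)
    ensemble = TreeEnsemble(model.booster, num_iteration=model.best_iteration)
    if not ensemble.trees:
        log.warning("model has no trees; interaction matrix is all zero")
        p = len(model.proteins)
        return pd.DataFrame(
            np.zeros((p, p)), index=model.proteins, columns=model.proteins
        )
    tensor = shap_interaction_values(ensemble, x.to_numpy(dtype=float))
    agg = np.abs(tensor).mean(axis=0)
    return pd.DataFrame(agg, index=model.proteins, columns=model.proteins)


@dataclass
class ProteinNetwork:
    """Weighted undirected protein network plus build provenance."""

    graph: nx.Graph
    threshold: float | None = None
    source: str = "interaction"

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    def degree_table(self) -> pd.DataFrame:
        deg = pd.Series(dict(self.graph.degree()), dtype=int, name="degree")
        return deg.sort_values(ascending=False).rename_axis("protein").to_frame()

    def edge_table(self) -> pd.DataFrame:
        rows = [
            {"protein_a": min(a, b), "protein_b": max(a, b),
             "weight": d.get("weight", np.nan)}
            for a, b, d in self.graph.edges(data=True)
        ]
        return pd.DataFrame(rows, columns=["protein_a", "protein_b", "weight"])

    def edge_set(self) -> set[tuple[str, str]]:
        return {tuple(sorted(e)) for e in self.graph.edges}


def build_interaction_network(
    matrix: pd.DataFrame,
    threshold: float | None = None,
    target_n_nodes: int | None = None,
) -> ProteinNetwork:
    """Threshold the interaction matrix into a network.

    Off-diagonal entries at or above ``threshold`` become edges
    (self-loops never form).  Alternatively ``target_n_nodes``
    auto-picks the smallest threshold whose network has at most that
    many connected nodes, matching the network's size to a reference
    subnetwork.
    """
    if (threshold is None) == (target_n_nodes is None):
        raise ValueError("give exactly one of threshold or target_n_nodes")
    vals = matrix.to_numpy()
    if not np.allclose(vals, vals.T, atol=1e-8):
        raise ValueError("interaction matrix must be symmetric")
    proteins = list(matrix.index)
    iu = np.triu_indices(len(proteins), k=1)
    weights = vals[iu]

    def network_at(th: float) -> nx.Graph:
        g = nx.Graph()
        keep = weights >= th
        for a, b, w in zip(iu[0][keep], iu[1][keep], weights[keep]):
            g.add_edge(proteins[a], proteins[b], weight=float(w))
        return g

    if threshold is not None:
        if threshold < 0:
            raise ValueError("threshold must be >= 0")
        return ProteinNetwork(network_at(threshold), threshold=threshold)

    # auto mode: scan candidate thresholds (the distinct edge weights,
    # descending) until the node count would exceed the target
    cand = np.unique(weights)[::-1]
    chosen = float(cand[0]) + 1.0  # empty network fallback
    for th in cand:
        if network_at(float(th)).number_of_nodes() > target_n_nodes:
            break
        chosen = float(th)
    return ProteinNetwork(network_at(chosen), threshold=chosen)


def read_reference_edges(path) -> pd.DataFrame:
    """Read a 3-column delimited edge list (protein_a, protein_b, score)."""
    df = pd.read_csv(path)
    expected = {"protein_a", "protein_b", "score"}
    if not expected.issubset(df.columns):
        raise ValueError(f"reference edge list needs columns {sorted(expected)}")
    return df


def filter_reference_edges(
    edges: pd.DataFrame,
    min_confidence: float = 0.7,
    min_degree: int = 2,
) -> ProteinNetwork:
    """High-confidence reference subnetwork.

    Keeps edges with confidence strictly above ``min_confidence``, then
    iteratively removes nodes of degree below ``min_degree`` until a
    fixed point.  Malformed records (missing ids, scores outside
    [0, 1]) are skipped with a logged line number.
    """
    g = nx.Graph()
    for i, row in edges.reset_index(drop=True).iterrows():
        a, b, s = row.get("protein_a"), row.get("protein_b"), row.get("score")
        try:
            s = float(s)
        except (TypeError, ValueError):
            s = np.nan
        if (not isinstance(a, str) or not isinstance(b, str) or a == b
                or not np.isfinite(s) or not 0.0 <= s <= 1.0):
            log.warning("skipping malformed reference edge at line %d", i + 1)
            continue
        if s > min_confidence:
            # unordered-unique: keep the max score for duplicate pairs
            if g.has_edge(a, b):
                g[a][b]["weight"] = max(g[a][b]["weight"], s)
            else:
                g.add_edge(a, b, weight=s)
    while True:
        low = [n for n, d in g.degree() if d < min_degree]
        if not low:
            break
        g.remove_nodes_from(low)
    return ProteinNetwork(g, threshold=min_confidence, source="reference")


def network_overlap(a: ProteinNetwork, b: ProteinNetwork) -> dict[str, float]:
    """Node and edge Jaccard overlap between two networks."""
    na, nb = set(a.graph.nodes), set(b.graph.nodes)
    ea, eb = a.edge_set(), b.edge_set()

    def jaccard(x: set, y: set) -> float:
        return len(x & y) / len(x | y) if (x | y) else float("nan")

    return {
        "shared_nodes": float(len(na & nb)),
        "shared_edges": float(len(ea & eb)),
        "node_jaccard": jaccard(na, nb),
        "edge_jaccard": jaccard(ea, eb),
    }
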