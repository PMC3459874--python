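"""Tissue-specific network construction: Node Removal and Edge Reweight.

Node Removal (NR) deletes proteins not expressed in the tissue together with
their edges; surviving edges keep their original confidence.  Edge Reweight
(ERW) keeps the topology and multiplies each edge's confidence by a penalty
factor ``rw`` per unexpressed endpoint, i.e. ``w' = w * rw^n`` with
``n in {0, 1, 2}``.  ``rw`` is interpreted as the probability that a gene
below the presence-call threshold is nonetheless expressed, so ``rw = 0``
reduces to NR (up to zero-weight edges kept structurally) and ``rw = 1``
leaves the generic network untouched.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
import scipy.sparse.csgraph as csgraph
from scipy import stats

from .core import ValidationError, WeightedNetwork

logger = logging.getLogger(__name__)

__all__ = [
    "ReweightConfig",
    "NetworkStats",
    "node_removal",
    "edge_reweight",
    "network_stats",
    "stats_report",
]


@dataclass(frozen=True)
class ReweightConfig:
    """Edge-reweight penalty factor, ``0 <= rw <= 1``."""

    rw: float = 0.1

    def __post_init__(self) -> None:
        if not (0.0 <= self.rw <= 1.0):
            raise ValidationError(f"rw={self.rw} outside [0, 1]")


@dataclass(frozen=True)
class NetworkStats:
    """Topological summary of one (tissue-specific) network."""

    n_nodes: int
    n_edges: int
    n_components: int
    giant_size: int
    mean_edges_per_expressed: float


def node_removal(net: WeightedNetwork, expressed: set[int]) -> WeightedNetwork:
    """Remove unexpressed proteins and all edges adjacent to them.

    Surviving edges retain their original weights.  Expressed nodes that lose
    every interactor stay in the node set as isolated nodes.
    """
    out = WeightedNetwork()
    kept_nodes = net.nodes & expressed
    for u, v, w in net.iter_edges():
        if u in kept_nodes and v in kept_nodes:
            out.add_edge(u, v, w)
    out._nodes.update(kept_nodes)  # keep isolated expressed nodes
    if not kept_nodes:
        logger.warning("node removal produced an empty network")
    return out


def edge_reweight(
    net: WeightedNetwork, expressed: set[int], cfg: ReweightConfig
) -> WeightedNetwork:
    """Penalize each edge by ``rw`` per unexpressed endpoint.

    The topology is unchanged: with ``rw = 0`` edges touching unexpressed
    genes are kept in the structure with weight 0, so node sets and score
    vector dimensions stay fixed across an rw sweep (propagation ignores
    zero-weight edges).
    """
    rw = cfg.rw
    out = WeightedNetwork()
    for u, v, w in net.iter_edges():
        n = (u not in expressed) + (v not in expressed)
        out.add_edge(u, v, w * rw**n)
    out._nodes.update(net.nodes)
    return out


def network_stats(net: WeightedNetwork, expressed: set[int]) -> NetworkStats:
    """Node/edge counts and component structure over positive-weight edges.

    A node with only zero-weight incident edges counts as a singleton
    component.  ``mean_edges_per_expressed`` divides the positive edge count
    by the number of expressed proteins present in the network (NaN if none).
    """
    nodes = sorted(net.nodes)
    pos = net.positive_edges()
    if nodes:
        if pos:
            adj = net.adjacency(max(nodes) + 1)
            adj = adj[nodes, :][:, nodes]
            n_comp, labels = csgraph.connected_components(adj, directed=False)
        else:
            n_comp, labels = len(nodes), np.arange(len(nodes))
        sizes = np.bincount(labels, minlength=n_comp)
        giant = int(sizes.max()) if sizes.size else 0
    else:
        n_comp, giant = 0, 0
    n_expr = len(expressed & net.nodes)
    mean_edges = len(pos) / n_expr if n_expr else float("nan")
    return NetworkStats(
        n_nodes=len(nodes),
        n_edges=len(pos),
        n_components=int(n_comp),
        giant_size=giant,
        mean_edges_per_expressed=mean_edges,
    )


def stats_report(
    stats_by_tissue: Mapping[str, NetworkStats],
    expressed_counts: Mapping[str, int] | None = None,
) -> tuple[pd.DataFrame, dict[str, tuple[float, float]]]:
    """Tabulate per-tissue stats and Pearson correlations.

    Correlates the expressed-protein count with (a) the edge count and (b) the
    mean number of edges per expressed protein.  ``expressed_counts`` defaults
    to the node counts of the stats themselves.  Zero-variance columns yield
    ``(nan, nan)``.
    """
    if len(stats_by_tissue) < 3:
        raise ValidationError("need at least 3 tissues for a correlation report")
    rows = []
    for tissue, s in stats_by_tissue.items():
        n_expr = (
            expressed_counts[tissue] if expressed_counts is not None else s.n_nodes
        )
        rows.append(
            {
                "tissue": tissue,
                "expressed_proteins": n_expr,
                "nodes": s.n_nodes,
                "edges": s.n_edges,
                "components": s.n_components,
                "giant_component": s.giant_size,
                "mean_edges_per_expressed": s.mean_edges_per_expressed,
            }
        )
    table = pd.DataFrame(rows).set_index("tissue")

    def _pearson(x: pd.Series, y: pd.Series) -> tuple[float, float]:
        if x.nunique() < 2 or y.nunique() < 2:
            return (float("nan"), float("nan"))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            r = stats.pearsonr(x, y)
        return (float(r.statistic), float(r.pvalue))

    correlations = {
        "expressed_vs_edges": _pearson(table["expressed_proteins"], table["edges"]),
        "expressed_vs_mean_edges": _pearson(
            table["expressed_proteins"], table["mean_edges_per_expressed"]
        ),
    }
    return table, correlations
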