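"""Propagation-based gene prioritization (the PRINCE scheme).

Given a query disease ``q``, each gene ``v`` receives a prior
``Y(v) = L(sim(q, d*))`` where ``d*`` is the disease associated with ``v``
that is phenotypically most similar to ``q`` and ``L`` is a logistic
``L(x) = 1 / (1 + exp(c*x + b))``; genes with no usable association get 0.
The prior is smoothed over the network by the iteration

    F <- alpha * W' F + (1 - alpha) * Y,      F0 = Y

where ``W'`` is the confidence matrix symmetrically normalized by weighted
degree, ``w'(u,v) = w(u,v) / sqrt(d(u) d(v))``.  Defaults follow the original
method: ``alpha = 0.9``, ``c = -15``, 10 iterations, and ``b = ln 9999`` so
that ``L(0) = 1e-4``.  The exact fixed point
``F* = (1 - alpha) (I - alpha W')^{-1} Y`` is available as a dense-solve
oracle for small networks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .core import (
    DiseaseSimilarity,
    GeneDiseaseAssociations,
    PropagationResult,
    ValidationError,
    WeightedNetwork,
)

__all__ = [
    "PropagationConfig",
    "logistic",
    "build_prior",
    "normalize_network",
    "propagate",
    "closed_form",
    "score_disease",
]

#: Node-count guard for the dense closed-form solver.
CLOSED_FORM_MAX_NODES = 2000


@dataclass(frozen=True)
class PropagationConfig:
    """Smoothing weight, iteration count and logistic prior constants."""

    alpha: float = 0.9
    iterations: int = 10
    c: float = -15.0
    b: float = math.log(9999.0)

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValidationError(f"alpha={self.alpha} outside (0, 1)")
        if self.iterations < 1:
            raise ValidationError("iterations must be >= 1")


def logistic(x: float, cfg: PropagationConfig) -> float:
    """The prior transfer function ``L(x) = 1 / (1 + exp(c*x + b))``."""
    return 1.0 / (1.0 + math.exp(cfg.c * x + cfg.b))


def build_prior(
    query: str,
    sim: DiseaseSimilarity,
    assocs: GeneDiseaseAssociations,
    cfg: PropagationConfig,
    n_genes: int,
    exclude: frozenset[tuple[int, str]] | set[tuple[int, str]] = frozenset(),
) -> np.ndarray:
    """Prior vector Y over the full catalog for one query disease.

    For each gene with at least one association not in ``exclude``, the
    associated disease most similar to ``query`` is chosen (the query itself,
    at similarity 1, qualifies when the gene is associated with it and the
    pair is not excluded).  All other genes get exactly 0.  In leave-one-out
    evaluation ``exclude`` holds the held-out pair and every other pair
    involving the held-out gene.
    """
    if query not in sim:
        raise ValidationError(f"unknown query disease {query!r}")
    Y = np.zeros(n_genes)
    for gene in assocs.genes:
        best = 0.0
        usable = False
        for d in assocs.diseases_of(gene):
            if (gene, d) in exclude:
                continue
            usable = True
            s = sim.sim(query, d)
            if s > best:
                best = s
        if usable:
            Y[gene] = logistic(best, cfg)
    return Y


def normalize_network(net: WeightedNetwork, n_genes: int) -> sp.csr_matrix:
    """Symmetric degree normalization ``w'(u,v) = w(u,v)/sqrt(d(u) d(v))``.

    Degrees are weighted (sums of incident confidences), which is what makes
    the normalization meaningful on edge-reweighted networks where the weights
    carry the tissue signal.  Nodes of zero weighted degree contribute no
    edges.  The operator is symmetric with spectral radius <= 1.
    """
    W = net.adjacency(n_genes)
    d = np.asarray(W.sum(axis=1)).ravel()
    with np.errstate(divide="ignore"):
        dinv = np.where(d > 0, 1.0 / np.sqrt(np.where(d > 0, d, 1.0)), 0.0)
    D = sp.diags(dinv)
    return (D @ W @ D).tocsr()


def propagate(
    Wn: sp.spmatrix,
    Y: np.ndarray,
    cfg: PropagationConfig,
    node_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Run the smoothing iteration for ``cfg.iterations`` steps from F0 = Y.

    ``node_mask`` marks genes present in the scored network; genes outside it
    (including their priors) are forced to exactly 0, implementing the rule
    that proteins absent from a node-removal network score 0.  Isolated nodes
    *inside* the mask converge to ``(1 - alpha) * Y``.
    """
    Y = np.asarray(Y, dtype=float)
    if not np.all(np.isfinite(Y)):
        raise ValidationError("non-finite prior")
    if node_mask is not None:
        Y = np.where(node_mask, Y, 0.0)
    F = Y.copy()
    for _ in range(cfg.iterations):
        F = cfg.alpha * (Wn @ F) + (1.0 - cfg.alpha) * Y
    if node_mask is not None:
        F = np.where(node_mask, F, 0.0)
    return F


def closed_form(
    Wn: sp.spmatrix,
    Y: np.ndarray,
    alpha: float,
    node_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Exact fixed point ``F* = (1 - alpha)(I - alpha W')^{-1} Y``.

    Dense solve, guarded to networks of at most 2000 nodes; used as the
    propagation oracle in tests.
    """
    n = Wn.shape[0]
    if n > CLOSED_FORM_MAX_NODES:
        raise ValidationError(
            f"closed-form solver limited to {CLOSED_FORM_MAX_NODES} nodes, got {n}"
        )
    Y = np.asarray(Y, dtype=float)
    if node_mask is not None:
        Y = np.where(node_mask, Y, 0.0)
    A = np.eye(n) - alpha * np.asarray(Wn.todense())
    F = np.linalg.solve(A, (1.0 - alpha) * Y)
    if node_mask is not None:
        F = np.where(node_mask, F, 0.0)
    return F


def score_disease(
    query: str,
    net: WeightedNetwork,
    sim: DiseaseSimilarity,
    assocs: GeneDiseaseAssociations,
    n_genes: int,
    cfg: PropagationConfig | None = None,
    exclude: frozenset[tuple[int, str]] | set[tuple[int, str]] = frozenset(),
    label: str = "generic",
) -> PropagationResult:
    """Convenience wrapper: prior construction + normalization + propagation."""
    cfg = cfg or PropagationConfig()
    Y = build_prior(query, sim, assocs, cfg, n_genes, exclude=exclude)
    Wn = normalize_network(net, n_genes)
    F = propagate(Wn, Y, cfg, node_mask=net.node_mask(n_genes))
    return PropagationResult(query=query, label=label, scores=F)
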