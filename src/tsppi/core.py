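"""Core domain types for tissue-specific network-based gene prioritization.

The pipeline works over a catalog of genes indexed contiguously ``0..G-1``
(files use 1-based indices; conversion happens at the I/O boundary in
:mod:`tsppi.io`).  The central objects are a weighted undirected
protein-interaction network, a gene-by-tissue expression matrix in Affymetrix
average-difference (AD) units with its binarized presence calls, and the three
association tables that drive prioritization: gene-disease pairs, a
disease-disease phenotypic similarity matrix in [0, 1], and a disease-by-tissue
association-score matrix normalized to percentages per disease.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd
import scipy.sparse as sp

logger = logging.getLogger(__name__)

__all__ = [
    "ValidationError",
    "ParseError",
    "GeneCatalog",
    "WeightedNetwork",
    "ExpressionMatrix",
    "BinaryExpressionProfiles",
    "GeneDiseaseAssociations",
    "DiseaseSimilarity",
    "DiseaseTissueMatrix",
    "PropagationResult",
    "DEFAULT_TAU",
]

#: Default presence-call threshold in Affymetrix average-difference units.
DEFAULT_TAU = 200.0


class ValidationError(ValueError):
    """An input object violates a documented invariant."""


class ParseError(ValueError):
    """A file could not be parsed; the message carries the line number."""


class GeneCatalog:
    """Ordered gene catalog with genomic positions.

    Parameters
    ----------
    gene_ids:
        External identifiers (e.g. Entrez ids as strings), one per gene.  The
        position in this sequence *is* the internal 0-based index.
    chromosomes:
        Chromosome label per gene.
    positions:
        Ordinal position of the gene along its chromosome.  Ordinals must be
        unique within a chromosome; they need not be dense.
    """

    def __init__(
        self,
        gene_ids: Iterable[str],
        chromosomes: Iterable[str],
        positions: Iterable[int],
    ):
        self.gene_ids = tuple(str(g) for g in gene_ids)
        self.chromosomes = tuple(str(c) for c in chromosomes)
        self.positions = tuple(int(p) for p in positions)
        if not (len(self.gene_ids) == len(self.chromosomes) == len(self.positions)):
            raise ValidationError("catalog columns have unequal lengths")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValidationError("duplicate gene ids in catalog")
        seen: set[tuple[str, int]] = set()
        for c, p in zip(self.chromosomes, self.positions):
            if (c, p) in seen:
                raise ValidationError(
                    f"duplicate genomic ordinal {p} on chromosome {c!r}"
                )
            seen.add((c, p))
        self._index = {g: i for i, g in enumerate(self.gene_ids)}
        self._by_chrom: dict[str, list[int]] = {}
        for i, c in enumerate(self.chromosomes):
            self._by_chrom.setdefault(c, []).append(i)
        for c, members in self._by_chrom.items():
            members.sort(key=lambda i: self.positions[i])

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def index_of(self, gene_id: str) -> int:
        try:
            return self._index[gene_id]
        except KeyError:
            raise ValidationError(f"unknown gene id {gene_id!r}") from None

    def genes_on(self, chromosome: str) -> list[int]:
        """Internal indices of the genes on ``chromosome`` in genomic order."""
        return list(self._by_chrom.get(chromosome, []))

    def __len__(self) -> int:
        return self.n_genes

    def __repr__(self) -> str:
        return f"GeneCatalog({self.n_genes} genes, {len(self._by_chrom)} chromosomes)"


def _edge_key(u: int, v: int) -> tuple[int, int]:
    return (u, v) if u < v else (v, u)


class WeightedNetwork:
    """Undirected weighted protein-interaction network over catalog indices.

    Edges are unordered pairs with a confidence weight.  Stored weights live in
    ``[0, 1]``: a weight of exactly 0 is permitted in memory so that the
    edge-reweight construction with ``rw = 0`` can keep the topology fixed
    across a parameter sweep, but the on-disk format (and propagation) treat
    zero-weight edges as absent.  Self-loops and duplicate edges are rejected.
    The node set may include isolated nodes (e.g. expressed proteins whose
    every interactor was removed).
    """

    __slots__ = ("_nodes", "_edges")

    def __init__(
        self,
        edges: Mapping[tuple[int, int], float] | Iterable[tuple[int, int, float]] = (),
        nodes: Iterable[int] = (),
    ):
        self._nodes: set[int] = set(int(n) for n in nodes)
        self._edges: dict[tuple[int, int], float] = {}
        if isinstance(edges, Mapping):
            items: Iterable[tuple[int, int, float]] = (
                (u, v, w) for (u, v), w in edges.items()
            )
        else:
            items = edges
        for u, v, w in items:
            self.add_edge(u, v, w)

    def add_edge(self, u: int, v: int, w: float) -> None:
        u, v = int(u), int(v)
        if u == v:
            raise ValidationError(f"self-loop on gene index {u}")
        if not (0.0 <= w <= 1.0):
            raise ValidationError(f"edge weight {w} outside [0, 1] for ({u}, {v})")
        key = _edge_key(u, v)
        if key in self._edges:
            raise ValidationError(f"duplicate edge ({u}, {v})")
        self._edges[key] = float(w)
        self._nodes.add(u)
        self._nodes.add(v)

    def set_weight(self, u: int, v: int, w: float) -> None:
        """Overwrite the weight of an existing edge (still in [0, 1])."""
        key = _edge_key(int(u), int(v))
        if key not in self._edges:
            raise ValidationError(f"no edge ({u}, {v}) to reweight")
        if not (0.0 <= w <= 1.0):
            raise ValidationError(f"edge weight {w} outside [0, 1]")
        self._edges[key] = float(w)

    @property
    def nodes(self) -> frozenset[int]:
        return frozenset(self._nodes)

    @property
    def edges(self) -> dict[tuple[int, int], float]:
        return dict(self._edges)

    @property
    def n_nodes(self) -> int:
        return len(self._nodes)

    @property
    def n_edges(self) -> int:
        return len(self._edges)

    def weight(self, u: int, v: int) -> float:
        return self._edges[_edge_key(u, v)]

    def has_edge(self, u: int, v: int) -> bool:
        return _edge_key(u, v) in self._edges

    def iter_edges(self) -> Iterator[tuple[int, int, float]]:
        for (u, v), w in self._edges.items():
            yield u, v, w

    def positive_edges(self) -> list[tuple[int, int, float]]:
        return [(u, v, w) for (u, v), w in self._edges.items() if w > 0.0]

    def adjacency(self, n_genes: int) -> sp.csr_matrix:
        """Symmetric sparse adjacency over the full catalog index space.

        Zero-weight edges are dropped (propagation treats them as absent).
        """
        pos = self.positive_edges()
        if not pos:
            return sp.csr_matrix((n_genes, n_genes))
        us, vs, ws = zip(*pos)
        rows = np.concatenate([us, vs])
        cols = np.concatenate([vs, us])
        data = np.concatenate([ws, ws])
        return sp.csr_matrix((data, (rows, cols)), shape=(n_genes, n_genes))

    def node_mask(self, n_genes: int) -> np.ndarray:
        mask = np.zeros(n_genes, dtype=bool)
        if self._nodes:
            mask[np.fromiter(self._nodes, dtype=int)] = True
        return mask

    def copy(self) -> "WeightedNetwork":
        out = WeightedNetwork()
        out._nodes = set(self._nodes)
        out._edges = dict(self._edges)
        return out

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, WeightedNetwork):
            return NotImplemented
        return self._nodes == other._nodes and self._edges == other._edges

    def __repr__(self) -> str:
        return f"WeightedNetwork({self.n_nodes} nodes, {self.n_edges} edges)"


class ExpressionMatrix:
    """Gene-by-tissue expression in Affymetrix average-difference units.

    Rows are indexed by internal gene indices, columns by tissue names.
    Negative entries (microarray artifacts) are floored to zero at
    construction with a logged warning.
    """

    def __init__(self, data: pd.DataFrame):
        if data.columns.duplicated().any():
            raise ValidationError("duplicate tissue names in expression matrix")
        if data.index.duplicated().any():
            raise ValidationError("duplicate gene rows in expression matrix")
        values = data.to_numpy(dtype=float)
        if not np.all(np.isfinite(values)):
            raise ValidationError("non-finite expression values")
        n_neg = int((values < 0).sum())
        if n_neg:
            logger.warning("flooring %d negative AD entries to 0", n_neg)
            values = np.clip(values, 0.0, None)
        self.data = pd.DataFrame(values, index=data.index, columns=data.columns)

    @property
    def tissues(self) -> list[str]:
        return [str(t) for t in self.data.columns]

    @property
    def gene_indices(self) -> np.ndarray:
        return self.data.index.to_numpy()

    def __repr__(self) -> str:
        return f"ExpressionMatrix({self.data.shape[0]} genes x {self.data.shape[1]} tissues)"


class BinaryExpressionProfiles:
    """Presence calls: gene is expressed in a tissue iff AD >= tau (inclusive)."""

    def __init__(self, calls: pd.DataFrame, tau: float):
        if calls.columns.duplicated().any():
            raise ValidationError("duplicate tissue names in profiles")
        self.calls = calls.astype(bool)
        self.tau = float(tau)

    @property
    def tissues(self) -> list[str]:
        return [str(t) for t in self.calls.columns]

    def is_expressed(self, gene: int, tissue: str) -> bool:
        try:
            return bool(self.calls.at[gene, tissue])
        except KeyError:
            raise ValidationError(
                f"unknown gene {gene} or tissue {tissue!r} in profiles"
            ) from None

    def expressed_in(self, tissue: str) -> set[int]:
        """Internal indices of the genes called present in ``tissue``."""
        if tissue not in self.calls.columns:
            raise ValidationError(f"unknown tissue {tissue!r}")
        col = self.calls[tissue]
        return set(col.index[col.to_numpy()].tolist())

    def breadth(self, gene: int) -> int:
        """Expression breadth: number of tissues where the gene is present."""
        if gene not in self.calls.index:
            raise ValidationError(f"unknown gene {gene} in profiles")
        return int(self.calls.loc[gene].sum())

    def __repr__(self) -> str:
        return (
            f"BinaryExpressionProfiles({self.calls.shape[0]} genes x "
            f"{self.calls.shape[1]} tissues, tau={self.tau})"
        )


class GeneDiseaseAssociations:
    """A set of (gene index, disease id) association pairs."""

    def __init__(self, pairs: Iterable[tuple[int, str]]):
        seen: set[tuple[int, str]] = set()
        ordered: list[tuple[int, str]] = []
        for g, d in pairs:
            key = (int(g), str(d))
            if key in seen:
                raise ValidationError(f"duplicate association {key}")
            seen.add(key)
            ordered.append(key)
        self.pairs: tuple[tuple[int, str], ...] = tuple(ordered)
        self._by_gene: dict[int, list[str]] = {}
        self._by_disease: dict[str, list[int]] = {}
        for g, d in self.pairs:
            self._by_gene.setdefault(g, []).append(d)
            self._by_disease.setdefault(d, []).append(g)

    def validate_against(
        self,
        catalog: GeneCatalog | None = None,
        similarity: "DiseaseSimilarity | None" = None,
    ) -> None:
        if catalog is not None:
            for g, _ in self.pairs:
                if not (0 <= g < catalog.n_genes):
                    raise ValidationError(f"gene index {g} outside catalog")
        if similarity is not None:
            known = set(similarity.diseases)
            for _, d in self.pairs:
                if d not in known:
                    raise ValidationError(
                        f"disease {d!r} absent from similarity matrix"
                    )

    @property
    def genes(self) -> set[int]:
        return set(self._by_gene)

    @property
    def diseases(self) -> set[str]:
        return set(self._by_disease)

    def diseases_of(self, gene: int) -> list[str]:
        return list(self._by_gene.get(gene, []))

    def genes_of(self, disease: str) -> list[int]:
        return list(self._by_disease.get(disease, []))

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self) -> Iterator[tuple[int, str]]:
        return iter(self.pairs)

    def __repr__(self) -> str:
        return (
            f"GeneDiseaseAssociations({len(self.pairs)} pairs, "
            f"{len(self._by_gene)} genes, {len(self._by_disease)} diseases)"
        )


class DiseaseSimilarity:
    """Symmetric disease-disease phenotypic similarity matrix with entries in [0, 1].

    The diagonal is treated as 1 by :meth:`sim` regardless of the stored value;
    callers implement their own exclusion rules (e.g. leave-one-out removal of
    held-out associations) before querying.
    """

    def __init__(self, data: pd.DataFrame):
        if list(data.index) != list(data.columns):
            raise ValidationError("similarity matrix rows and columns differ")
        values = data.to_numpy(dtype=float)
        if values.shape[0] != values.shape[1]:
            raise ValidationError("similarity matrix is not square")
        if not np.all(np.isfinite(values)):
            raise ValidationError("non-finite similarity values")
        if (values < 0).any() or (values > 1).any():
            raise ValidationError("similarity values outside [0, 1]")
        if not np.allclose(values, values.T, atol=1e-12):
            raise ValidationError("similarity matrix is not symmetric")
        self.data = pd.DataFrame(values, index=data.index, columns=data.columns)
        self._pos = {str(d): i for i, d in enumerate(data.index)}
        self._values = values

    @property
    def diseases(self) -> list[str]:
        return [str(d) for d in self.data.index]

    def sim(self, a: str, b: str) -> float:
        if a == b:
            return 1.0
        try:
            return float(self._values[self._pos[a], self._pos[b]])
        except KeyError as exc:
            raise ValidationError(f"unknown disease {exc.args[0]!r}") from None

    def __contains__(self, disease: str) -> bool:
        return disease in self._pos


class DiseaseTissueMatrix:
    """Disease-by-tissue association scores in percent, normalized per disease.

    Every row must be nonnegative and sum to 100 (tolerance 1e-6).
    """

    ROW_SUM_TOL = 1e-6

    def __init__(self, data: pd.DataFrame):
        values = data.to_numpy(dtype=float)
        if (values < 0).any():
            raise ValidationError("negative disease-tissue score")
        sums = values.sum(axis=1)
        bad = np.where(np.abs(sums - 100.0) > self.ROW_SUM_TOL)[0]
        if bad.size:
            d = data.index[bad[0]]
            raise ValidationError(
                f"disease {d!r} row sums to {sums[bad[0]]:.8f}, expected 100"
            )
        if data.columns.duplicated().any():
            raise ValidationError("duplicate tissue names")
        if data.index.duplicated().any():
            raise ValidationError("duplicate disease rows")
        self.data = pd.DataFrame(values, index=data.index, columns=data.columns)

    @property
    def diseases(self) -> list[str]:
        return [str(d) for d in self.data.index]

    @property
    def tissues(self) -> list[str]:
        return [str(t) for t in self.data.columns]


@dataclass
class PropagationResult:
    """Per-gene propagation scores for one query disease on one network.

    ``scores`` spans the whole catalog; genes absent from the scored network
    carry a score of exactly 0.
    """

    query: str
    label: str
    scores: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if not np.all(np.isfinite(self.scores)):
            raise ValidationError("non-finite propagation scores")

    def __repr__(self) -> str:
        return (
            f"PropagationResult(query={self.query!r}, label={self.label!r}, "
            f"{self.scores.size} genes)"
        )
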