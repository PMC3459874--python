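"""Cross-validation benchmark for generic vs. tissue-specific prioritization.

Each held-out gene-disease association becomes an evaluation case: the pair
(and every other association of the held-out gene) is removed, the
prioritizer scores the network, and the causal gene competes against an
artificial genomic interval of 100 network genes surrounding it.  Results are
aggregated as a pooled ROC/AUC (scores bundled across all trials), a per-case
rank comparison between network variants with a Wilcoxon signed-rank test,
repeated k-fold AUC spreads, and an rw parameter sweep.

Tie-breaking is pessimistic throughout: the causal gene is ranked after every
candidate tied with it.  Node-removal networks assign many exact zeros to
unexpressed candidates, and an optimistic rule would fabricate perfect ranks
for unexpressed causal genes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sstats
from sklearn.metrics import roc_curve as _sk_roc_curve

from .core import (
    BinaryExpressionProfiles,
    DiseaseSimilarity,
    GeneCatalog,
    GeneDiseaseAssociations,
    PropagationResult,
    ValidationError,
    WeightedNetwork,
)
from .expression import TissueAssignment
from .networks import ReweightConfig, edge_reweight
from .propagation import PropagationConfig, build_prior, normalize_network, propagate

logger = logging.getLogger(__name__)

__all__ = [
    "NetworkVariant",
    "EvaluationCase",
    "BenchmarkResult",
    "build_interval",
    "rank_of",
    "loocv",
    "RocCurve",
    "pooled_roc",
    "auc_from_scores",
    "RankComparison",
    "compare_rankings",
    "WilcoxonResult",
    "wilcoxon_signed_rank",
    "KFoldResult",
    "kfold_auc_spread",
    "SweepResult",
    "rw_sweep",
    "attenuate_unexpressed",
]


@dataclass
class NetworkVariant:
    """One network configuration to benchmark.

    Either ``network`` (a single tissue-agnostic network) or ``by_tissue``
    (one network per tissue; cases are scored on their disease's assigned
    tissue) must be set.  ``attenuate`` additionally zeroes the scores of
    genes not expressed in the case's tissue after propagation.
    """

    label: str
    network: WeightedNetwork | None = None
    by_tissue: Mapping[str, WeightedNetwork] | None = None
    attenuate: bool = False

    def __post_init__(self) -> None:
        if (self.network is None) == (self.by_tissue is None):
            raise ValidationError(
                f"variant {self.label!r}: exactly one of network/by_tissue required"
            )

    @property
    def tissue_specific(self) -> bool:
        return self.by_tissue is not None

    def resolve(self, tissue: str | None) -> WeightedNetwork:
        if self.by_tissue is None:
            assert self.network is not None
            return self.network
        if tissue is None or tissue not in self.by_tissue:
            raise ValidationError(
                f"variant {self.label!r}: no network for tissue {tissue!r}"
            )
        return self.by_tissue[tissue]


@dataclass
class EvaluationCase:
    """One held-out association with its candidate interval and per-network ranks.

    Candidate scores are aligned to ``candidates`` = interval genes followed by
    the held-out gene itself (so the causal score is always last).
    """

    gene: int
    disease: str
    tissue: str | None
    interval: tuple[int, ...]
    scores: dict[str, np.ndarray] = field(default_factory=dict, repr=False)
    ranks: dict[str, int] = field(default_factory=dict)

    @property
    def candidates(self) -> tuple[int, ...]:
        return self.interval + (self.gene,)


def build_interval(
    g: int,
    catalog: GeneCatalog,
    net: WeightedNetwork,
    size: int = 100,
) -> list[int]:
    """The ``size`` generic-network genes genomically nearest to ``g``.

    Balanced 50/50 up/downstream of ``g`` on its chromosome, spilling over to
    the other side at chromosome ends; non-network genes are skipped.  ``g``
    itself is excluded.  Raises if the chromosome holds fewer than ``size``
    network genes besides ``g``.
    """
    if g not in net.nodes:
        raise ValidationError(f"gene {g} is not part of the network")
    chrom = catalog.chromosomes[g]
    members = [i for i in catalog.genes_on(chrom) if i in net.nodes]
    pos = members.index(g)
    left, right = members[:pos], members[pos + 1 :]
    if len(left) + len(right) < size:
        raise ValidationError(
            f"chromosome {chrom!r} has only {len(left) + len(right)} network genes "
            f"around gene {g}, need {size}"
        )
    n_left = size // 2
    n_right = size - n_left
    if len(left) < n_left:
        n_right += n_left - len(left)
        n_left = len(left)
    if len(right) < n_right:
        n_left += n_right - len(right)
        n_right = len(right)
    chosen = (left[len(left) - n_left :] if n_left else []) + right[:n_right]
    return chosen


def rank_of(scores: np.ndarray, target_pos: int) -> int:
    """Rank of ``scores[target_pos]`` by descending score, pessimistic on ties."""
    scores = np.asarray(scores, dtype=float)
    s = scores[target_pos]
    higher = int((scores > s).sum())
    tied = int((scores == s).sum()) - 1
    return higher + tied + 1


class _VariantState:
    """Lazily cached normalized operators / masks per (variant, tissue)."""

    def __init__(self, variant: NetworkVariant, n_genes: int):
        self.variant = variant
        self.n_genes = n_genes
        self._cache: dict[str | None, tuple] = {}

    def operator(self, tissue: str | None):
        key = None if not self.variant.tissue_specific else tissue
        if key not in self._cache:
            net = self.variant.resolve(tissue)
            self._cache[key] = (
                normalize_network(net, self.n_genes),
                net.node_mask(self.n_genes),
            )
        return self._cache[key]


def _select_cases(
    assocs: GeneDiseaseAssociations,
    assign: TissueAssignment | None,
    mas_threshold: float | None,
    expressed_only: bool,
    profiles: BinaryExpressionProfiles | None,
    need_tissue: bool,
) -> list[tuple[int, str, str | None]]:
    cases: list[tuple[int, str, str | None]] = []
    for g, d in assocs.pairs:
        tissue: str | None = None
        if assign is not None and d in assign.tissue:
            if mas_threshold is not None and assign.mas[d] <= mas_threshold:
                continue
            tissue = assign.tissue[d]
        elif mas_threshold is not None or need_tissue:
            raise ValidationError(f"disease {d!r} has no tissue assignment")
        if expressed_only:
            if profiles is None or tissue is None:
                raise ValidationError(
                    "expressed_only requires profiles and tissue assignments"
                )
            if not profiles.is_expressed(g, tissue):
                continue
        cases.append((g, d, tissue))
    return cases


def _score_case(
    g: int,
    d: str,
    tissue: str | None,
    interval: list[int],
    exclude: frozenset[tuple[int, str]],
    states: dict[str, _VariantState],
    sim: DiseaseSimilarity,
    assocs: GeneDiseaseAssociations,
    cfg: PropagationConfig,
    n_genes: int,
    profiles: BinaryExpressionProfiles | None,
) -> EvaluationCase:
    case = EvaluationCase(gene=g, disease=d, tissue=tissue, interval=tuple(interval))
    Y = build_prior(d, sim, assocs, cfg, n_genes, exclude=exclude)
    cand = np.array(case.candidates, dtype=int)
    for label, state in states.items():
        Wn, mask = state.operator(tissue)
        F = propagate(Wn, Y, cfg, node_mask=mask)
        if state.variant.attenuate:
            if profiles is None or tissue is None:
                raise ValidationError(
                    f"variant {label!r}: attenuation requires profiles and a tissue"
                )
            expr_mask = np.zeros(n_genes, dtype=bool)
            expr_mask[list(profiles.expressed_in(tissue))] = True
            F = np.where(expr_mask, F, 0.0)
        case.scores[label] = F[cand]
        case.ranks[label] = rank_of(case.scores[label], len(cand) - 1)
    return case


def loocv(
    assocs: GeneDiseaseAssociations,
    variants: Sequence[NetworkVariant],
    *,
    sim: DiseaseSimilarity,
    catalog: GeneCatalog,
    interval_network: WeightedNetwork,
    assign: TissueAssignment | None = None,
    profiles: BinaryExpressionProfiles | None = None,
    cfg: PropagationConfig | None = None,
    mas_threshold: float | None = None,
    expressed_only: bool = False,
    interval_size: int = 100,
) -> list[EvaluationCase]:
    """Leave-one-out cross-validation over all (filtered) associations.

    For each case the held-out pair and every other association involving the
    held-out gene are removed before prior construction; all requested network
    variants are then scored on the same candidates (the interval built on the
    generic ``interval_network`` plus the gene itself).
    """
    cfg = cfg or PropagationConfig()
    n_genes = catalog.n_genes
    need_tissue = any(v.tissue_specific or v.attenuate for v in variants)
    cases_def = _select_cases(
        assocs, assign, mas_threshold, expressed_only, profiles, need_tissue
    )
    states = {v.label: _VariantState(v, n_genes) for v in variants}
    out: list[EvaluationCase] = []
    for g, d, tissue in cases_def:
        interval = build_interval(g, catalog, interval_network, size=interval_size)
        exclude = frozenset((g, d2) for d2 in assocs.diseases_of(g))
        out.append(
            _score_case(
                g, d, tissue, interval, exclude, states, sim, assocs, cfg,
                n_genes, profiles,
            )
        )
    return out


@dataclass
class RocCurve:
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    n_pos: int
    n_neg: int


def auc_from_scores(pos: np.ndarray, neg: np.ndarray) -> float:
    """AUC by the Mann-Whitney rank formula (ties contribute 1/2)."""
    pos = np.asarray(pos, dtype=float)
    neg = np.asarray(neg, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValidationError("AUC needs at least one positive and one negative")
    pooled = np.concatenate([pos, neg])
    if np.all(pooled == pooled[0]):
        warnings.warn("all pooled scores identical; AUC is 0.5 by tie convention")
    ranks = sstats.rankdata(pooled)
    r_pos = ranks[: pos.size].sum()
    return float((r_pos - pos.size * (pos.size + 1) / 2.0) / (pos.size * neg.size))


def pooled_roc(cases: Sequence[EvaluationCase], label: str) -> RocCurve:
    """ROC over scores bundled across all cross-validation trials.

    Positives are the held-out causal genes; negatives all other interval
    candidates (labels assigned per trial, then concatenated).
    """
    pos = np.array([c.scores[label][-1] for c in cases])
    neg = np.concatenate([c.scores[label][:-1] for c in cases])
    y = np.concatenate([np.ones(pos.size), np.zeros(neg.size)])
    s = np.concatenate([pos, neg])
    fpr, tpr, _ = _sk_roc_curve(y, s)
    return RocCurve(
        fpr=fpr, tpr=tpr, auc=auc_from_scores(pos, neg),
        n_pos=pos.size, n_neg=neg.size,
    )


@dataclass
class WilcoxonResult:
    statistic: float  # W+ (sum of ranks of positive differences)
    p_value: float
    n_used: int


def wilcoxon_signed_rank(x: Sequence[float], y: Sequence[float]) -> WilcoxonResult:
    """Two-sided Wilcoxon signed-rank test on paired samples.

    Zero differences are dropped.  For n <= 25 the p-value is exact,
    computed from the conditional permutation distribution of W+ given the
    observed (possibly tied, mid-) ranks; above that, a normal approximation
    with tie and continuity corrections is used.
    """
    d = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    d = d[d != 0]
    n = d.size
    if n == 0:
        return WilcoxonResult(statistic=0.0, p_value=1.0, n_used=0)
    ranks = sstats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= 25:
        r2 = np.rint(2 * ranks).astype(int)  # doubled ranks are integers
        total = int(r2.sum())
        counts = np.zeros(total + 1)
        counts[0] = 1.0
        for r in r2:
            shifted = np.concatenate([np.zeros(r), counts[: total + 1 - r]])
            counts = counts + shifted
        w2 = int(round(2 * w_plus))
        denom = 2.0**n
        p_ge = counts[w2:].sum() / denom
        p_le = counts[: w2 + 1].sum() / denom
        p = min(1.0, 2.0 * min(p_ge, p_le))
    else:
        mu = n * (n + 1) / 4.0
        var = n * (n + 1) * (2 * n + 1) / 24.0
        _, tie_counts = np.unique(ranks, return_counts=True)
        var -= (tie_counts**3 - tie_counts).sum() / 48.0
        diff = w_plus - mu
        corr = 0.5 * np.sign(diff)
        z = (diff - corr) / np.sqrt(var) if var > 0 else 0.0
        p = min(1.0, 2.0 * sstats.norm.sf(abs(z)))
    return WilcoxonResult(statistic=w_plus, p_value=float(p), n_used=n)


@dataclass
class RankComparison:
    better: int  # cases where A ranks the causal gene better (lower) than B
    tie: int
    worse: int
    wilcoxon: WilcoxonResult


def compare_rankings(
    ranks_a: Sequence[int], ranks_b: Sequence[int]
) -> RankComparison:
    """Per-case rank comparison between two network variants.

    ``better`` counts cases where variant A gives the causal gene a strictly
    better (numerically lower) rank.  The Wilcoxon signed-rank test is applied
    to the paired ranks with zero differences dropped; if all pairs tie the
    p-value is 1.
    """
    a = np.asarray(ranks_a)
    b = np.asarray(ranks_b)
    if a.shape != b.shape:
        raise ValidationError("rank vectors must pair the same case set")
    return RankComparison(
        better=int((a < b).sum()),
        tie=int((a == b).sum()),
        worse=int((a > b).sum()),
        wilcoxon=wilcoxon_signed_rank(a, b),
    )


@dataclass
class BenchmarkResult:
    """Aggregate of a benchmark run across network variants."""

    auc: dict[str, float]
    rank_table: pd.DataFrame
    comparisons: dict[str, RankComparison]  # each variant vs. the baseline
    baseline: str

    def __post_init__(self) -> None:
        n = len(self.rank_table)
        for label, comp in self.comparisons.items():
            if comp.better + comp.tie + comp.worse != n:
                raise ValidationError(f"comparison {label!r} does not cover all cases")


def summarize(
    cases: Sequence[EvaluationCase], baseline: str = "generic"
) -> BenchmarkResult:
    """Pooled AUC per variant plus rank comparisons against ``baseline``."""
    labels = list(cases[0].ranks)
    table = pd.DataFrame(
        {label: [c.ranks[label] for c in cases] for label in labels},
        index=pd.MultiIndex.from_tuples(
            [(c.disease, c.gene) for c in cases], names=["disease", "gene"]
        ),
    )
    auc = {label: pooled_roc(cases, label).auc for label in labels}
    comparisons = {
        label: compare_rankings(table[label], table[baseline])
        for label in labels
        if label != baseline
    }
    return BenchmarkResult(
        auc=auc, rank_table=table, comparisons=comparisons, baseline=baseline
    )


@dataclass
class KFoldResult:
    mean_auc: float
    std_auc: float
    aucs: np.ndarray


def kfold_auc_spread(
    assocs: GeneDiseaseAssociations,
    variant: NetworkVariant,
    *,
    sim: DiseaseSimilarity,
    catalog: GeneCatalog,
    interval_network: WeightedNetwork,
    assign: TissueAssignment | None = None,
    profiles: BinaryExpressionProfiles | None = None,
    cfg: PropagationConfig | None = None,
    mas_threshold: float | None = None,
    expressed_only: bool = False,
    interval_size: int = 100,
    k: int = 25,
    n_partitions: int = 10,
    seed: int | None = None,
) -> KFoldResult:
    """AUC spread over repeated random k-fold partitions (error bars).

    For each partition the associations are split into ``k`` folds; each fold
    is held out en bloc (its pairs, plus every association of its genes, are
    excluded from the prior) and all per-case scores of the partition are
    pooled into a single AUC.  The standard deviation over partitions is the
    reported spread.
    """
    if seed is None:
        raise ValidationError("a seed is required for random partitions")
    cfg = cfg or PropagationConfig()
    n_genes = catalog.n_genes
    need_tissue = variant.tissue_specific or variant.attenuate
    cases_def = _select_cases(
        assocs, assign, mas_threshold, expressed_only, profiles, need_tissue
    )
    if k > len(cases_def):
        raise ValidationError(f"k={k} exceeds the {len(cases_def)} cases")
    if n_partitions == 1:
        warnings.warn("a single partition yields a zero standard deviation")
    rng = np.random.default_rng(seed)
    states = {variant.label: _VariantState(variant, n_genes)}
    intervals = {
        g: build_interval(g, catalog, interval_network, size=interval_size)
        for g, _, _ in cases_def
    }
    aucs = np.empty(n_partitions)
    for p in range(n_partitions):
        order = rng.permutation(len(cases_def))
        folds = np.array_split(order, k)
        pos_scores: list[float] = []
        neg_scores: list[np.ndarray] = []
        for fold in folds:
            fold_cases = [cases_def[i] for i in fold]
            exclude = set()
            for g, d, _ in fold_cases:
                for d2 in assocs.diseases_of(g):
                    exclude.add((g, d2))
            fexclude = frozenset(exclude)
            for g, d, tissue in fold_cases:
                case = _score_case(
                    g, d, tissue, intervals[g], fexclude, states, sim,
                    assocs, cfg, n_genes, profiles,
                )
                s = case.scores[variant.label]
                pos_scores.append(float(s[-1]))
                neg_scores.append(s[:-1])
        aucs[p] = auc_from_scores(np.array(pos_scores), np.concatenate(neg_scores))
    return KFoldResult(float(aucs.mean()), float(aucs.std()), aucs)


@dataclass
class SweepResult:
    table: dict[float, float]  # rw -> pooled AUC
    best_rw: float


def rw_sweep(
    assocs: GeneDiseaseAssociations,
    generic: WeightedNetwork,
    expressed_by_tissue: Mapping[str, set[int]],
    *,
    sim: DiseaseSimilarity,
    catalog: GeneCatalog,
    assign: TissueAssignment,
    profiles: BinaryExpressionProfiles | None = None,
    cfg: PropagationConfig | None = None,
    mas_threshold: float | None = None,
    expressed_only: bool = False,
    interval_size: int = 100,
    grid_step: float = 0.1,
    convergence_tol: float = 0.005,
    max_refinements: int = 6,
) -> SweepResult:
    """Sweep the ERW penalty over a constant grid, then refine downward.

    The grid covers [0, 1] at ``grid_step``; afterwards the lowest nonzero
    grid value is divided by successive orders of magnitude until performance
    declines and converges (within ``convergence_tol``) to the AUC at rw = 0.
    Returns the full rw -> AUC table and the argmax.
    """

    def _auc_at(rw: float) -> float:
        nets = {
            t: edge_reweight(generic, ex, ReweightConfig(rw))
            for t, ex in expressed_by_tissue.items()
        }
        cases = loocv(
            assocs,
            [NetworkVariant(label="erw", by_tissue=nets)],
            sim=sim,
            catalog=catalog,
            interval_network=generic,
            assign=assign,
            profiles=profiles,
            cfg=cfg,
            mas_threshold=mas_threshold,
            expressed_only=expressed_only,
            interval_size=interval_size,
        )
        return pooled_roc(cases, "erw").auc

    grid = np.arange(0.0, 1.0 + 1e-9, grid_step)
    table: dict[float, float] = {}
    for rw in grid:
        table[float(round(rw, 10))] = _auc_at(float(rw))
    auc_zero = table[0.0]
    lowest_nonzero = float(round(grid[1], 10)) if grid.size > 1 else grid_step
    prev = table[lowest_nonzero]
    rw = lowest_nonzero
    for _ in range(max_refinements):
        rw /= 10.0
        auc = _auc_at(rw)
        table[float(rw)] = auc
        declined = auc < prev
        converged = abs(auc - auc_zero) <= convergence_tol
        prev = auc
        if declined and converged:
            break
    best_rw = max(table, key=lambda r: (table[r], r))
    return SweepResult(table=table, best_rw=best_rw)


def attenuate_unexpressed(
    result: PropagationResult, expressed: set[int]
) -> PropagationResult:
    """Zero the scores of genes outside ``expressed``; others unchanged."""
    scores = result.scores.copy()
    mask = np.zeros(scores.size, dtype=bool)
    if expressed:
        mask[np.fromiter(expressed, dtype=int)] = True
    scores[~mask] = 0.0
    return PropagationResult(
        query=result.query, label=f"{result.label}+attenuated", scores=scores
    )
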