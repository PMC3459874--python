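# Methods

## Model overview

`tsppi` treats a disease's tissue selectivity as a property of the *active*
interactome: a protein interaction can only contribute to disease mechanism in
a tissue where both partners are present. The pipeline therefore (1) derives
binary presence calls from an mRNA expression atlas, (2) rewrites a weighted
generic protein-interaction network into one network per tissue, (3) runs a
propagation-based prioritizer on the tissue network matching each disease, and
(4) quantifies what the tissue information buys, both for candidate-gene
ranking and for inferring which tissues a disease touches.

The underlying assumptions are explicit and testable: mRNA presence is a
usable proxy for protein presence; an interaction's confidence in tissue *t*
is its generic confidence times the probability both partners are expressed
in *t*; and genes causing phenotypically similar diseases lie close to one
another in the (tissue-specific) network.

## Presence calls and expression statistics

Probe-level atlases are collapsed in two steps: replicate arrays of a tissue
are arithmetic-averaged per probe, then each gene keeps the single probe with
the maximal *across-tissue mean*. The alternative — picking the best probe
per tissue — would splice incomparable probes into one profile; the global
choice keeps a gene's values comparable across tissues. A gene is *expressed*
in a tissue iff its value is at least τ Affymetrix average-difference (AD)
units; τ = 200 by default and "at least" is inclusive. "Lowly expressed" and
"not expressed" are the same predicate (AD < τ). Negative AD entries (array
artifacts) are floored to zero at load time with a warning.

Each disease is assigned the tissue attaining its maximal association score
(MAS, in percent, rows normalized to 100); diseases below a MAS threshold
(default 40%) are excluded. Two permutation tests accompany the
expressed-fraction statistic:

- the **assignment-vector null** permutes the disease→tissue assignment as a
  vector, preserving the empirical popularity of tissues, and tests the
  observed expressed fraction against the upper tail;
- the **matched-random null** replaces each lowly-expressed causal gene by a
  random gene lowly expressed in the same tissue (without replacement within
  a set, with replacement across the 10,000 sets) and compares mean
  expression breadth and mean across-tissue AD level two-sidedly.

All empirical p-values use the add-one convention `(1+k)/(N+1)`, so zero
exceedances of 10,000 permutations report `1/10001` — the package never
claims p = 0.

## Tissue-specific networks

*Node Removal* (NR) intersects the node set with the expressed genes and keeps
surviving edges at their original weights; expressed proteins that lose every
interactor remain as isolated nodes. *Edge Reweight* (ERW) keeps the topology
and multiplies each edge by `rw` per unexpressed endpoint (`w·rw^n`,
`n ∈ {0,1,2}`). `rw` is interpreted as the probability that a gene below τ is
nonetheless expressed; the defaults expose `rw = 0.1` as the
moderately-tissue-specific operating point.

Two representation choices matter downstream. First, ERW with `rw = 0` keeps
zero-weight edges *structurally*, so node sets and score-vector dimensions are
constant across an `rw` sweep; propagation and component statistics treat
zero-weight edges as absent, which makes the `rw = 0` network exactly
equivalent to NR after stripping (an identity the test suite asserts
bitwise). Second, connected components are defined over positive-weight edges
only, an expressed node with all-zero incident weights counting as its own
singleton.

## Propagation

For query disease *q*, gene *v* receives the prior
`Y(v) = L(max_d sim(q, d))` over *v*'s associated diseases *d*, with the
logistic `L(x) = 1/(1+exp(c·x+b))`; genes without usable associations get
exactly 0. Defaults `c = −15` and `b = ln 9999` put `L(0) = 1e−4` and
`L(1) ≈ 0.997`, so only genuinely similar diseases inject prior mass; both
constants are configurable. The network operator is the symmetric
normalization `w′(u,v) = w(u,v)/√(d(u)d(v))` with *weighted* degrees — on ERW
networks the weights carry the tissue signal, so edge-count degrees would
discard it. Scores follow

    F⁰ = Y,   Fᵗ⁺¹ = α·W′Fᵗ + (1−α)·Y

for 10 iterations at α = 0.9. Since the spectral radius of `αW′` is at most
α, the iteration contracts geometrically toward the fixed point
`F* = (1−α)(I−αW′)⁻¹Y`; a dense solver for `F*` (guarded to ≤ 2000 nodes)
serves as the in-package oracle, and the suite checks
`‖F₁₀−F*‖∞ ≤ α¹⁰‖Y‖∞` on random networks. Genes absent from the scored
network are forced to exactly 0 — this is what ranks unexpressed candidates
last on NR networks. Initialization at Y is a convention, not a commitment:
the fixed point is initialization-independent.

In cross-validation, the held-out pair *and every other association of the
held-out gene* are removed before prior construction (otherwise a gene
causing two similar diseases would be trivially recovered). Other genes
associated with the query itself keep their evidence at similarity 1.

## Benchmark harness

Each surviving association ⟨g, d⟩ yields one case: candidates are the 100
generic-network genes genomically nearest to *g* (balanced 50/50 up- and
downstream, spilling over at chromosome ends, non-network genes skipped)
plus *g* itself. Ranks are *pessimistic under ties* — the causal gene ranks
after every tied candidate. NR networks give unexpressed candidates exact
zeros, and an optimistic tie rule would award unexpressed causal genes rank 1
for free; the pessimistic rule makes the NR zero-score convention bite.

The pooled ROC concatenates scores across all trials (positives = held-out
causal genes, labels assigned per trial), and AUC uses the Mann–Whitney rank
formula, i.e. ties contribute ½ — identical to the trapezoid over the step
curve and cross-checked against a concordant-pair-counting oracle. Per-case
rank comparisons report better/tie/worse counts plus a two-sided Wilcoxon
signed-rank test: zero differences dropped, and for n ≤ 25 the p-value is
computed *exactly* from the permutation distribution of signed ranks
conditional on the observed (tied, mid-) ranks via a dynamic program over
doubled ranks; larger n uses the normal approximation with tie and continuity
corrections. The in-package implementation exists because the standard exact
routines decline data with ties or zeros, which paired integer ranks always
contain; it is validated against full 2ⁿ sign enumeration.

AUC uncertainty comes from repeated random k-fold partitions (default 25
folds, 10 partitions; a fold's pairs and its genes' other associations are
excluded en bloc), reported as the standard deviation over partition AUCs.
The `rw` sweep evaluates a constant grid on [0,1] then refines downward by
orders of magnitude, stopping once performance declines and converges to the
`rw = 0` AUC; the post-processing *attenuation* baseline (zero the scores of
unexpressed genes after generic propagation) is available for comparison
against the network-level constructions.

## Disease–tissue inference

For a disease with known causal gene, the prioritizer runs once per tissue on
that tissue's ERW network (`rw = 0.1`, a setting that behaves robustly across
association sets; configurable). Tissues are ordered by the causal gene's
relative rank in its artificial interval (scheme `relative_rank`) or by its
raw score (`absolute_score`, which differentiates more finely because raw
scores rarely tie). Tied tissues share a competition rank ("1, 2, 2, 4");
since a tie at the top makes several tissues "ranked first", the agreement
statistic is reported both tie-inclusively and strictly. The null redraws
each disease's tissue uniformly among the tissues where its causal gene is
expressed — countering the selection bias introduced by restricting to
expressed causal genes — and counts top-ranked draws over 1000 permutations.

## Synthetic data: what it emulates, and what it does not

The generator emulates the *shape* of the real inputs at desk scale:

- a preferential-attachment interactome (1500 genes, mean degree ≈ 2·m = 6 at
  the default m = 3) with confidences uniform on (0.05, 1];
- a housekeeping core (35% of genes expressed everywhere) plus random
  tissue-restricted expression tuned to ≈ 45% expressed per tissue, matching
  the middle of the range atlases report (13–71%);
- AD magnitudes drawn strictly on the designed side of τ — expressed values
  are `τ + LogNormal(ln 150, 1)`, unexpressed `τ·Beta(1.5, 4)` — so
  binarization recovers the designed calls exactly and every downstream test
  is crisp; marginal realism of AD values is deliberately secondary;
- disease families (four evaluated diseases + three *anchor* diseases each)
  sharing a home tissue and block-structured phenotypic similarity
  (within-family 0.6–0.9, baseline 0.02–0.15). Anchor genes form the
  family's network core: every evaluated causal gene links to every anchor
  at weight 0.35, so priors propagate between family members. Anchor
  diseases carry flat MAS rows (100/T per tissue) and therefore never pass
  the MAS filter — they supply prior mass but are never evaluation cases;
- causal genes are drawn from the network periphery (unweighted degree ≤ 6),
  reflecting that disease proteins are typically not the largest hubs, and
  are always expressed in their home tissue (a stated fraction is flipped
  unexpressed in the `confounded` preset, emulating the real-world minority
  of causal genes lowly expressed in their disease tissue);
- MAS rows put 55–80% on the home tissue (argmax is unambiguous) and rows
  sum to exactly 100; genomic order is a random permutation into ~300-gene
  chromosomes, so every gene has ≥ 100 network neighbors for interval
  construction.

The *decoy benchmark* additionally plants, per evaluated disease, five genes
inside the causal gene's genomic interval that are wired at weight 0.9 to all
of the family's anchors but are unexpressed in the home tissue. On the
generic network these decoys out-collect the causal gene (their prior-source
coupling is stronger by construction: weight 0.9 to every anchor vs. 0.35,
from a lower-degree position); on the home tissue's ERW network every decoy
edge is penalized by `rw`, demoting them. Decoys never connect to evaluated
causal genes — wiring them to family members directly would feed flow *back*
to the held-out gene through sibling decoys and dissolve the contrast. The
generic-vs-tissue-specific AUC gap grows monotonically with the decoy count.

What the generator does **not** emulate: probe-level noise and
cross-hybridization, correlated expression between network neighbors,
literature-derived similarity artifacts, dosage-dependent confidences, or any
property of the real human datasets. Passing tests therefore demonstrate that
the algorithms are implemented correctly and that the tissue mechanism works
*when present* — not that any particular real dataset contains it, nor do
they reproduce absolute performance numbers reported on proprietary data
assemblies.

## Numerical and design choices

- Gene indices are 1-based in files, 0-based in memory; conversion happens
  only in `tsppi.io`. Edge weights serialize via shortest round-trip `repr`,
  making write→read bit-exact; disease and tissue ids are opaque,
  case-sensitive strings.
- The sectioned edge-list format carries only edges, so isolated nodes do not
  survive serialization; NR outputs may contain isolated expressed nodes,
  which is documented behavior.
- Degenerate inputs are defined, not crashed on: an all-identical pooled
  score set yields AUC 0.5 with a warning; an all-tied rank comparison yields
  p = 1; a single-tissue assignment vector yields a degenerate null with
  p = 1; zero-variance columns in the correlation report yield NaN.
- Calibration of the permutation machinery is checked in the validity
  direction: under tissue-agnostic data the empirical CDF of 200 replicate
  p-values must not exceed the diagonal by more than the one-sided
  Kolmogorov–Smirnov critical value at level 0.01. Add-one permutation
  p-values are discrete and super-uniform by construction, so the two-sided
  statistic would be inflated by atom sizes even for a correct
  implementation; the one-sided form tests exactly the property that matters
  (no anti-conservatism) while still catching a dropped `+1`, a wrong tail,
  or broken exchangeability.
- Problem sizes: the shipped benchmark uses 1500 genes, 15 tissues and 200
  evaluated associations, sizes chosen so the full acceptance pipeline —
  LOOCV over three network variants, per-tissue inference and all permutation
  nulls — completes in seconds while leaving every statistical contrast
  decisive (the planted AUC gap is ≈ 0.06 with Wilcoxon p < 1e−30).

## Known limitations

- mRNA presence thresholding is binary; no soft presence probability is
  propagated besides the single global `rw`.
- The prioritizer implements the symmetric-normalization propagation variant
  only; asymmetric random-walk-with-restart kernels are out of scope.
- `collapse_probes` assumes each probe maps to at most one gene.
- The k-fold partitioner does not stratify by disease family; with few
  families per fold the AUC spread can be optimistic.
- Interval construction requires the causal gene's chromosome to hold at
  least 100 other network genes; datasets with short chromosomes need a
  smaller `interval_size`.
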