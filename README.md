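# tsppi — tissue-specific PPI networks for disease-gene prioritization

Most network-based gene prioritizers score candidate disease genes on a single,
static ("generic") protein–protein interaction network, even though hereditary
diseases typically manifest in one or a few tissues whose active interactomes
differ dramatically. `tsppi` is a toolkit for systems biologists who want to
ask: *does tissue-specific expression information improve network-based
prioritization, and which tissues does a disease touch?*

The package provides:

- **Tissue-specific network construction** from binary expression presence
  calls (AD units ≥ τ, default τ = 200):
  - *Node Removal* (NR): delete unexpressed proteins and their edges;
  - *Edge Reweight* (ERW): keep the topology and set
    `w'(i,j) = w(i,j) · rw^n`, where `n ∈ {0,1,2}` counts unexpressed
    endpoints and `rw ∈ [0,1]` is the probability a below-threshold gene is
    expressed anyway (`rw = 0` ≡ NR, `rw = 1` ≡ generic).
- **Propagation-based prioritization** (the PRINCE scheme): a query disease
  induces a prior `Y(v) = L(sim(q, d*))` on genes with known associations
  (`d*` the most query-similar associated disease,
  `L(x) = 1/(1+exp(c·x+b))`, `c = −15`, `b = ln 9999`), which is smoothed by
  `F ← α·W′F + (1−α)·Y` for 10 iterations at `α = 0.9` over the
  degree-normalized network `w′(u,v) = w(u,v)/√(d(u)d(v))`.
- **A cross-validation benchmark**: leave-one-out over gene–disease
  associations, each causal gene competing against an artificial genomic
  interval of its 100 nearest network genes; pooled ROC/AUC, per-case rank
  comparison with an exact Wilcoxon signed-rank test, k-fold AUC error bars,
  and an `rw` sweep.
- **Disease–tissue inference**: run the prioritizer once per tissue network
  and rank tissues by the causal gene's relative rank (or absolute score);
  significance via a permutation null over expression-eligible tissues.
- **A synthetic-data generator** producing a complete input bundle (weighted
  scale-free network, AD-unit expression atlas, disease families with
  phenotypic similarity, per-disease tissue association scores, genomic gene
  order) with planted tissue-specific signal, including a *decoy benchmark*
  where tissue information is provably necessary for good ranking.

## Worked example

Generate a small planted decoy bundle and benchmark generic vs.
tissue-specific prioritization:

```bash
tsppi synth --preset decoy --seed 3 --out bundle --config small.yaml
tsppi benchmark --data bundle --variants generic,nr,erw:0.1 \
    --expressed-only --seed 5 --out bench
```

with `small.yaml` holding `{n_genes: 400, n_tissues: 6, n_diseases: 24,
family_size: 4, chromosome_size: 200, attachment_m: 2}`. This prints

```
generic: AUC=0.8825
nr: AUC=0.9847
erw:0.1: AUC=0.9838
```

i.e. on data where decoy genes near the causal gene attract propagation flow
but are not expressed in the disease's tissue, both tissue-specific network
constructions lift the pooled cross-validation AUC by ~0.1 over the generic
network; `bench/summary.tsv` additionally shows that all 24 held-out cases
were ranked better (0 ties, 0 worse; Wilcoxon p ≈ 1.2e−7). Tissue inference
on the same bundle:

```bash
tsppi infer-tissues --data bundle --n-perm 500 --seed 7 --out tissues
# assigned tissue ranked first in 100.0% of cases (p=0.002)
```

The disease's annotated tissue tops the per-tissue ranking for every disease,
far beyond the permutation null (p = 1/501, the smallest value 500
permutations can certify).

Other subcommands: `build-ts-nets` (emit NR/ERW networks in the sectioned
edge-list format), `net-stats` (per-tissue topology table with Pearson
correlations), `prince` (score all genes for one query disease),
`expressed-fraction` (fraction of causal genes expressed in their disease's
assigned tissue, with a 10,000-permutation null). Every run writes a
`manifest.json` with the seed, parameters, and SHA-256 digests of its inputs.

## Layout

- `src/tsppi/core.py` — domain types, validation, index conventions
- `src/tsppi/io.py` — sectioned edge-list and TSV readers/writers
- `src/tsppi/expression.py` — probe collapsing, presence calls, permutation tests
- `src/tsppi/networks.py` — NR/ERW construction, topology statistics
- `src/tsppi/propagation.py` — prior, normalization, smoothing, closed form
- `src/tsppi/evaluation.py` — LOOCV harness, ROC/AUC, Wilcoxon, rw sweep
- `src/tsppi/disease_tissue.py` — tissue ranking and permutation inference
- `src/tsppi/synthetic.py` — synthetic bundles and the planted decoy benchmark
- `src/tsppi/cli.py` — `tsppi` command-line entry point
- `docs/methods.md` — models, assumptions, parameter choices, limitations
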