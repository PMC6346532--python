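# snr

A headless Python engine for **contextual exploration of differential-expression
(DE) experiments**: load many DE result tables (your own and public ones), see
which experiments have similar significance profiles, filter and brush genes,
and score Gene Ontology terms against the current selection — all as plain
library calls and CLI commands, with no server or browser involved.

It is aimed at computational biologists who have stacks of RNA-seq DE tables
(one row per gene: `EnsemblID`, `foldChange`, `pValue`, `baseMean`, …) and want
reproducible, scriptable answers to questions like *"which public experiments
look like mine?"*, *"what do my significantly up-regulated genes do?"* and
*"does this related experiment regulate the same processes in the same
direction?"*.

## What it computes

- **Similarity overview.**  Experiments are embedded in 2-D by PCA of the
  experiments × genes matrix of p-values: gene columns are mean-centered (not
  scaled) and the top two principal-component scores are returned, using a
  seeded randomized SVD for large collections (exact SVD below 26×26).
  Missing (experiment, gene) cells are imputed with p = 1.  Experiments whose
  genes reach similar significance — including a comparison and the same
  comparison run in the opposite direction — land on the same spot.  The PCA
  can be re-run on any selected gene subset.
- **Selection engine.**  Cumulative filter clauses (`pValue < 0.005`,
  `foldChange > 0`, substring match on categorical columns) and rectangular
  brushes in transformed plot space, combined with AND semantics and linked
  to every experiment by gene-set intersection.
- **Plot models.**  Eight axis transforms (`linear … -log10, sqrt`), flat-top
  hexagonal binning with exact count conservation, the dots-below-5000 render
  rule, axis swapping, and a blue–white–red diverging color scale — as data
  structures any front-end can render (plus optional matplotlib output).
- **GO coverage scoring.**  Terms from a local annotation (TSV or GAF 2.x)
  containing selected genes, ranked by coverage = 100·|selection∩term|/|term|
  with term-size bounds, plus per-term "GO plot" models of gene fold changes.
- **Synthetic data.**  A seeded generator of DE collections with planted
  similarity clusters, null experiments, inverted-comparison twins and
  enriched GO terms, used by the whole test suite (`snr.synthgen`).

See `docs/methods.md` for the models, defaults and limitations.

## Worked example

```python
from snr import (assemble_pvalue_matrix, compute_overview,
                 nearest_experiments, scan_terms)
from snr.query import FilterClause, apply_filters
from snr.synthgen import SynthConfig, generate_collection, generate_go_annotation

cfg = SynthConfig(n_genes=1000, n_clusters=2, experiments_per_cluster=3,
                  n_null_experiments=1, n_terms=30, term_size_range=(8, 30), seed=1)
collection, truth = generate_collection(cfg)
annotation, truth = generate_go_annotation(cfg, truth)

coords = compute_overview(assemble_pvalue_matrix(collection), seed=1)
for i, eid in enumerate(coords.experiment_ids):
    print(f"{eid:13s} {coords.pc1[i]:7.3f} {coords.pc2[i]:7.3f}")
print(nearest_experiments(coords, "cluster0_rep0", k=3))

focus = collection["cluster0_rep0"]
sel = apply_filters(focus, [FilterClause("pValue", "lt", 0.005),
                            FilterClause("foldChange", "gt", 0)])
print(len(sel.selected), "genes selected of", focus.n_genes)
for s in scan_terms(annotation, sel, min_size=5)[:3]:
    print(s.term_id, s.term_size, s.n_selected, round(s.coverage_pct, 1))
```

prints

```
cluster0_rep0  -4.360  -1.334
cluster0_rep1  -5.623  -2.100
cluster0_rep2  -5.548  -0.151
cluster1_rep0   4.766  -2.153
cluster1_rep1   5.106  -0.470
cluster1_rep2   4.787  -2.869
null0           0.873   9.077
[('cluster0_rep1', 1.477), ('cluster0_rep2', 1.677), ('cluster1_rep0', 9.163)]
60 genes selected of 980
GO:S000006 9 8 88.9
GO:S000008 8 6 75.0
GO:S000002 28 14 50.0
```

The two planted clusters separate along PC1 (the null experiment drifts off on
PC2), the two replicates of the focus experiment are its nearest neighbors,
the p < 0.005 ∧ fold change > 0 filter recovers the up-regulated half of the
planted signature, and the top-ranked GO terms are the ones generated as
enriched in that cluster's signature (high coverage, small size first on
ties).

The same session as shell commands:

```sh
snr synth --out demo --seed 1
snr overview --collection demo --seed 1 --out coords.tsv
snr query cluster0_rep0 --collection demo \
    --where "pValue<0.005" --where "foldChange>0" --out ids.txt
snr go cluster0_rep0 --collection demo --annotation demo/go_annotation.tsv \
    --select ids.txt --min 5 --out terms.tsv
```

`snr run session.json` replays a recorded list of such steps
deterministically; `snr import`, `snr collection ls/focus` and `snr plot`
cover table registration, focus management and hex-bin model export.

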