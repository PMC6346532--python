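# Methods

`snr` is a headless engine for exploring collections of differential-expression
(DE) result tables: it computes an experiment-similarity overview, evaluates
cumulative filter/brush selections, builds hex-binned plot models, and scores
Gene Ontology terms against the current gene selection.  This note documents
the models, the numerical choices, and what the bundled synthetic-data
generator does and does not emulate.

## Input model

A DE table has one row per gene, keyed by an `EnsemblID` column, with numeric
statistics such as `foldChange` (log2 fold change), `pValue` and `baseMean`.
Column semantics are declared by a JSON *data dictionary*
(`docs/data_dictionary.schema.json`); the dictionary is authoritative and no
type inference is performed — a deliberate trade of convenience for
reproducibility.  Delimiters are auto-detected from the header (tab preferred,
comma fallback).  Missing values are `""`, `"NA"`, `"NaN"` (case-insensitive)
on input and `"NA"` on output; numeric output uses the shortest decimal
representation that round-trips the binary value, so the reader inverts the
writer exactly.  All validation errors are typed (`ValidationError`,
`ParseError`); malformed input never silently coerces.

## The p-value matrix and the similarity overview

The overview places experiments in a plane such that experiments whose genes
reach similar significance sit close together.  It is the PCA of the
experiments × genes matrix of raw p-values:

- **Gene universe = union with p = 1 imputation.**  Experiments need not share
  gene sets.  The universe is the union in first-seen order; a cell whose gene
  the experiment did not test — or tested with a missing p-value — is set to
  1.0 (maximally non-significant) and flagged in `imputed_mask`.  Union keeps
  all information; 1.0 is the conservative neutral value.
- **Raw p-values, mean-centered columns, no scaling.**  P-values already share
  the [0, 1] scale; unit-variance scaling would amplify near-constant genes.
  A `transform` hook on `assemble_pvalue_matrix` exists for experimentation
  (e.g. −log10) but defaults off.
- **Experiments are the observations.**  Scores for the top two components are
  returned together with per-component explained-variance fractions.
- **Randomized SVD** (scikit-learn's implementation; oversampling 10, two
  power iterations, seeded) is used when both dimensions exceed 25; otherwise
  an exact LAPACK SVD, which is also the independent oracle in the tests.
  Component signs follow a fixed convention — the largest-magnitude gene
  loading of each component is made positive — so coordinates are stable
  across runs, seeds and algorithms.
- Scores are computed by projecting the centered matrix onto the loadings,
  with identical rows deduplicated before the projection.  This guarantees a
  structural invariant: two experiments with identical p-value vectors — in
  particular a comparison and the same comparison run in the opposite
  direction, whose fold changes are negated but whose p-values are unchanged —
  receive bit-identical coordinates.

**Accuracy of the randomized path.**  When the (centered) matrix rank fits
inside the randomized sketch (components + oversampling = 12), the randomized
decomposition recovers the exact subspace to machine precision, and the test
suite verifies ≤ 1e-6 agreement with the exact oracle on random matrices of
rank ≤ 8 up to 50 × 5000.  On full-rank matrices with near-degenerate leading
singular values the fixed 2 power iterations leave the components free to
rotate within the leading subspace, and per-component scores can differ
substantially from the exact decomposition even though the projected geometry
is similar.  This is an inherent property of sketch-based SVD at fixed budget,
not an implementation defect; collections whose leading components are
well-separated (the regime the overview is useful in) are unaffected in
practice.

Restricting the overview to a selected gene subset is literally
`compute_overview(assemble_pvalue_matrix(collection, selection))`; nothing else
changes, so the subset view is exactly reproducible from its inputs.

## Selection engine

Selections are an ordered chain of clauses combined with AND; order never
matters and each added clause can only shrink the selection.

- Numeric `<` and `>` are strict; numeric `=` is exact equality (no
  tolerance — predictable, and users can bracket with `<`/`>`).
- Categorical `=` is case-insensitive substring containment, mirroring
  spreadsheet "find" behavior.
- A gene with a missing value on a clause's dimension fails that clause under
  every operator.
- Brush rectangles live in *transformed* plot space and are closed intervals
  (boundary points are selected).  Genes outside a transform's domain are
  never brush-selectable.

The selected set is linked to other experiments by plain intersection with
their gene universes; a single hovered gene can additionally be highlighted
and propagates to every view that contains it.

## Plot models

Eight axis transforms are supported: `linear, -linear, log2, -log2, log10,
-log10, sqrt, -sqrt`; the `-` variants negate their base transform.  Values
outside a transform's domain (p = 0 under `-log10`, negatives under `sqrt`)
are dropped from the plot, not clipped — volcano plots with underflowed p = 0
rows lose those rows from the y-axis, loudly documented here because it is the
most common surprise.

Hex binning uses a flat-top hexagonal lattice anchored at the data minimum,
default radius = x-range/30 (≈30 columns); every point is assigned to its
nearest center, distance ties broken toward the smaller (column, row) index,
and empty hexes are omitted.  Counts therefore always sum to the number of
in-domain points.  Views render individual dots when the gene count is
strictly below 5 000 (a named config constant), when a selection is active in
any view, or when the user forces dots; otherwise they render hex bins.
Switching modes never changes the selection.

The diverging color scale is piecewise-linear blue (0,0,255) → white
(255,255,255) → red (255,0,0) with inputs clamped to the limits; default
limits for fold-change coloring are symmetric about 0 at the maximum |value|
displayed, so 0 (no regulation) is always white.

Small multiples of context experiments copy the focus view's axes, transforms
and full ranges, never zoom into a selection, and highlight the selected genes
they contain.

## GO term scoring

A local annotation table (flat TSV or GAF 2.x; memberships only, qualifiers
ignored) maps terms to gene sets.  Terms containing at least one selected
gene are scored by coverage = 100·|selection ∩ term|/|term| and sorted by
coverage descending, ties by term size ascending then term id — a total
order.  The denominator is the *term* size: this is what makes the metric
provably favor small terms (for nested terms with equal intersections the
smaller one never scores lower), which is why min/max term-size bounds are
exposed (defaults: 1 and unbounded).  No enrichment p-value is computed;
coverage ranking is the method, and a hypergeometric test is left as an
extension hook.  GO plot models list one (gene, value, color) entry per
selected gene of the term (or all genes on request), ordered by value
descending with unmeasured genes last in grey; widths are proportional to
entry counts relative to the widest term in the displayed list.

## Synthetic data generator

The generator emulates, at the DE-table level, the one statistical assumption
the engine relies on: related experiments share small p-values on the same
genes.  Per cluster a disjoint signature gene set (default 10% of genes — a
typical DE fraction) receives a fixed per-gene sign; the model is a calibrated
small-replicate DE test with `pseudo_n` = 6 effective replicates and
per-replicate noise `noise_sd`:

    fc_observed ~ Normal(sign·effect_size or 0,  noise_sd/√pseudo_n)
    p = 2·Φ(−|fc_observed|/noise_sd·√pseudo_n)

Under the null the statistic is standard normal, so non-regulated genes — and
every gene of a null experiment — get exactly uniform p-values, as a
well-calibrated test on real data produces.  Defaults are 3 clusters × 5
experiments + 3 null experiments over 2 000 genes, effect size 1.0 (mean
|log2 fold change| of signature genes), noise SD 0.5.  baseMean is log-normal
(median e³ ≈ 20 counts, σ = 1.5 on the log scale); each experiment drops a
random 2% of genes so the union/imputation paths are exercised.  GO terms are
generated with matching structure: 30% of terms are *enriched* (≥ 90% of
their genes drawn from one cluster's signature, round-robin over clusters),
the rest sample genes uniformly; term sizes are uniform over the configured
range.  Everything derives from one integer seed; identical seeds give
byte-identical artifacts.  Planted truth (cluster labels, signatures,
enriched terms) is returned alongside so tests never re-derive ground truth.

What the generator does **not** emulate: count-level noise and
mean–variance coupling, correlated gene modules outside the planted
signatures, batch effects, p-value inflation from misspecified DE models, or
realistic GO term overlap/hierarchy.  Passing tests therefore demonstrate the
engine's correctness and the recoverability of planted structure under clean
conditions, not robustness to every pathology of real data.

## Problem sizes used in the checks

The bundled verification script (`scripts/acceptance.py`) and test suite use
sizes chosen to exercise every code path while staying fast on one CPU: 200
random matrices up to 50 × 5000 for the PCA oracle, 20 independent seeds of
the default 18-experiment/2000-gene collection for cluster recovery and GO
enrichment recovery, 200 random filter instances, and 100 random point sets /
annotations for the hex-bin and GO-scan oracles.

## Known limitations

- The overview is strictly two-dimensional; structure beyond the second
  component (e.g. many equidistant clusters) is invisible in it.
- Raw p-values compress all significance below ~0.01 into a thin slice of the
  [0, 1] scale; the `transform` hook exists precisely to experiment with
  −log10 inputs, but the default follows the plain p-value definition.
- Numeric `=` at full floating-point precision rarely matches values typed by
  hand; this is intentional (see above).
- GAF parsing keeps only gene↔term pairs; OBO ontology structure (term
  parentage) is out of scope, so coverage is computed per annotated term with
  no propagation to ancestors.
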