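"""Local GO annotation store, coverage scanning, and GO-plot models.

The annotation is a local table of (term, gene) memberships — a stand-in for a
cached Biomart/GO download, so nothing is ever fetched over the network.  When
genes are selected in any view, every term containing at least one selected
gene is scored by *coverage*:

    coverage_pct = 100 · |selection ∩ term| / |term|

and the list is sorted by coverage descending.  This metric deliberately
favors small terms — a 5-gene term fully covered beats a 500-gene term with
50 selected genes — which is why the scan takes min/max term-size bounds to
keep the list informative.  No enrichment p-value is computed; coverage
ranking is the method.  (A hypergeometric test would be a natural extension
hook; it is intentionally not part of the scan.)

Each term can be rendered as a *GO plot*: one small rectangle per gene,
colored by a numeric dimension (usually fold change) on a blue–white–red
diverging scale, ordered by value.  Plot width is proportional to the number
of genes shown, relative to the widest term in the returned list.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .errors import ParseError, ValidationError
from .io import Experiment
from .plotmodel import diverging_color
from .query import SelectionState

#: color for genes in a term but absent from (or unmeasured in) the experiment
MISSING_COLOR = (180, 180, 180)

GO_URL_PREFIX = "http://amigo.geneontology.org/amigo/term/"


@dataclass(frozen=True)
class GoTerm:
    id: str
    name: str
    definition: str
    genes: frozenset

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValidationError(f"term {self.id!r} has an empty gene set")

    @property
    def url(self) -> str:
        return GO_URL_PREFIX + self.id


@dataclass(frozen=True)
class GoAnnotation:
    """term_id → term plus the exact inverse gene → term_ids index."""

    terms: Mapping[str, GoTerm]
    gene_index: Mapping[str, frozenset]

    def terms_of(self, gene: str) -> frozenset:
        return self.gene_index.get(gene, frozenset())


@dataclass(frozen=True)
class GoTermScore:
    term_id: str
    term_size: int
    n_selected: int
    coverage_pct: float

    def __post_init__(self) -> None:
        if not (0 < self.n_selected <= self.term_size):
            raise ValidationError("n_selected must lie in (0, term_size]")


@dataclass(frozen=True)
class GoPlotModel:
    """Renderable model of one term: (gene, value, color) entries plus width."""

    term_id: str
    entries: tuple  # of (gene_id, value | None, (r, g, b))
    width_units: int
    width_fraction: float


def _build(pairs: Iterable[tuple[str, str, str, str]]) -> GoAnnotation:
    members: dict[str, set] = {}
    meta: dict[str, tuple[str, str]] = {}
    for term_id, name, definition, gene in pairs:
        members.setdefault(term_id, set()).add(gene)
        if term_id not in meta or (name or definition):
            meta[term_id] = (name, definition)
    terms = {
        tid: GoTerm(tid, meta[tid][0], meta[tid][1], frozenset(genes))
        for tid, genes in members.items()
    }
    index: dict[str, set] = {}
    for tid, term in terms.items():
        for g in term.genes:
            index.setdefault(g, set()).add(tid)
    return GoAnnotation(terms, {g: frozenset(t) for g, t in index.items()})


def load_go_annotation(path) -> GoAnnotation:
    """Load term↔gene memberships from a flat TSV or a GAF 2.x file.

    The flat format has a header row with ``term_id``, ``term_name``,
    ``term_definition`` and ``gene_id`` columns.  GAF input (detected by the
    ``!gaf-version`` comment header) uses column 2 as the gene ID and column 5
    as the GO term; qualifiers and evidence codes are ignored.  Duplicate
    (term, gene) pairs collapse to a single membership.
    """
    with open(path, "r", encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise ParseError(f"{path}: empty annotation file")
    if lines[0].startswith("!"):
        return _load_gaf(lines, path)
    header = lines[0].split("\t")
    required = ["term_id", "term_name", "term_definition", "gene_id"]
    missing = [c for c in required if c not in header]
    if missing:
        raise ParseError(f"{path}: header lacks column(s) {missing}")
    col = {c: header.index(c) for c in required}
    pairs = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        cells = line.split("\t")
        if len(cells) < len(header):
            raise ParseError(f"{path}: line {lineno}: expected {len(header)} columns")
        pairs.append(
            (
                cells[col["term_id"]],
                cells[col["term_name"]],
                cells[col["term_definition"]],
                cells[col["gene_id"]],
            )
        )
    if not pairs:
        raise ParseError(f"{path}: no annotation rows")
    return _build(pairs)


def _load_gaf(lines: list[str], path) -> GoAnnotation:
    pairs = []
    for lineno, line in enumerate(lines, start=1):
        if not line.strip() or line.startswith("!"):
            continue
        cells = line.split("\t")
        if len(cells) < 5:
            raise ParseError(f"{path}: line {lineno}: GAF row has fewer than 5 columns")
        pairs.append((cells[4], "", "", cells[1]))
    if not pairs:
        raise ParseError(f"{path}: no annotation rows")
    return _build(pairs)


def write_go_annotation(annotation: GoAnnotation, path) -> None:
    """Write the flat TSV format (deterministic row order)."""
    lines = ["term_id\tterm_name\tterm_definition\tgene_id"]
    for tid in sorted(annotation.terms):
        term = annotation.terms[tid]
        for g in sorted(term.genes):
            lines.append(f"{tid}\t{term.name}\t{term.definition}\t{g}")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")


def scan_terms(
    annotation: GoAnnotation,
    selection,
    min_size: int = 1,
    max_size: int | None = None,
) -> list[GoTermScore]:
    """Score every term containing selected genes by coverage percentage.

    Terms outside [min_size, max_size] are excluded.  Sorted by coverage
    descending, ties by term size ascending then term id — a total,
    deterministic order.  Accepts a :class:`SelectionState` or an iterable of
    gene IDs; an empty selection is an error.
    """
    sel = selection.selected if isinstance(selection, SelectionState) else frozenset(selection)
    if not sel:
        raise ValidationError("empty selection")
    if min_size < 1:
        raise ValidationError("min_size must be >= 1")
    if max_size is not None and max_size < min_size:
        raise ValidationError("max_size must be >= min_size")
    candidates = set()
    for g in sel:
        candidates |= annotation.terms_of(g)
    scores = []
    for tid in candidates:
        term = annotation.terms[tid]
        size = len(term.genes)
        if size < min_size or (max_size is not None and size > max_size):
            continue
        n_sel = len(sel & term.genes)
        scores.append(GoTermScore(tid, size, n_sel, 100.0 * n_sel / size))
    scores.sort(key=lambda s: (-s.coverage_pct, s.term_size, s.term_id))
    return scores


def _entry_values(
    term: GoTerm,
    experiment: Experiment,
    sel: frozenset,
    color_dim: str,
    all_genes: bool,
) -> list[tuple[str, float | None]]:
    shown = term.genes if all_genes else (term.genes & sel)
    value_of = dict(zip(experiment.genes, experiment.numeric_values(color_dim).tolist()))
    out: list[tuple[str, float | None]] = []
    for g in shown:
        v = value_of.get(g)
        out.append((g, None if v is None or math.isnan(v) else float(v)))
    # value descending, genes without a value last; gene id breaks ties
    out.sort(key=lambda t: (t[1] is None, -(t[1] if t[1] is not None else 0.0), t[0]))
    return out


def default_color_limits(values: Iterable[float | None]) -> tuple[float, float, float]:
    """Symmetric limits about 0 from the largest |value| shown (fold-change style)."""
    vmax = max((abs(v) for v in values if v is not None), default=1.0)
    if vmax == 0.0:
        vmax = 1.0
    return (-vmax, 0.0, vmax)


def go_plot_data(
    annotation: GoAnnotation,
    term_id: str,
    experiment: Experiment,
    selection,
    color_dim: str = "foldChange",
    limits: tuple[float, float, float] | None = None,
    all_genes: bool = False,
    max_width_units: int | None = None,
) -> GoPlotModel:
    """Build the GO-plot model for one term against one experiment.

    Entries are the selected genes of the term (or all its genes with
    ``all_genes``), ordered by ``color_dim`` value descending and colored on
    the diverging scale.  Genes the experiment does not measure get
    :data:`MISSING_COLOR` and no value.  ``limits`` defaults to a symmetric
    range about 0 from the displayed values; ``max_width_units`` (from the
    widest term of a scan) sets the relative width.
    """
    if term_id not in annotation.terms:
        raise ValidationError(f"unknown GO term {term_id!r}")
    sel = selection.selected if isinstance(selection, SelectionState) else frozenset(selection)
    term = annotation.terms[term_id]
    entries = _entry_values(term, experiment, sel, color_dim, all_genes)
    if limits is None:
        limits = default_color_limits(v for _, v in entries)
    low, mid, high = limits
    colored = tuple(
        (g, v, MISSING_COLOR if v is None else diverging_color(v, low, mid, high))
        for g, v in entries
    )
    width = len(colored)
    denom = max_width_units if max_width_units else width
    fraction = (width / denom) if denom else 0.0
    return GoPlotModel(term_id, colored, width, fraction)


def go_plot_models(
    annotation: GoAnnotation,
    term_ids: Sequence[str],
    experiment: Experiment,
    selection,
    color_dim: str = "foldChange",
    limits: tuple[float, float, float] | None = None,
    all_genes: bool = False,
) -> list[GoPlotModel]:
    """GO plots for a list of terms with widths relative to the widest one."""
    models = [
        go_plot_data(
            annotation, tid, experiment, selection, color_dim, limits, all_genes
        )
        for tid in term_ids
    ]
    max_w = max((m.width_units for m in models), default=0)
    if max_w:
        models = [
            GoPlotModel(m.term_id, m.entries, m.width_units, m.width_units / max_w)
            for m in models
        ]
    return models
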