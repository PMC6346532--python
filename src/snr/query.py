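"""The filter / brush / link engine.

Selections are built from an ordered chain of clauses — table filters
(``dim < | > | = value``) and rectangular brushes in transformed plot space —
combined with AND semantics: a gene is selected iff it satisfies every clause.
The chain is order-independent by construction, and adding a clause can only
shrink the selection.

Rules the whole engine (and its test oracle) follows:

* numeric ``<``/``>`` are strict; numeric ``=`` is exact equality;
* ``=`` on a categorical dimension is case-insensitive substring containment
  (spreadsheet-style "find");
* a gene with a missing value on a clause's dimension fails that clause, for
  every operator;
* brush rectangles are closed intervals in transformed space (boundary points
  are selected); genes outside a transform's domain are never selected by a
  brush.

The resulting selection is *linked* to every other view: context experiments
highlight the selected genes they contain, and a single hovered gene can be
highlighted on top of the selection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence, Union

import numpy as np

from .errors import ValidationError
from .io import Experiment
from .plotmodel import ViewState, transform_values

_OPS = ("lt", "gt", "eq")
_OP_SYMBOL = {"<": "lt", ">": "gt", "=": "eq"}


@dataclass(frozen=True)
class FilterClause:
    """One table-header filter: ``dimension (< | > | =) operand``."""

    dimension: str
    op: str
    operand: object

    def __post_init__(self) -> None:
        if self.op not in _OPS:
            raise ValidationError(f"unknown operator {self.op!r}; expected lt|gt|eq")


@dataclass(frozen=True)
class BrushRect:
    """A rectangular brush in transformed plot space (closed intervals)."""

    x_dim: str
    y_dim: str
    transform_x: str
    transform_y: str
    x_range: tuple[float, float]
    y_range: tuple[float, float]

    def __post_init__(self) -> None:
        for lo, hi in (self.x_range, self.y_range):
            if not (math.isfinite(lo) and math.isfinite(hi)):
                raise ValidationError("brush ranges must be finite")
            if lo > hi:
                raise ValidationError("brush range min must not exceed max")


Clause = Union[FilterClause, BrushRect]


@dataclass(frozen=True)
class SelectionState:
    """A clause chain, the gene IDs it selects, and an optional highlight.

    ``selected`` is always a subset of the focus experiment's genes
    (``universe``) and always equals the exact evaluation of the chain.
    """

    clauses: tuple[Clause, ...]
    selected: frozenset
    universe: frozenset
    highlighted: str | None = None

    def __post_init__(self) -> None:
        if not self.selected <= self.universe:
            raise ValidationError("selected genes must belong to the focus experiment")

    @property
    def active(self) -> bool:
        """True when any clause restricts the view (drives dot rendering)."""
        return bool(self.clauses)


def _numeric_operand(clause: FilterClause) -> float:
    try:
        return float(clause.operand)  # type: ignore[arg-type]
    except (TypeError, ValueError):
        raise ValidationError(
            f"clause on numeric dimension {clause.dimension!r}: operand "
            f"{clause.operand!r} is not a number"
        ) from None


def _clause_mask(experiment: Experiment, clause: Clause) -> np.ndarray:
    if isinstance(clause, BrushRect):
        names = experiment.dictionary.names
        for d in (clause.x_dim, clause.y_dim):
            if d not in names:
                raise ValidationError(f"unknown dimension {d!r}")
        tx, mx = transform_values(
            experiment.numeric_values(clause.x_dim), clause.transform_x
        )
        ty, my = transform_values(
            experiment.numeric_values(clause.y_dim), clause.transform_y
        )
        mask = mx & my
        (xl, xh), (yl, yh) = clause.x_range, clause.y_range
        inside = np.zeros(len(tx), dtype=bool)
        inside[mask] = (
            (tx[mask] >= xl) & (tx[mask] <= xh) & (ty[mask] >= yl) & (ty[mask] <= yh)
        )
        return inside

    kind = experiment.dictionary.kind_of(clause.dimension)
    if kind == "numeric":
        x = experiment.numeric_values(clause.dimension)
        v = _numeric_operand(clause)
        valid = ~np.isnan(x)
        if clause.op == "lt":
            return valid & (x < v)
        if clause.op == "gt":
            return valid & (x > v)
        return valid & (x == v)
    # categorical / identifier: only "=", as case-insensitive substring match
    if clause.op != "eq":
        raise ValidationError(
            f"dimension {clause.dimension!r} is {kind}; only '=' applies"
        )
    needle = str(clause.operand).lower()
    col = experiment.data[clause.dimension]
    out = np.zeros(len(col), dtype=bool)
    for i, cell in enumerate(col):
        if cell is None or (isinstance(cell, float) and math.isnan(cell)):
            continue  # missing fails every clause
        out[i] = needle in str(cell).lower()
    return out


def evaluate_chain(experiment: Experiment, clauses: Sequence[Clause]) -> frozenset:
    """Gene IDs of ``experiment`` satisfying every clause (AND semantics)."""
    mask = np.ones(experiment.n_genes, dtype=bool)
    for clause in clauses:
        mask &= _clause_mask(experiment, clause)
    genes = np.asarray(experiment.genes, dtype=object)
    return frozenset(genes[mask].tolist())


def apply_filters(
    experiment: Experiment, clauses: Sequence[Clause]
) -> SelectionState:
    """Evaluate a clause chain against the focus experiment.

    An empty chain selects every gene.  The result is independent of clause
    order.
    """
    chain = tuple(clauses)
    return SelectionState(
        clauses=chain,
        selected=evaluate_chain(experiment, chain),
        universe=frozenset(experiment.genes),
    )


def apply_brush(
    experiment: Experiment,
    view_state: ViewState,
    rect: BrushRect,
    zoom: bool = True,
    state: SelectionState | None = None,
) -> tuple[SelectionState, ViewState]:
    """Brush a rectangle in the current view; optionally zoom into it.

    The rectangle's axes and transforms must match the view's.  The brush is
    appended to any existing clause chain.  With ``zoom`` (the main plot's
    default) the returned view's ranges shrink to the rectangle; in
    small-multiples mode (``zoom=False``, or a view with zooming disabled)
    only the selection changes.
    """
    if (rect.x_dim, rect.y_dim) != (view_state.x_dim, view_state.y_dim):
        raise ValidationError(
            f"brush axes ({rect.x_dim!r}, {rect.y_dim!r}) do not match the view "
            f"({view_state.x_dim!r}, {view_state.y_dim!r})"
        )
    if (rect.transform_x, rect.transform_y) != (
        view_state.transform_x,
        view_state.transform_y,
    ):
        raise ValidationError("brush transforms do not match the view")
    prior = state.clauses if state is not None else ()
    chain = prior + (rect,)
    selection = SelectionState(
        clauses=chain,
        selected=evaluate_chain(experiment, chain),
        universe=frozenset(experiment.genes),
        highlighted=state.highlighted if state is not None else None,
    )
    view = view_state.copy()
    if zoom and view_state.zoom_enabled:
        view.x_range = rect.x_range
        view.y_range = rect.y_range
    return selection, view


def link_selection(selection, other_experiment: Experiment) -> frozenset:
    """Project a selection onto another experiment's gene universe.

    Genes the other experiment lacks are silently dropped.  Accepts a
    :class:`SelectionState` or any iterable of gene IDs.
    """
    sel = selection.selected if isinstance(selection, SelectionState) else frozenset(selection)
    return sel & frozenset(other_experiment.genes)


def highlight_gene(
    selection: SelectionState, gene_id: str | None
) -> SelectionState:
    """Set (or with ``None`` clear) the hovered-gene highlight.

    The selection itself is unchanged; the highlight rides along to all linked
    views that contain the gene.
    """
    if gene_id is not None and gene_id not in selection.universe:
        raise ValidationError(f"unknown gene {gene_id!r}")
    return replace(selection, highlighted=gene_id)


def highlight_in(selection: SelectionState, other_experiment: Experiment) -> str | None:
    """The highlighted gene as seen by a context experiment (None if absent)."""
    g = selection.highlighted
    if g is not None and g in set(other_experiment.genes):
        return g
    return None


# ---------------------------------------------------------------------------
# clause mini-grammar for the CLI: dim(<|>|=)value


def parse_clause(text: str, experiment: Experiment) -> FilterClause:
    """Parse ``"pValue<0.005"``-style clause strings.

    The first ``<``, ``>`` or ``=`` splits dimension from operand; surrounding
    whitespace is stripped.  Numeric operands are parsed per the dimension's
    declared kind.
    """
    for sym in "<>=":
        i = text.find(sym)
        if i > 0:
            dim = text[:i].strip()
            operand_text = text[i + 1:].strip()
            op = _OP_SYMBOL[sym]
            kind = experiment.dictionary.kind_of(dim)  # raises on unknown dim
            operand: object = operand_text
            if kind == "numeric":
                try:
                    operand = float(operand_text)
                except ValueError:
                    raise ValidationError(
                        f"clause {text!r}: {operand_text!r} is not numeric"
                    ) from None
            return FilterClause(dim, op, operand)
    raise ValidationError(f"cannot parse clause {text!r}; expected dim(<|>|=)value")
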