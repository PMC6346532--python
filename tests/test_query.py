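"""Filter/brush/link engine against brute-force row-scan oracles."""

import math

import numpy as np
import pytest

from snr.errors import ValidationError
from snr.plotmodel import ViewState
from snr.query import (
    BrushRect,
    FilterClause,
    apply_brush,
    apply_filters,
    evaluate_chain,
    highlight_gene,
    highlight_in,
    link_selection,
    parse_clause,
)

from conftest import make_experiment, random_experiment


# ---------------------------------------------------------------------------
# oracle: per-gene linear scan, written independently of the engine


def scan_oracle(experiment, clauses):
    """Evaluate the clause chain gene by gene with plain Python."""
    selected = set()
    for i, gene in enumerate(experiment.genes):
        ok = True
        for c in clauses:
            if isinstance(c, BrushRect):
                ok = ok and _in_rect(experiment, i, c)
            else:
                ok = ok and _passes(experiment, i, c)
            if not ok:
                break
        if ok:
            selected.add(gene)
    return selected


def _passes(experiment, i, clause):
    kind = experiment.dictionary.kind_of(clause.dimension)
    cell = experiment.data[clause.dimension].iloc[i]
    if kind == "numeric":
        v = float(cell)
        if math.isnan(v):
            return False  # missing fails every clause
        x = float(clause.operand)
        return {"lt": v < x, "gt": v > x, "eq": v == x}[clause.op]
    if not isinstance(cell, str):
        return False
    return str(clause.operand).lower() in cell.lower()


def _in_rect(experiment, i, rect):
    def t(name, value):
        if name == "linear":
            return value, True
        if name == "-linear":
            return -value, True
        neg = name.startswith("-")
        base = name[1:] if neg else name
        if base in ("log2", "log10") and value <= 0:
            return None, False
        if base == "sqrt" and value < 0:
            return None, False
        out = {"log2": math.log2, "log10": math.log10, "sqrt": math.sqrt}[base](value)
        return (-out if neg else out), True

    xv = float(experiment.data[rect.x_dim].iloc[i])
    yv = float(experiment.data[rect.y_dim].iloc[i])
    if math.isnan(xv) or math.isnan(yv):
        return False
    tx, okx = t(rect.transform_x, xv)
    ty, oky = t(rect.transform_y, yv)
    if not (okx and oky):
        return False
    return rect.x_range[0] <= tx <= rect.x_range[1] and rect.y_range[0] <= ty <= rect.y_range[1]


def random_clause(rng, experiment):
    dim = rng.choice(["pValue", "foldChange", "baseMean", "geneName"])
    if dim == "geneName":
        return FilterClause(dim, "eq", rng.choice(["g1", "G2", "g", "nope"]))
    op = rng.choice(["lt", "gt", "eq"])
    col = experiment.numeric_values(dim)
    finite = col[~np.isnan(col)]
    if op == "eq" and len(finite) and rng.random() < 0.5:
        operand = float(rng.choice(finite))  # force exact hits sometimes
    else:
        operand = float(rng.normal(0, 1))
    return FilterClause(dim, op, operand)


# ---------------------------------------------------------------------------
# table filters


def test_pvalue_threshold_is_strict():
    """The '<' operator excludes the boundary: p < 0.005 keeps only smaller rows."""
    exp = make_experiment("f", ["G1", "G2", "G3", "G4"], pValue=[0.001, 0.004, 0.005, 0.5])
    state = apply_filters(exp, [FilterClause("pValue", "lt", 0.005)])
    assert state.selected == {"G1", "G2"}


def test_empty_chain_selects_everything():
    exp = make_experiment("f", ["G1", "G2"])
    state = apply_filters(exp, [])
    assert state.selected == {"G1", "G2"}
    assert not state.active


def test_random_chains_match_linear_scan_oracle():
    rng = np.random.default_rng(99)
    for trial in range(200):
        exp = random_experiment(rng, f"t{trial}", n=60, missing_frac=0.2)
        clauses = [random_clause(rng, exp) for _ in range(rng.integers(1, 5))]
        assert apply_filters(exp, clauses).selected == scan_oracle(exp, clauses)


def test_missing_value_fails_every_operator():
    exp = make_experiment("f", ["G1", "G2"], pValue=[np.nan, 0.5])
    for op, operand in (("lt", 1.0), ("gt", -1.0), ("eq", float("nan"))):
        state = apply_filters(exp, [FilterClause("pValue", op, operand)])
        assert "G1" not in state.selected


def test_categorical_eq_is_substring_case_insensitive():
    exp = make_experiment("f", ["G1", "G2", "G3"], geneName=["Soat1", "soat2", "Abc"])
    state = apply_filters(exp, [FilterClause("geneName", "eq", "SOAT")])
    assert state.selected == {"G1", "G2"}


def test_clause_order_irrelevant_and_monotone():
    rng = np.random.default_rng(7)
    exp = random_experiment(rng, "m", n=80)
    clauses = [random_clause(rng, exp) for _ in range(3)]
    base = apply_filters(exp, clauses).selected
    assert apply_filters(exp, clauses[::-1]).selected == base
    # adding a clause never enlarges the selection
    assert base <= apply_filters(exp, clauses[:2]).selected


def test_filter_errors():
    exp = make_experiment("f", ["G1"])
    with pytest.raises(ValidationError, match="nope"):
        apply_filters(exp, [FilterClause("nope", "lt", 1)])
    with pytest.raises(ValidationError, match="'='"):
        apply_filters(exp, [FilterClause("geneName", "lt", "x")])


# ---------------------------------------------------------------------------
# brushes


def _view(exp, tx="linear", ty="-log10"):
    return ViewState(
        x_dim="foldChange", y_dim="pValue", transform_x=tx, transform_y=ty,
        numeric_dims=frozenset(exp.dictionary.numeric_names),
    )


def _rect(view, x_range, y_range):
    return BrushRect(view.x_dim, view.y_dim, view.transform_x, view.transform_y,
                     x_range, y_range)


def test_rect_covering_everything_selects_all_in_domain():
    exp = make_experiment(
        "b", ["G1", "G2", "G3"], foldChange=[1.0, -1.0, 0.5], pValue=[0.1, 0.01, 0.0]
    )
    view = _view(exp)
    sel, _ = apply_brush(exp, view, _rect(view, (-10, 10), (-10, 10)), zoom=False)
    # G3 has p = 0: outside the -log10 domain, never selectable
    assert sel.selected == {"G1", "G2"}


def test_rect_in_empty_region_selects_nothing():
    exp = make_experiment("b", ["G1"], foldChange=[0.0], pValue=[0.5])
    view = _view(exp)
    sel, _ = apply_brush(exp, view, _rect(view, (100, 101), (100, 101)), zoom=False)
    assert sel.selected == set()


def test_brush_boundary_is_inclusive():
    exp = make_experiment("b", ["G1"], foldChange=[2.0], pValue=[0.01])
    view = _view(exp)
    sel, _ = apply_brush(exp, view, _rect(view, (2.0, 3.0), (2.0, 2.0)), zoom=False)
    assert sel.selected == {"G1"}  # (-log10(0.01), fc) sits exactly on the corner


def test_random_rects_match_containment_oracle():
    rng = np.random.default_rng(55)
    exp = random_experiment(rng, "b", n=500, missing_frac=0.1)
    view = _view(exp)
    for _ in range(30):
        lo = sorted(rng.normal(0, 1, 2))
        hi = sorted(rng.uniform(0, 3, 2))
        rect = _rect(view, tuple(lo), tuple(hi))
        sel, _ = apply_brush(exp, view, rect, zoom=False)
        assert sel.selected == scan_oracle(exp, [rect])


def test_zoom_shrinks_view_only_when_enabled():
    exp = make_experiment("b", ["G1"], foldChange=[0.0], pValue=[0.5])
    view = _view(exp)
    rect = _rect(view, (-1.0, 1.0), (0.0, 2.0))
    _, zoomed = apply_brush(exp, view, rect, zoom=True)
    assert zoomed.x_range == (-1.0, 1.0) and zoomed.y_range == (0.0, 2.0)
    _, unzoomed = apply_brush(exp, view, rect, zoom=False)
    assert unzoomed.x_range is None
    small = view.copy()
    small.zoom_enabled = False  # small-multiples never zoom
    _, still = apply_brush(exp, small, rect, zoom=True)
    assert still.x_range is None


def test_brush_axes_must_match_view():
    exp = make_experiment("b", ["G1"])
    view = _view(exp)
    bad = BrushRect("baseMean", "pValue", "linear", "-log10", (0, 1), (0, 1))
    with pytest.raises(ValidationError, match="axes"):
        apply_brush(exp, view, bad)


def test_filter_then_brush_equals_brush_then_filter():
    rng = np.random.default_rng(77)
    exp = random_experiment(rng, "c", n=200, missing_frac=0.1)
    view = _view(exp, ty="linear")
    rect = _rect(view, (-0.5, 1.5), (0.1, 0.8))
    clause = FilterClause("baseMean", "gt", 5.0)
    a = evaluate_chain(exp, [clause, rect])
    b = evaluate_chain(exp, [rect, clause])
    assert a == b == scan_oracle(exp, [clause, rect])


# ---------------------------------------------------------------------------
# linking and highlighting


def test_link_selection_is_set_intersection():
    rng = np.random.default_rng(13)
    focus = random_experiment(rng, "F", n=60, missing_frac=0)
    other = random_experiment(rng, "O", n=60, missing_frac=0)
    state = apply_filters(focus, [])
    assert link_selection(state, focus) == state.selected
    assert link_selection(state, other) == state.selected & set(other.genes)
    none_shared = make_experiment("N", ["ZZZ1", "ZZZ2"])
    assert link_selection(state, none_shared) == set()


def test_highlight_set_and_clear_roundtrip():
    exp = make_experiment("h", ["G1", "G2"])
    state = apply_filters(exp, [])
    lit = highlight_gene(state, "G1")
    assert lit.highlighted == "G1" and lit.selected == state.selected
    assert highlight_gene(lit, None) == state


def test_highlight_propagates_by_membership():
    exp = make_experiment("h", ["G1", "G2"])
    state = highlight_gene(apply_filters(exp, []), "G1")
    has = make_experiment("c1", ["G1", "G9"])
    lacks = make_experiment("c2", ["G8", "G9"])
    assert highlight_in(state, has) == "G1"
    assert highlight_in(state, lacks) is None


def test_highlight_unknown_gene_errors():
    exp = make_experiment("h", ["G1"])
    with pytest.raises(ValidationError, match="G9"):
        highlight_gene(apply_filters(exp, []), "G9")


# ---------------------------------------------------------------------------
# clause grammar


@pytest.mark.parametrize(
    "text, expected",
    [
        ("pValue<0.005", FilterClause("pValue", "lt", 0.005)),
        ("foldChange > 0", FilterClause("foldChange", "gt", 0.0)),
        ("geneName=soat", FilterClause("geneName", "eq", "soat")),
    ],
)
def test_parse_clause_grammar(text, expected):
    exp = make_experiment("p", ["G1"])
    assert parse_clause(text, exp) == expected


def test_parse_clause_rejects_garbage():
    exp = make_experiment("p", ["G1"])
    with pytest.raises(ValidationError):
        parse_clause("pValue", exp)
    with pytest.raises(ValidationError, match="not numeric"):
        parse_clause("pValue<abc", exp)
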