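"""Plot-space models: axis transforms, hex binning, render-mode rule, colors.

These are the *data* models behind the scatter/hex views — bin centers, counts
and gene assignments — not pixels.  A front-end (or the optional matplotlib
renderer in the CLI) draws them.

Transforms: ``linear, -linear, log2, -log2, log10, -log10, sqrt, -sqrt``.
The ``-`` variants negate their base transform (a mirrored axis).  Inputs
outside a transform's domain (p = 0 under ``-log10``, negatives under
``sqrt``) are masked out of the plot — dropped, never clipped — and are
therefore also ineligible for brushing.  This bites volcano plots whose DE
test underflowed to p = 0; such genes simply do not appear on the y-axis.

The default scatter is the volcano plot: −log10(pValue) against foldChange.
Views fall back from individual dots to hexagonal binned aggregation when the
number of genes to render reaches :data:`DOT_THRESHOLD` (strictly below the
threshold renders dots), unless a selection is active elsewhere or the user
forces dots.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .errors import ValidationError
from .io import Experiment

#: genes-to-render threshold: strictly below → dots, at or above → hex bins
DOT_THRESHOLD = 5000

#: default hex radius = x-range / HEX_COLUMNS
HEX_COLUMNS = 30

SQRT3 = math.sqrt(3.0)

TRANSFORM_NAMES = (
    "linear", "-linear", "log2", "-log2", "log10", "-log10", "sqrt", "-sqrt",
)

_BASE_FN = {
    "linear": lambda x: x.copy(),
    "log2": np.log2,
    "log10": np.log10,
    "sqrt": np.sqrt,
}
_BASE_DOMAIN = {
    "linear": lambda x: np.ones(x.shape, dtype=bool),
    "log2": lambda x: x > 0,
    "log10": lambda x: x > 0,
    "sqrt": lambda x: x >= 0,
}


def transform_values(values, transform: str) -> tuple[np.ndarray, np.ndarray]:
    """Apply an axis transform; return (transformed, in_domain mask).

    Out-of-domain inputs (and NaN) are masked, with NaN in the output at those
    positions.  ``-`` variants negate the base transform.
    """
    if transform not in TRANSFORM_NAMES:
        raise ValidationError(
            f"unknown transform {transform!r}; expected one of {TRANSFORM_NAMES}"
        )
    x = np.asarray(values, dtype=float)
    negate = transform.startswith("-")
    base = transform[1:] if negate else transform
    mask = _BASE_DOMAIN[base](x) & ~np.isnan(x)
    out = np.full(x.shape, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        out[mask] = _BASE_FN[base](x[mask])
    if negate:
        out = -out
    return out, mask


@dataclass
class ViewState:
    """Axes, transforms and ranges of one scatter/hex view.

    ``x_range``/``y_range`` are in *transformed* space; ``None`` means the full
    data range.  ``transform_memory`` remembers the last transform used per
    dimension so axis swaps restore it.
    """

    x_dim: str
    y_dim: str
    transform_x: str = "linear"
    transform_y: str = "linear"
    x_range: tuple[float, float] | None = None
    y_range: tuple[float, float] | None = None
    force_dots: bool = False
    zoom_enabled: bool = True
    numeric_dims: frozenset = frozenset()
    transform_memory: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for t in (self.transform_x, self.transform_y):
            if t not in TRANSFORM_NAMES:
                raise ValidationError(f"unknown transform {t!r}")

    def copy(self) -> "ViewState":
        return replace(self, transform_memory=dict(self.transform_memory))


def default_view(experiment: Experiment) -> ViewState:
    """The initial view: a volcano plot, −log10(pValue) against foldChange."""
    for dim in ("foldChange", "pValue"):
        if dim not in experiment.dictionary.names:
            raise ValidationError(
                f"experiment {experiment.id!r} lacks dimension {dim!r} "
                f"needed for the default volcano view"
            )
    numeric = frozenset(experiment.dictionary.numeric_names)
    return ViewState(
        x_dim="foldChange",
        y_dim="pValue",
        transform_x="linear",
        transform_y="-log10",
        numeric_dims=numeric,
        transform_memory={"foldChange": "linear", "pValue": "-log10"},
    )


def view_points(
    experiment: Experiment, view: ViewState
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(gene indices in-domain, x, y) of an experiment under the view's transforms."""
    tx, mx = transform_values(experiment.numeric_values(view.x_dim), view.transform_x)
    ty, my = transform_values(experiment.numeric_values(view.y_dim), view.transform_y)
    mask = mx & my
    idx = np.flatnonzero(mask)
    return idx, tx[idx], ty[idx]


def swap_axis(view: ViewState, clicked_dim: str) -> ViewState:
    """Put the clicked dimension on the x-axis, moving the current x to the y-axis.

    Each dimension keeps its last-used transform (default linear).  Clicking
    the current x dimension is a no-op.
    """
    if view.numeric_dims and clicked_dim not in view.numeric_dims:
        raise ValidationError(
            f"cannot plot non-numeric dimension {clicked_dim!r} on an axis"
        )
    if clicked_dim == view.x_dim:
        return view.copy()
    out = view.copy()
    out.transform_memory[view.x_dim] = view.transform_x
    out.transform_memory[view.y_dim] = view.transform_y
    out.y_dim = view.x_dim
    out.transform_y = view.transform_x
    out.x_dim = clicked_dim
    out.transform_x = out.transform_memory.get(clicked_dim, "linear")
    out.x_range = None
    out.y_range = None
    return out


# ---------------------------------------------------------------------------
# hexagonal binning


@dataclass(frozen=True)
class HexBinGrid:
    """Flat-top hexagonal lattice with per-hex gene counts.

    Only occupied hexes are listed; every assigned gene maps to its nearest
    center (ties broken toward the smaller (column, row) lattice index).
    """

    orientation: str
    radius: float
    centers: tuple[tuple[float, float], ...]
    counts: np.ndarray
    assignment: dict

    @property
    def total(self) -> int:
        return int(self.counts.sum()) if len(self.counts) else 0


def _hex_center(col: int, row: int, x0: float, y0: float, r: float) -> tuple[float, float]:
    cx = x0 + 1.5 * r * col
    cy = y0 + SQRT3 * r * row + (SQRT3 / 2.0 * r if col % 2 else 0.0)
    return cx, cy


def hexbin(points, radius: float, ids: Sequence | None = None) -> HexBinGrid:
    """Assign 2-D points to a flat-top hexagonal lattice anchored at the data minimum.

    ``points`` is an (n, 2) array of transformed, in-domain coordinates.  Each
    point goes to its nearest lattice center; empty hexes are omitted.  ``ids``
    (default: point indices) key the assignment map.
    """
    if radius <= 0:
        raise ValidationError("hex radius must be > 0")
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    if ids is None:
        ids = list(range(len(pts)))
    if len(ids) != len(pts):
        raise ValidationError("ids and points length mismatch")
    if len(pts) == 0:
        return HexBinGrid("flat-top", float(radius), (), np.zeros(0, dtype=int), {})
    if not np.isfinite(pts).all():
        raise ValidationError("hexbin requires finite, in-domain points")

    x0 = float(pts[:, 0].min())
    y0 = float(pts[:, 1].min())
    r = float(radius)

    keys: list[tuple[int, int]] = []
    for x, y in pts:
        c_est = (x - x0) / (1.5 * r)
        r_est = (y - y0) / (SQRT3 * r)
        best = None
        for col in range(int(math.floor(c_est)) - 2, int(math.floor(c_est)) + 3):
            for row in range(int(math.floor(r_est)) - 2, int(math.floor(r_est)) + 3):
                cx, cy = _hex_center(col, row, x0, y0, r)
                d2 = (x - cx) ** 2 + (y - cy) ** 2
                cand = (d2, col, row)
                if best is None or cand < best:
                    best = cand
        keys.append((best[1], best[2]))

    occupied = sorted(set(keys))
    index_of = {k: i for i, k in enumerate(occupied)}
    counts = np.zeros(len(occupied), dtype=int)
    assignment: dict = {}
    for pid, k in zip(ids, keys):
        i = index_of[k]
        counts[i] += 1
        assignment[pid] = i
    centers = tuple(_hex_center(c, w, x0, y0, r) for c, w in occupied)
    return HexBinGrid("flat-top", r, centers, counts, assignment)


def default_hex_radius(x_values: np.ndarray) -> float:
    """Default hex radius: one thirtieth of the x data range (min 1e-9)."""
    x = np.asarray(x_values, dtype=float)
    span = float(np.nanmax(x) - np.nanmin(x)) if x.size else 0.0
    return max(span / HEX_COLUMNS, 1e-9)


def render_mode(
    n_to_render: int,
    any_selection_active: bool = False,
    force_dots: bool = False,
    threshold: int = DOT_THRESHOLD,
) -> str:
    """Decide dots vs hex bins: dots iff forced, a selection is active, or
    the gene count is strictly below the threshold."""
    if n_to_render < 0:
        raise ValidationError("n_to_render must be >= 0")
    return "dots" if (force_dots or any_selection_active or n_to_render < threshold) else "hex"


# ---------------------------------------------------------------------------
# diverging color scale (blue → white → red)


def diverging_color(
    value: float, low: float, mid: float, high: float
) -> tuple[int, int, int]:
    """Map a value to the blue(low) → white(mid) → red(high) diverging scale.

    Piecewise-linear per channel; inputs clamped to [low, high].
    """
    if low >= high:
        raise ValidationError("diverging_color requires low < high")
    if not (low <= mid <= high):
        raise ValidationError("mid must lie in [low, high]")
    v = min(max(float(value), low), high)
    if v <= mid:
        t = 1.0 if mid == low else (v - low) / (mid - low)
        # blue (0,0,255) -> white (255,255,255)
        c = (round(255 * t), round(255 * t), 255)
    else:
        t = (v - mid) / (high - mid)
        # white -> red (255,0,0)
        c = (255, round(255 * (1 - t)), round(255 * (1 - t)))
    return (int(c[0]), int(c[1]), int(c[2]))


# ---------------------------------------------------------------------------
# small multiples


def small_multiple_view(
    context_experiment: Experiment,
    focus_view: ViewState,
    selection,
) -> tuple[ViewState, frozenset]:
    """The view model of one context experiment's small multiple.

    Shares the focus view's axes, transforms and full ranges; never zooms into
    the selected area.  The highlight set is the selection linked into the
    context experiment (genes it lacks are dropped).
    """
    from .query import link_selection  # local import: avoid cycle

    missing = [
        d for d in (focus_view.x_dim, focus_view.y_dim)
        if d not in context_experiment.dictionary.names
    ]
    if missing:
        raise ValidationError(
            f"context experiment {context_experiment.id!r} lacks dimension(s) {missing}"
        )
    view = focus_view.copy()
    view.zoom_enabled = False
    highlight = frozenset(link_selection(selection, context_experiment))
    return view, highlight
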