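"""The experiment-similarity overview: PCA of the p-value matrix.

Experiments are the observations, genes the variables.  Gene columns are
mean-centered but not scaled (p-values already share the [0,1] scale; unit
variance would amplify near-constant genes).  Experiments whose genes reach
similar significance land close together in the (PC1, PC2) plane — including
an experiment and the same comparison run in the opposite direction, whose
p-values are identical.

Large matrices use a seeded randomized SVD (oversampling 10, two power
iterations); matrices whose smaller dimension is at most
:data:`EXACT_FALLBACK_DIM` use an exact decomposition, which also serves as
the correctness oracle for the randomized path.  Component signs follow a
fixed convention — the largest-magnitude gene loading of each component is
made positive — so coordinates are stable across runs and implementations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np
from sklearn.utils.extmath import randomized_svd

from .collection import ExperimentCollection, PvalueMatrix, assemble_pvalue_matrix
from .errors import ValidationError

#: exact SVD is used when min(n_experiments, n_genes) does not exceed this
EXACT_FALLBACK_DIM = 25

#: randomized-SVD parameters (speed knobs; correctness is oracle-defined)
N_OVERSAMPLES = 10
N_POWER_ITER = 2


@dataclass(frozen=True)
class OverviewCoordinates:
    """Per-experiment scores on the leading principal components."""

    experiment_ids: tuple[str, ...]
    pc1: np.ndarray
    pc2: np.ndarray
    explained_variance: tuple[float, ...]
    n_genes_used: int
    seed: int

    def __post_init__(self) -> None:
        n = len(self.experiment_ids)
        if len(self.pc1) != n or len(self.pc2) != n:
            raise ValidationError("coordinate lengths disagree with experiment ids")
        if not (np.isfinite(self.pc1).all() and np.isfinite(self.pc2).all()):
            raise ValidationError("coordinates must be finite")

    def coords(self, eid: str) -> tuple[float, float]:
        try:
            i = self.experiment_ids.index(eid)
        except ValueError:
            raise ValidationError(f"unknown experiment id {eid!r}") from None
        return float(self.pc1[i]), float(self.pc2[i])


def _scores_from_loadings(Xc: np.ndarray, vt: np.ndarray) -> np.ndarray:
    """Project onto the loadings with a fixed sign convention.

    Scores are computed as ``Xc @ vt.T`` (not ``U·S``) so experiments with
    bit-identical p-value rows always receive bit-identical coordinates.  Each
    component's sign is fixed by making its largest-magnitude gene loading
    positive.
    """
    vt = vt.copy()
    for j in range(vt.shape[0]):
        i = int(np.argmax(np.abs(vt[j])))
        if vt[j, i] < 0:
            vt[j] *= -1.0
    # project unique rows once: identical rows must get bit-identical scores,
    # which BLAS does not guarantee across row positions
    uniq, inverse = np.unique(Xc, axis=0, return_inverse=True)
    return (uniq @ vt.T)[inverse]


def compute_overview(
    matrix: PvalueMatrix, n_components: int = 2, seed: int = 0
) -> OverviewCoordinates:
    """Project experiments onto the leading principal components of the p-value matrix.

    Columns are mean-centered; no scaling.  The randomized algorithm is seeded,
    so identical seeds give bit-identical coordinates.  Raises if the matrix
    has fewer than two experiments or carries no variance at all.
    """
    X = np.asarray(matrix.values, dtype=float)
    n, g = X.shape
    if n < 2:
        raise ValidationError("overview needs at least 2 experiments")
    if g < 2:
        raise ValidationError("overview needs at least 2 genes")
    Xc = X - X.mean(axis=0, keepdims=True)
    total_var = float((Xc * Xc).sum())
    if total_var == 0.0:
        raise ValidationError("no variance: all experiments have identical p-values")

    k = min(n_components, n, g)
    if min(n, g) <= EXACT_FALLBACK_DIM:
        u, s, vt = np.linalg.svd(Xc, full_matrices=False)
        u, s, vt = u[:, :k], s[:k], vt[:k]
    else:
        u, s, vt = randomized_svd(
            Xc,
            n_components=k,
            n_oversamples=N_OVERSAMPLES,
            n_iter=N_POWER_ITER,
            random_state=seed,
        )
    scores = _scores_from_loadings(Xc, vt)
    if k < n_components:  # pad degenerate trailing components with zeros
        scores = np.hstack([scores, np.zeros((n, n_components - k))])
        s = np.concatenate([s, np.zeros(n_components - k)])
    explained = tuple(float(si * si) / total_var for si in s[:n_components])
    return OverviewCoordinates(
        experiment_ids=matrix.experiment_ids,
        pc1=scores[:, 0].copy(),
        pc2=scores[:, 1].copy(),
        explained_variance=explained,
        n_genes_used=g,
        seed=seed,
    )


def recompute_on_selection(
    collection: ExperimentCollection,
    selection: Iterable[str],
    seed: int = 0,
    n_components: int = 2,
) -> OverviewCoordinates:
    """Re-run the overview restricted to a selected gene set.

    Equivalent to assembling the p-value matrix over ``selection`` and calling
    :func:`compute_overview`; ``n_genes_used`` reports the intersection size.
    """
    selected = set(selection)
    if not selected:
        raise ValidationError("empty selection")
    matrix = assemble_pvalue_matrix(collection, selected)
    return compute_overview(matrix, n_components=n_components, seed=seed)


def nearest_experiments(
    coords: OverviewCoordinates, focus_id: str, k: int = 5
) -> list[tuple[str, float]]:
    """Experiments nearest the focus in the (PC1, PC2) plane, ascending.

    Euclidean distance; ties broken lexicographically by id; the focus itself
    is excluded; ``k`` larger than the number of other experiments returns all
    of them.
    """
    if k < 1:
        raise ValidationError("k must be >= 1")
    fx, fy = coords.coords(focus_id)
    out = []
    for i, eid in enumerate(coords.experiment_ids):
        if eid == focus_id:
            continue
        d = math.hypot(float(coords.pc1[i]) - fx, float(coords.pc2[i]) - fy)
        out.append((eid, d))
    out.sort(key=lambda t: (t[1], t[0]))
    return out[:k]
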