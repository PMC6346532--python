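"""Experiment collections, focus/context bookkeeping, and p-value matrix assembly.

A collection holds many experiments (public and private).  One of them may be
the *focus experiment* — the one under detailed scrutiny — while an ordered set
of *context experiments* is displayed alongside for comparison.  Docs note: the
tool performs well beyond it, but a maximum of 4 context experiments is the
recommended working set.

The cross-experiment similarity machinery consumes an experiments × genes
matrix of p-values.  The gene universe is the UNION of all gene sets; a gene
absent from an experiment (or present with a missing p-value) is imputed with
1.0 — a missing test is treated as maximally non-significant — and flagged in
``imputed_mask``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Callable, Iterable

import numpy as np

from .errors import ValidationError
from .io import (
    Experiment,
    read_data_dictionary,
    read_de_table,
    write_data_dictionary,
    write_de_table,
)

#: imputation constant for (experiment, gene) cells without an observed p-value
IMPUTED_P = 1.0

#: the paper-recommended maximum number of context experiments (advisory only)
RECOMMENDED_MAX_CONTEXT = 4


@dataclass(frozen=True)
class ExperimentCollection:
    """An insertion-ordered set of experiments with focus/context designation."""

    experiments: dict[str, Experiment]
    focus_id: str | None = None
    context_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        for eid in ([self.focus_id] if self.focus_id else []) + list(self.context_ids):
            if eid not in self.experiments:
                raise ValidationError(f"unknown experiment id {eid!r}")
        if self.focus_id is not None and self.focus_id in self.context_ids:
            raise ValidationError("focus experiment cannot also be a context experiment")
        if len(set(self.context_ids)) != len(self.context_ids):
            raise ValidationError("context_ids contains duplicates")

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(self.experiments)

    def __len__(self) -> int:
        return len(self.experiments)

    def __getitem__(self, eid: str) -> Experiment:
        try:
            return self.experiments[eid]
        except KeyError:
            raise ValidationError(f"unknown experiment id {eid!r}") from None

    @property
    def focus(self) -> Experiment:
        if self.focus_id is None:
            raise ValidationError("no focus experiment set")
        return self.experiments[self.focus_id]


@dataclass(frozen=True)
class PvalueMatrix:
    """experiments × genes p-value matrix with imputation provenance."""

    experiment_ids: tuple[str, ...]
    gene_universe: tuple[str, ...]
    values: np.ndarray
    imputed_mask: np.ndarray

    def __post_init__(self) -> None:
        n, g = len(self.experiment_ids), len(self.gene_universe)
        if self.values.shape != (n, g) or self.imputed_mask.shape != (n, g):
            raise ValidationError("matrix shape does not match its labels")
        if len(set(self.experiment_ids)) != n or len(set(self.gene_universe)) != g:
            raise ValidationError("matrix labels must be unique")
        if np.isnan(self.values).any() or (self.values < 0).any() or (self.values > 1).any():
            raise ValidationError("p-values must lie in [0, 1]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def build_collection(experiments: Iterable[Experiment]) -> ExperimentCollection:
    """Build a collection from experiments; insertion order is preserved.

    Raises on an empty list or duplicate ids.  No focus is set.
    """
    exps = list(experiments)
    if not exps:
        raise ValidationError("cannot build a collection from an empty experiment list")
    by_id: dict[str, Experiment] = {}
    for e in exps:
        if e.id in by_id:
            raise ValidationError(f"duplicate experiment id {e.id!r}")
        by_id[e.id] = e
    return ExperimentCollection(by_id)


def set_focus(collection: ExperimentCollection, eid: str) -> ExperimentCollection:
    """Designate ``eid`` as focus; the previous focus becomes a context experiment.

    Setting the current focus again is a no-op.
    """
    if eid not in collection.experiments:
        raise ValidationError(f"unknown experiment id {eid!r}")
    if eid == collection.focus_id:
        return collection
    context = [c for c in collection.context_ids if c != eid]
    if collection.focus_id is not None:
        context.append(collection.focus_id)
    return replace(collection, focus_id=eid, context_ids=tuple(context))


def assemble_pvalue_matrix(
    collection: ExperimentCollection,
    gene_subset: Iterable[str] | None = None,
    *,
    transform: Callable[[np.ndarray], np.ndarray] | None = None,
) -> PvalueMatrix:
    """Stack all experiments' p-values over the union gene universe.

    The universe is the union of gene IDs across experiments in insertion
    order (first-seen order), optionally intersected with ``gene_subset``.
    Cells with no observed p-value hold :data:`IMPUTED_P` and are flagged in
    the imputed mask.

    ``transform`` is an experimentation hook applied to the finished value
    matrix (e.g. ``lambda p: -np.log10(p + 1e-300)``); the default — raw
    p-values — is what the similarity overview is defined on.
    """
    ids = collection.ids
    missing_p = [
        eid for eid in ids if "pValue" not in collection[eid].dictionary.names
    ]
    if missing_p:
        raise ValidationError(f"experiment(s) lacking a pValue dimension: {missing_p}")

    universe: list[str] = []
    seen: set[str] = set()
    for eid in ids:
        for g in collection[eid].genes:
            if g not in seen:
                seen.add(g)
                universe.append(g)
    if gene_subset is not None:
        keep = set(gene_subset)
        universe = [g for g in universe if g in keep]
    if not universe:
        raise ValidationError("empty gene universe")

    col_of = {g: j for j, g in enumerate(universe)}
    n, g = len(ids), len(universe)
    values = np.full((n, g), IMPUTED_P, dtype=float)
    imputed = np.ones((n, g), dtype=bool)
    for i, eid in enumerate(ids):
        for gene, p in collection[eid].pvalue_map().items():
            j = col_of.get(gene)
            if j is None:
                continue
            if math.isnan(p):
                continue  # present but unobserved: stays imputed at 1.0
            values[i, j] = p
            imputed[i, j] = False
    if transform is not None:
        values = np.asarray(transform(values), dtype=float)
    return PvalueMatrix(tuple(ids), tuple(universe), values, imputed)


# ---------------------------------------------------------------------------
# on-disk collection layout: one subfolder per experiment + a manifest


def save_collection(collection: ExperimentCollection, directory) -> None:
    """Write a collection directory: per-experiment subfolders plus manifest.json.

    Each subfolder holds ``table.tsv``, ``dictionary.json`` and ``meta.json``.
    """
    root = Path(directory)
    root.mkdir(parents=True, exist_ok=True)
    for eid in collection.ids:
        exp = collection[eid]
        sub = root / eid
        sub.mkdir(parents=True, exist_ok=True)
        write_de_table(exp, sub / "table.tsv")
        write_data_dictionary(exp.dictionary, sub / "dictionary.json")
        meta = {
            "id": exp.id,
            "title": exp.title,
            "visibility": exp.visibility,
            "icon": exp.icon,
        }
        with open(sub / "meta.json", "w", encoding="utf-8") as fh:
            json.dump(meta, fh, indent=2, sort_keys=True)
            fh.write("\n")
    manifest = {
        "experiments": list(collection.ids),
        "focus": collection.focus_id,
        "context": list(collection.context_ids),
    }
    with open(root / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")


def load_collection(directory) -> ExperimentCollection:
    """Read a collection directory written by :func:`save_collection`."""
    root = Path(directory)
    manifest_path = root / "manifest.json"
    if not manifest_path.exists():
        raise ValidationError(f"{root}: no manifest.json")
    with open(manifest_path, "r", encoding="utf-8") as fh:
        manifest = json.load(fh)
    exps = []
    for eid in manifest["experiments"]:
        sub = root / eid
        with open(sub / "meta.json", "r", encoding="utf-8") as fh:
            meta = json.load(fh)
        dictionary = read_data_dictionary(sub / "dictionary.json")
        exps.append(
            read_de_table(
                sub / "table.tsv",
                dictionary,
                id=meta["id"],
                title=meta.get("title", ""),
                visibility=meta.get("visibility", "private"),
                icon=meta.get("icon", "box"),
            )
        )
    coll = build_collection(exps)
    context = tuple(manifest.get("context") or ())
    focus = manifest.get("focus")
    return replace(coll, focus_id=focus, context_ids=context)
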