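"""Reading and writing differential-expression tables and their data dictionaries.

A DE table is delimited text with one gene per row: an ``EnsemblID`` column plus
numeric statistics such as ``foldChange``, ``pValue`` and ``baseMean``.  Which
columns exist, and their semantic kind, is declared by a JSON *data dictionary*;
the dictionary is authoritative — no type inference is ever performed on the
table itself.

Missing values are recognised on input as ``""``, ``"NA"`` or ``"NaN"``
(case-insensitive) and always written back as ``NA``.  The read/write pair is an
exact round trip on every declared dimension.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ParseError, ValidationError

REQUIRED_ID = "EnsemblID"

#: semantic kinds a dimension may declare
KINDS = ("numeric", "categorical", "identifier")

#: case-insensitive missing-value markers accepted on input
MISSING_MARKERS = frozenset({"", "na", "nan"})

#: marker written for missing values
MISSING_OUT = "NA"


@dataclass(frozen=True)
class Dimension:
    """One named column of a DE table with its semantic kind."""

    name: str
    kind: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.name:
            raise ValidationError("dimension name must be non-empty")
        if self.kind not in KINDS:
            raise ValidationError(
                f"dimension {self.name!r}: unknown kind {self.kind!r}; "
                f"expected one of {KINDS}"
            )


@dataclass(frozen=True)
class DataDictionary:
    """Declares the dimensions of a DE table.

    Invariants: exactly one dimension has kind ``identifier`` and it is named
    ``EnsemblID``; names are unique and non-empty.  Unknown top-level JSON
    fields are preserved in :attr:`extra` as opaque metadata.
    """

    dimensions: tuple[Dimension, ...]
    extra: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = [d.name for d in self.dimensions]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValidationError(f"duplicate dimension names: {dupes}")
        ids = [d.name for d in self.dimensions if d.kind == "identifier"]
        if ids != [REQUIRED_ID]:
            raise ValidationError(
                f"a data dictionary must declare exactly one identifier "
                f"dimension named {REQUIRED_ID!r}; found {ids!r}"
            )

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(d.name for d in self.dimensions)

    def kind_of(self, name: str) -> str:
        for d in self.dimensions:
            if d.name == name:
                return d.kind
        raise ValidationError(f"unknown dimension {name!r}")

    @property
    def numeric_names(self) -> tuple[str, ...]:
        return tuple(d.name for d in self.dimensions if d.kind == "numeric")

    def with_dimensions(self, new: Iterable[Dimension]) -> "DataDictionary":
        return DataDictionary(self.dimensions + tuple(new), self.extra)


@dataclass
class Experiment:
    """One DE experiment: a gene × dimension table plus metadata.

    ``data`` holds one column per declared dimension, in dictionary order;
    numeric columns are float64 with NaN for missing, other columns are
    strings with NaN for missing.  Gene IDs are unique and row order is
    meaningful (it is preserved through every operation).
    """

    id: str
    title: str
    visibility: str
    icon: str
    data: pd.DataFrame
    dictionary: DataDictionary

    def __post_init__(self) -> None:
        if self.visibility not in ("public", "private"):
            raise ValidationError(
                f"experiment {self.id!r}: visibility must be public|private, "
                f"got {self.visibility!r}"
            )
        missing_cols = [n for n in self.dictionary.names if n not in self.data.columns]
        if missing_cols:
            raise ValidationError(
                f"experiment {self.id!r}: table lacks declared dimensions "
                f"{missing_cols}"
            )
        genes = self.data[REQUIRED_ID]
        if genes.isna().any():
            raise ValidationError(f"experiment {self.id!r}: missing gene IDs")
        dup = genes[genes.duplicated()].unique().tolist()
        if dup:
            raise ValidationError(
                f"experiment {self.id!r}: duplicate EnsemblID values: {dup[:10]}"
            )
        if "pValue" in self.data.columns and self.dictionary.kind_of("pValue") == "numeric":
            p = self.data["pValue"].to_numpy(dtype=float)
            bad = np.flatnonzero(~np.isnan(p) & ((p < 0.0) | (p > 1.0)))
            if bad.size:
                raise ValidationError(
                    f"experiment {self.id!r}: pValue outside [0,1] at rows "
                    f"{bad[:10].tolist()}"
                )

    @property
    def genes(self) -> tuple[str, ...]:
        return tuple(self.data[REQUIRED_ID].tolist())

    @property
    def n_genes(self) -> int:
        return len(self.data)

    def numeric_values(self, dimension: str) -> np.ndarray:
        """Float64 values of a numeric dimension (NaN where missing)."""
        if self.dictionary.kind_of(dimension) != "numeric":
            raise ValidationError(f"dimension {dimension!r} is not numeric")
        return self.data[dimension].to_numpy(dtype=float)

    def pvalue_map(self) -> dict[str, float]:
        """gene ID -> pValue (NaN where missing)."""
        p = self.numeric_values("pValue")
        return dict(zip(self.genes, p.tolist()))


@dataclass(frozen=True)
class AnnotationTable:
    """A local gene-annotation table keyed by EnsemblID, one row per key."""

    data: pd.DataFrame  # index = EnsemblID

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dup = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValidationError(f"annotation has duplicate keys: {dup[:10]}")

    @property
    def columns(self) -> tuple[str, ...]:
        return tuple(self.data.columns)


# ---------------------------------------------------------------------------
# data dictionary I/O


def read_data_dictionary(path) -> DataDictionary:
    """Load and validate a data dictionary from a JSON document.

    The document must contain a ``dimensions`` array of objects with ``name``,
    ``kind`` and optional ``description``; any other top-level fields are kept
    as opaque metadata.
    """
    with open(path, "r", encoding="utf-8") as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ParseError(
                f"{path}: malformed JSON at line {exc.lineno}, column {exc.colno}: "
                f"{exc.msg}"
            ) from exc
    return data_dictionary_from_obj(doc)


def data_dictionary_from_obj(doc: object) -> DataDictionary:
    if not isinstance(doc, dict):
        raise ValidationError("data dictionary must be a JSON object")
    if "dimensions" not in doc:
        raise ValidationError("data dictionary lacks the 'dimensions' field")
    raw = doc["dimensions"]
    if not isinstance(raw, list):
        raise ValidationError("'dimensions' must be an array")
    dims = []
    for i, entry in enumerate(raw):
        if not isinstance(entry, dict) or "name" not in entry or "kind" not in entry:
            raise ValidationError(
                f"dimensions[{i}] must be an object with 'name' and 'kind'"
            )
        dims.append(
            Dimension(
                name=str(entry["name"]),
                kind=str(entry["kind"]),
                description=str(entry.get("description", "")),
            )
        )
    extra = {k: v for k, v in doc.items() if k != "dimensions"}
    return DataDictionary(tuple(dims), extra)


def write_data_dictionary(dictionary: DataDictionary, path) -> None:
    doc: dict[str, object] = dict(dictionary.extra)
    doc["dimensions"] = [
        {"name": d.name, "kind": d.kind, "description": d.description}
        for d in dictionary.dimensions
    ]
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=2, sort_keys=True)
        fh.write("\n")


# ---------------------------------------------------------------------------
# DE table I/O


def _detect_delimiter(header_line: str) -> str:
    # tab preferred, comma fallback
    return "\t" if "\t" in header_line else ","


def _parse_numeric_column(raw: pd.Series, name: str, path) -> np.ndarray:
    out = np.empty(len(raw), dtype=float)
    for i, cell in enumerate(raw):
        s = "" if cell is None or (isinstance(cell, float) and math.isnan(cell)) else str(cell).strip()
        if s.lower() in MISSING_MARKERS:
            out[i] = np.nan
            continue
        try:
            out[i] = float(s)
        except ValueError as exc:
            raise ParseError(
                f"{path}: column {name!r}, row {i}: cannot parse {s!r} as a number"
            ) from exc
    return out


def read_de_table(
    path,
    dictionary: DataDictionary,
    *,
    id: str | None = None,
    title: str = "",
    visibility: str = "private",
    icon: str = "box",
) -> Experiment:
    """Read a delimited DE table into an :class:`Experiment`.

    The delimiter is auto-detected from the header line (tab preferred, comma
    fallback).  Every dictionary dimension must appear in the header; extra
    columns are ignored.  Row order is preserved exactly.
    """
    with open(path, "r", encoding="utf-8") as fh:
        header_line = fh.readline()
    if not header_line:
        raise ParseError(f"{path}: empty file")
    sep = _detect_delimiter(header_line.rstrip("\n"))
    frame = pd.read_csv(
        path, sep=sep, dtype=str, keep_default_na=False, na_values=[], engine="python"
    )
    missing = [n for n in dictionary.names if n not in frame.columns]
    if missing:
        raise ValidationError(
            f"{path}: table lacks declared column(s) {missing}"
        )

    cols: dict[str, object] = {}
    for dim in dictionary.dimensions:
        raw = frame[dim.name]
        if dim.kind == "numeric":
            cols[dim.name] = _parse_numeric_column(raw, dim.name, path)
        else:
            vals = raw.astype(str).str.strip()
            cols[dim.name] = vals.where(~vals.str.lower().isin(MISSING_MARKERS), np.nan)
    data = pd.DataFrame(cols, columns=list(dictionary.names))
    exp_id = id if id is not None else str(path)
    return Experiment(
        id=exp_id,
        title=title,
        visibility=visibility,
        icon=icon,
        data=data,
        dictionary=dictionary,
    )


def _format_float(v: float) -> str:
    if math.isnan(v):
        return MISSING_OUT
    # repr gives the shortest string that round-trips the float64 exactly
    return repr(float(v))


def write_de_table(experiment: Experiment, path, *, sep: str = "\t") -> None:
    """Write an experiment's table as delimited text.

    Numeric values use the shortest decimal representation that round-trips the
    binary value exactly, so ``read_de_table`` inverts this function.
    """
    dims = experiment.dictionary.dimensions
    lines = [sep.join(d.name for d in dims)]
    numeric = {d.name for d in dims if d.kind == "numeric"}
    cells: list[list[str]] = []
    for d in dims:
        col = experiment.data[d.name]
        if d.name in numeric:
            cells.append([_format_float(v) for v in col.to_numpy(dtype=float)])
        else:
            cells.append(
                [MISSING_OUT if (isinstance(v, float) and math.isnan(v)) or v is None else str(v)
                 for v in col]
            )
    for row in zip(*cells):
        lines.append(sep.join(row))
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# annotation joins


def read_annotation_table(path) -> AnnotationTable:
    """Read a TSV annotation table keyed by EnsemblID."""
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, na_values=[])
    if REQUIRED_ID not in frame.columns:
        raise ValidationError(f"{path}: annotation table lacks {REQUIRED_ID!r}")
    frame = frame.set_index(REQUIRED_ID)
    return AnnotationTable(frame)


def join_annotations(
    experiment: Experiment,
    annotation: AnnotationTable,
    columns: Sequence[str],
) -> Experiment:
    """Attach annotation columns to an experiment as new categorical dimensions.

    Genes absent from the annotation receive missing values.  Gene order, gene
    count and all existing dimensions are untouched; an empty column list
    returns the experiment unchanged.
    """
    if not columns:
        return experiment
    absent = [c for c in columns if c not in annotation.columns]
    if absent:
        raise ValidationError(f"annotation column(s) not found: {absent}")
    clash = [c for c in columns if c in experiment.dictionary.names]
    if clash:
        raise ValidationError(f"column(s) already present in experiment: {clash}")
    data = experiment.data.copy()
    genes = data[REQUIRED_ID]
    new_dims = []
    for c in columns:
        mapped = genes.map(annotation.data[c])
        data[c] = mapped.where(mapped.notna(), np.nan)
        new_dims.append(Dimension(c, "categorical", "joined annotation column"))
    return replace(
        experiment,
        data=data,
        dictionary=experiment.dictionary.with_dimensions(new_dims),
    )
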