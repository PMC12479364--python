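"""Readers, writers and validation for the formats the pipeline touches.

Count matrices travel as TSV (first column = identifier, header row mandatory)
or MatrixMarket MTX with plain-text row/column name sidecars.  Gene sets travel
as GMT (``name<TAB>description<TAB>member...``).  The canonical orientation is
genes x samples for bulk data and cells x genes for single-cell data; the
orientation is always stated explicitly, never inferred from the shape.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

Orientation = Literal["genes_by_samples", "cells_by_genes"]

__all__ = [
    "CountMatrix",
    "SpatialDataset",
    "GeneSet",
    "GeneSetCollection",
    "ValidationFinding",
    "ValidationReport",
    "read_counts",
    "write_counts",
    "read_table",
    "write_table",
    "read_gmt",
    "write_gmt",
    "validate_dataset",
]


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


@dataclasses.dataclass
class CountMatrix:
    """Integer count matrix with unique row/column identifiers.

    ``values`` is a pandas DataFrame whose index/columns carry the
    identifiers.  ``orientation`` records which axis holds genes.
    """

    values: pd.DataFrame
    orientation: Orientation = "genes_by_samples"

    def __post_init__(self) -> None:
        v = self.values
        if v.index.has_duplicates:
            dups = v.index[v.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate row identifiers: {dups[:5]}")
        if v.columns.has_duplicates:
            dups = v.columns[v.columns.duplicated()].unique().tolist()
            raise FormatError(f"duplicate column identifiers: {dups[:5]}")
        arr = v.to_numpy()
        if arr.size and np.nanmin(arr) < 0:
            raise FormatError("negative counts are not allowed")

    @property
    def gene_ids(self) -> pd.Index:
        return (
            self.values.index
            if self.orientation == "genes_by_samples"
            else self.values.columns
        )

    @property
    def sample_ids(self) -> pd.Index:
        """Sample identifiers (cells for single-cell orientation)."""
        return (
            self.values.columns
            if self.orientation == "genes_by_samples"
            else self.values.index
        )

    def as_genes_by_samples(self) -> pd.DataFrame:
        if self.orientation == "genes_by_samples":
            return self.values
        return self.values.T

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def copy(self) -> "CountMatrix":
        return CountMatrix(self.values.copy(), self.orientation)


@dataclasses.dataclass
class GeneSet:
    name: str
    description: str
    members: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.members:
            raise FormatError(f"gene set {self.name!r} has no members")


class GeneSetCollection:
    """Ordered collection of named gene sets (GMT semantics)."""

    def __init__(self, sets: Iterable[GeneSet]):
        self._sets: dict[str, GeneSet] = {}
        for s in sets:
            if s.name in self._sets:
                raise FormatError(f"duplicate gene set name: {s.name!r}")
            self._sets[s.name] = s

    def __len__(self) -> int:
        return len(self._sets)

    def __iter__(self):
        return iter(self._sets.values())

    def __contains__(self, name: str) -> bool:
        return name in self._sets

    def __getitem__(self, name: str) -> GeneSet:
        return self._sets[name]

    @property
    def names(self) -> list[str]:
        return list(self._sets)

    def members(self, name: str) -> set[str]:
        return set(self._sets[name].members)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GeneSetCollection):
            return NotImplemented
        return list(self) == list(other)


@dataclasses.dataclass
class SpatialDataset:
    """Cells/spots with coordinates, optional region labels and annotations."""

    counts: CountMatrix  # cells_by_genes orientation
    coordinates: pd.DataFrame  # columns x, y; index = cell/spot ids
    region_labels: pd.Series | None = None  # NaN = unlabeled background
    annotations: pd.Series | None = None  # optional per-cell type labels

    def __post_init__(self) -> None:
        ids = self.counts.sample_ids
        if not self.coordinates.index.equals(pd.Index(ids)):
            raise FormatError("coordinate index does not match cell identifiers")
        if not np.isfinite(self.coordinates[["x", "y"]].to_numpy()).all():
            raise FormatError("coordinates must be finite")
        for s in (self.region_labels, self.annotations):
            if s is not None and not s.index.isin(ids).all():
                raise FormatError("label index contains unknown cell identifiers")

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_counts(self.counts, out / "counts.tsv")
        write_table(self.coordinates, out / "coordinates.tsv")
        if self.region_labels is not None:
            write_table(self.region_labels.to_frame("region"), out / "regions.tsv")
        if self.annotations is not None:
            write_table(self.annotations.to_frame("annotation"), out / "annotations.tsv")


# ---------------------------------------------------------------------------
# count matrices


def read_counts(
    path: str | Path,
    format: Literal["tsv", "csv", "mtx"] = "tsv",
    orientation: Orientation = "genes_by_samples",
) -> CountMatrix:
    """Read a count matrix, validating identifiers and integrality.

    MTX input expects ``<path>`` plus sidecars ``<stem>.rownames.txt`` and
    ``<stem>.colnames.txt`` (one identifier per line).
    """
    path = Path(path)
    if format in ("tsv", "csv"):
        sep = "\t" if format == "tsv" else ","
        df = pd.read_csv(path, sep=sep, index_col=0)
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
    elif format == "mtx":
        stem = path.with_suffix("")
        rownames = _read_lines(Path(f"{stem}.rownames.txt"))
        colnames = _read_lines(Path(f"{stem}.colnames.txt"))
        mat = scipy.io.mmread(path)
        if scipy.sparse.issparse(mat):
            mat = mat.toarray()
        mat = np.asarray(mat)
        if mat.shape != (len(rownames), len(colnames)):
            raise FormatError(
                f"MTX dimensions {mat.shape} do not match sidecar lengths "
                f"({len(rownames)}, {len(colnames)})"
            )
        df = pd.DataFrame(mat, index=rownames, columns=colnames)
    else:
        raise ValueError(f"unknown format: {format!r}")

    arr = df.to_numpy()
    if not np.issubdtype(arr.dtype, np.number):
        bad = df.columns[[not np.issubdtype(t, np.number) for t in df.dtypes]]
        raise FormatError(f"non-numeric entries in columns {list(bad)[:5]}")
    if np.any(arr != np.floor(arr)):
        g, s = np.argwhere(arr != np.floor(arr))[0]
        raise FormatError(
            f"non-integer count at row {df.index[g]!r}, column {df.columns[s]!r}"
        )
    return CountMatrix(df.astype(np.int64), orientation)


def write_counts(
    counts: CountMatrix, path: str | Path, format: Literal["tsv", "csv", "mtx"] = "tsv"
) -> None:
    path = Path(path)
    if format in ("tsv", "csv"):
        counts.values.to_csv(path, sep="\t" if format == "tsv" else ",")
    elif format == "mtx":
        stem = path.with_suffix("")
        scipy.io.mmwrite(path, scipy.sparse.coo_matrix(counts.values.to_numpy()))
        Path(f"{stem}.rownames.txt").write_text(
            "\n".join(map(str, counts.values.index)) + "\n"
        )
        Path(f"{stem}.colnames.txt").write_text(
            "\n".join(map(str, counts.values.columns)) + "\n"
        )
    else:
        raise ValueError(f"unknown format: {format!r}")


def _read_lines(path: Path) -> list[str]:
    if not path.exists():
        raise FormatError(f"missing sidecar file: {path}")
    return [ln for ln in path.read_text().splitlines() if ln]


def read_table(path: str | Path, index_col: int | None = 0) -> pd.DataFrame:
    """Read a TSV metadata table (samples, cells, coordinates, truth)."""
    df = pd.read_csv(path, sep="\t", index_col=index_col)
    if index_col is not None:
        df.index = df.index.astype(str)
    return df


def write_table(df: pd.DataFrame, path: str | Path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index)


# ---------------------------------------------------------------------------
# GMT


def read_gmt(path: str | Path) -> GeneSetCollection:
    sets: list[GeneSet] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise FormatError(
                f"{path}:{lineno}: GMT line needs name, description and >=1 member "
                f"(got {len(fields)} fields)"
            )
        name, description, *members = fields
        members = [m for m in members if m]
        if not members:
            raise FormatError(f"{path}:{lineno}: gene set {name!r} has no members")
        sets.append(GeneSet(name, description, tuple(members)))
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    lines = [
        "\t".join([s.name, s.description, *s.members]) for s in collection
    ]
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# dataset validation


@dataclasses.dataclass
class ValidationFinding:
    level: Literal["fatal", "warning"]
    message: str


@dataclasses.dataclass
class ValidationReport:
    findings: list[ValidationFinding]

    @property
    def fatal(self) -> bool:
        return any(f.level == "fatal" for f in self.findings)

    def __bool__(self) -> bool:  # truthy iff clean
        return not self.findings

    def messages(self, level: str | None = None) -> list[str]:
        return [f.message for f in self.findings if level is None or f.level == level]


def validate_dataset(
    counts: CountMatrix,
    meta: pd.DataFrame,
    required_factors: Sequence[str] = (),
) -> ValidationReport:
    """Cross-check a count matrix against its metadata table.

    Fatal findings: samples missing from metadata (or vice versa), missing
    declared factor columns.  Warnings: all-zero samples.
    """
    findings: list[ValidationFinding] = []
    sample_ids = counts.sample_ids
    meta_ids = meta.index.astype(str)

    missing_meta = sample_ids.difference(meta_ids)
    if len(missing_meta):
        findings.append(
            ValidationFinding(
                "fatal", f"samples absent from metadata: {sorted(missing_meta)[:10]}"
            )
        )
    extra_meta = meta_ids.difference(sample_ids)
    if len(extra_meta):
        findings.append(
            ValidationFinding(
                "fatal", f"metadata rows with no matching sample: {sorted(extra_meta)[:10]}"
            )
        )
    for col in required_factors:
        if col not in meta.columns:
            findings.append(
                ValidationFinding("fatal", f"missing declared factor column: {col!r}")
            )

    gxs = counts.as_genes_by_samples()
    zero = gxs.columns[(gxs.sum(axis=0) == 0).to_numpy()]
    for sid in zero:
        findings.append(ValidationFinding("warning", f"sample {sid!r} has zero total counts"))
    return ValidationReport(findings)
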