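"""Readers/writers for GMT gene set collections, expression and design
tables, and per-set results tables.

The GMT dialect is the MSigDB one: one set per line, tab separated, fields
``name<TAB>description<TAB>gene1<TAB>gene2...``, UTF-8, no quoting.
Expression tables are delimited text with gene identifiers in the first
column and sample identifiers in the header.  Missing values are rejected,
not imputed: the rotation model requires a complete matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionData",
    "DesignSpec",
    "GeneSet",
    "GeneSetCollection",
    "read_gmt",
    "write_gmt",
    "read_expression",
    "read_design",
    "two_group_design",
    "write_results",
    "RESULT_COLUMNS",
]


class GmtParseError(ValueError):
    """Raised when a GMT file violates the format."""


@dataclass(frozen=True)
class ExpressionData:
    """Log-scale expression matrix, genes x samples.

    Parameters
    ----------
    values
        ``(q, n)`` float array of log2 expression (intensities or
        regularized counts); must be finite.
    gene_ids
        Unique identifiers for the ``q`` rows.
    sample_ids
        Unique identifiers for the ``n`` columns.
    """

    values: np.ndarray
    gene_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "gene_ids", tuple(map(str, self.gene_ids)))
        object.__setattr__(self, "sample_ids", tuple(map(str, self.sample_ids)))
        if values.ndim != 2:
            raise ValueError("expression values must be a 2-d matrix")
        q, n = values.shape
        if len(self.gene_ids) != q:
            raise ValueError(f"{len(self.gene_ids)} gene ids for {q} rows")
        if len(self.sample_ids) != n:
            raise ValueError(f"{len(self.sample_ids)} sample ids for {n} columns")
        if len(set(self.gene_ids)) != q:
            dupes = _duplicates(self.gene_ids)
            raise ValueError(f"duplicate gene ids: {dupes}")
        if len(set(self.sample_ids)) != n:
            raise ValueError(f"duplicate sample ids: {_duplicates(self.sample_ids)}")
        if not np.all(np.isfinite(values)):
            bad = int(np.sum(~np.isfinite(values)))
            raise ValueError(f"expression matrix has {bad} non-finite entries")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.gene_ids), columns=list(self.sample_ids)
        )


@dataclass(frozen=True)
class DesignSpec:
    """Design matrix plus the single-degree-of-freedom contrast of interest.

    ``X`` is ``(n, p)`` and must have full column rank with ``n > p`` so at
    least one residual degree of freedom remains.  ``contrast`` is a length-p
    vector c; the tested effect is ``c' beta``.
    """

    X: np.ndarray
    contrast: np.ndarray
    column_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        X = np.atleast_2d(np.asarray(self.X, dtype=float))
        contrast = np.asarray(self.contrast, dtype=float).ravel()
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "contrast", contrast)
        n, p = X.shape
        names = tuple(self.column_names) or tuple(f"x{j}" for j in range(p))
        object.__setattr__(self, "column_names", names)
        if len(names) != p:
            raise ValueError("column_names length does not match design columns")
        if contrast.shape != (p,):
            raise ValueError(f"contrast length {contrast.size} != p = {p}")
        if not np.any(contrast != 0):
            raise ValueError("contrast is the zero vector")
        if n <= p:
            raise ValueError(f"need n > p for residual df (n={n}, p={p})")
        if np.linalg.matrix_rank(X) < p:
            raise ValueError("design matrix is rank deficient")
        if not np.all(np.isfinite(X)):
            raise ValueError("design matrix has non-finite entries")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_coef(self) -> int:
        return self.X.shape[1]

    @property
    def df_residual(self) -> int:
        return self.X.shape[0] - self.X.shape[1]


@dataclass(frozen=True)
class GeneSet:
    """A named gene set; genes are kept in file order, de-duplicated."""

    name: str
    genes: tuple[str, ...]
    description: str = ""

    def __post_init__(self) -> None:
        genes = tuple(dict.fromkeys(map(str, self.genes)))
        object.__setattr__(self, "genes", genes)
        if not genes:
            raise ValueError(f"gene set {self.name!r} is empty")

    @property
    def size(self) -> int:
        return len(self.genes)


@dataclass(frozen=True)
class GeneSetCollection:
    """Ordered collection of uniquely named gene sets."""

    sets: tuple[GeneSet, ...]

    def __post_init__(self) -> None:
        sets = tuple(self.sets)
        object.__setattr__(self, "sets", sets)
        names = [s.name for s in sets]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate gene set names: {_duplicates(names)}")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def __getitem__(self, key: int | str) -> GeneSet:
        if isinstance(key, str):
            for s in self.sets:
                if s.name == key:
                    return s
            raise KeyError(key)
        return self.sets[key]

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.sets)


def _duplicates(items: Iterable[str]) -> list[str]:
    seen: set[str] = set()
    out: list[str] = []
    for x in items:
        if x in seen and x not in out:
            out.append(x)
        seen.add(x)
    return out


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file into a :class:`GeneSetCollection`.

    Each non-blank line must have at least three tab-separated fields
    (name, description, one or more genes).  Duplicate genes within a line
    are dropped keeping the first occurrence; empty trailing fields are
    ignored.  A line with fewer than three fields or a repeated set name
    raises :class:`GmtParseError` naming the line.
    """
    path = Path(path)
    sets: list[GeneSet] = []
    with path.open("r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            fields = line.split("\t")
            # drop empty trailing fields (common when exported from sheets)
            while fields and fields[-1] == "":
                fields.pop()
            if len(fields) < 3:
                raise GmtParseError(
                    f"{path.name}:{lineno}: expected >=3 tab-separated fields, "
                    f"got {len(fields)}"
                )
            name, description, *genes = fields
            genes = [g for g in genes if g != ""]
            if not genes:
                raise GmtParseError(f"{path.name}:{lineno}: no genes listed")
            sets.append(GeneSet(name=name, description=description, genes=tuple(genes)))
    try:
        return GeneSetCollection(tuple(sets))
    except ValueError as exc:
        raise GmtParseError(f"{path.name}: {exc}") from exc


def write_gmt(collection: GeneSetCollection, path: str | Path) -> Path:
    """Write a collection in the same GMT dialect `read_gmt` accepts."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for s in collection:
            fh.write("\t".join([s.name, s.description, *s.genes]) + "\n")
    return path


def _read_table(path: str | Path) -> pd.DataFrame:
    sep = "," if str(path).endswith(".csv") else "\t"
    return pd.read_csv(path, sep=sep, index_col=0, dtype={0: str})


def read_expression(path: str | Path) -> ExpressionData:
    """Read a delimited expression table (first column gene ids, header row
    sample ids).  Duplicated gene ids, non-numeric cells and missing values
    are rejected; imputation is out of scope.
    """
    df = _read_table(path)
    index = df.index.astype(str)
    if index.duplicated().any():
        dupes = sorted(set(index[index.duplicated()]))
        raise ValueError(f"duplicate gene ids in {path}: {dupes}")
    try:
        values = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"non-numeric expression values in {path}: {exc}") from exc
    if np.isnan(values).any():
        n_bad = int(np.isnan(values).sum())
        raise ValueError(
            f"{n_bad} missing value(s) in {path}; complete matrices are required"
        )
    return ExpressionData(
        values=values,
        gene_ids=tuple(index),
        sample_ids=tuple(map(str, df.columns)),
    )


def read_design(
    path: str | Path, contrast: Sequence[float] | None = None
) -> DesignSpec:
    """Read a design table (first column sample ids, one column per
    covariate).  ``contrast`` defaults to selecting the last coefficient.
    """
    df = _read_table(path)
    X = df.to_numpy(dtype=float)
    if contrast is None:
        contrast = np.zeros(X.shape[1])
        contrast[-1] = 1.0
    return DesignSpec(X=X, contrast=np.asarray(contrast, float),
                      column_names=tuple(map(str, df.columns)))


def two_group_design(n_per_group: Sequence[int] | int) -> DesignSpec:
    """Intercept + group-indicator design for a two-group comparison.

    ``n_per_group`` may be a single int (balanced) or ``(n0, n1)``.  The
    contrast picks the group coefficient, i.e. the mean difference
    (group 1 minus group 0).
    """
    if isinstance(n_per_group, int):
        n0 = n1 = n_per_group
    else:
        n0, n1 = n_per_group
    group = np.r_[np.zeros(n0), np.ones(n1)]
    X = np.column_stack([np.ones(n0 + n1), group])
    return DesignSpec(X=X, contrast=np.array([0.0, 1.0]),
                      column_names=("intercept", "group"))


RESULT_COLUMNS = [
    "set_name",
    "size_total",
    "size_used",
    "score_name",
    "hypothesis",
    "observed_score",
    "pvalue",
    "fdr",
    "direction",
]


def write_results(results: pd.DataFrame, path: str | Path) -> Path:
    """Write a per-set results table as TSV.

    Requires the standard result columns (``effective_size`` optional);
    row order is preserved.  Empty tables are an error.
    """
    if results is None or len(results) == 0:
        raise ValueError("results table is empty")
    missing = [c for c in RESULT_COLUMNS if c not in results.columns]
    if missing:
        raise ValueError(f"results table missing columns: {missing}")
    cols = list(RESULT_COLUMNS)
    if "effective_size" in results.columns:
        cols.append("effective_size")
    path = Path(path)
    results.loc[:, cols].to_csv(path, sep="\t", index=False, float_format="%.10g")
    return path
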