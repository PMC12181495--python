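"""Reading and writing of count matrices, sample metadata, trained
references and prediction tables.

All formats are plain text: count matrices are TSV/CSV with genes as rows
and samples as columns (first column gene IDs, header row sample IDs),
metadata is a CSV with ``sample_id`` and ``age_months`` columns, and a
trained reference is a TSV with a small JSON header in ``#`` comment lines
so it stays human-inspectable and diff-able.

Gene identifiers are treated as opaque strings; no normalization of e.g.
Ensembl IDs is attempted.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConsistencyError, FormatError

__all__ = [
    "CountMatrix",
    "AgeAnnotation",
    "read_count_matrix",
    "write_count_matrix",
    "read_age_annotation",
    "write_age_annotation",
    "read_reference",
    "write_reference",
    "write_predictions",
]

_REFERENCE_MAGIC = "# txclock-reference"
_SCHEMA_VERSION = 1


def _check_unique(ids: Sequence[str], kind: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise FormatError(f"duplicate {kind} ID: {i!r}")
        seen.add(i)


class CountMatrix:
    """A genes x samples matrix of non-negative integer read counts.

    Parameters
    ----------
    gene_ids, sample_ids
        Unique row / column identifiers, order-preserving.
    counts
        Array of shape ``(len(gene_ids), len(sample_ids))``; values must be
        non-negative and integral (floats within 1e-9 of an integer are
        accepted and rounded).
    """

    def __init__(self, gene_ids: Sequence[str], sample_ids: Sequence[str],
                 counts: np.ndarray) -> None:
        gene_ids = tuple(str(g) for g in gene_ids)
        sample_ids = tuple(str(s) for s in sample_ids)
        _check_unique(gene_ids, "gene")
        _check_unique(sample_ids, "sample")
        arr = np.asarray(counts)
        if arr.ndim != 2 or arr.shape != (len(gene_ids), len(sample_ids)):
            raise FormatError(
                f"count matrix shape {arr.shape} does not match "
                f"{len(gene_ids)} genes x {len(sample_ids)} samples")
        if not np.isfinite(arr.astype(float)).all():
            raise FormatError("count matrix contains non-finite values")
        if (arr < 0).any():
            bad = arr.min()
            raise ValueError(f"negative count encountered: {bad}")
        if not np.issubdtype(arr.dtype, np.integer):
            rounded = np.rint(arr)
            if np.abs(arr - rounded).max() > 1e-9:
                raise ValueError("non-integral count values in matrix")
            arr = rounded
        self.gene_ids = gene_ids
        self.sample_ids = sample_ids
        self.counts = arr.astype(np.int64)

    # -- container niceties -------------------------------------------------
    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def column(self, sample_id: str) -> np.ndarray:
        """Counts for one sample, in gene order."""
        try:
            j = self.sample_ids.index(sample_id)
        except ValueError:
            raise KeyError(f"unknown sample {sample_id!r}") from None
        return self.counts[:, j].copy()

    def select_samples(self, sample_ids: Sequence[str]) -> "CountMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return CountMatrix(self.gene_ids, sample_ids, self.counts[:, idx])

    def drop_sample(self, sample_id: str) -> "CountMatrix":
        keep = [s for s in self.sample_ids if s != sample_id]
        if len(keep) == len(self.sample_ids):
            raise KeyError(f"unknown sample {sample_id!r}")
        return self.select_samples(keep)

    def select_genes(self, gene_ids: Sequence[str]) -> "CountMatrix":
        pos = {g: i for i, g in enumerate(self.gene_ids)}
        idx = [pos[g] for g in gene_ids]
        return CountMatrix(gene_ids, self.sample_ids, self.counts[idx, :])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.gene_ids),
                            columns=list(self.sample_ids))

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CountMatrix":
        return cls(list(df.index.astype(str)), list(df.columns.astype(str)),
                   df.to_numpy())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CountMatrix):
            return NotImplemented
        return (self.gene_ids == other.gene_ids
                and self.sample_ids == other.sample_ids
                and np.array_equal(self.counts, other.counts))

    def __repr__(self) -> str:
        return f"CountMatrix({self.n_genes} genes x {self.n_samples} samples)"


class AgeAnnotation:
    """Mapping of sample ID to chronological age in months (strictly > 0)."""

    def __init__(self, ages: Mapping[str, float]) -> None:
        clean: dict[str, float] = {}
        for sid, age in ages.items():
            a = float(age)
            if not np.isfinite(a) or a <= 0:
                raise ValueError(f"age for sample {sid!r} must be > 0, got {age}")
            clean[str(sid)] = a
        self._ages = clean

    def __getitem__(self, sample_id: str) -> float:
        return self._ages[sample_id]

    def __contains__(self, sample_id: str) -> bool:
        return sample_id in self._ages

    def __len__(self) -> int:
        return len(self._ages)

    def __iter__(self):
        return iter(self._ages)

    def items(self):
        return self._ages.items()

    def ages_for(self, sample_ids: Sequence[str]) -> np.ndarray:
        """Ages for the given samples, in the given order."""
        missing = [s for s in sample_ids if s not in self._ages]
        if missing:
            raise KeyError(f"samples without age annotation: {missing}")
        return np.array([self._ages[s] for s in sample_ids], dtype=float)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AgeAnnotation):
            return NotImplemented
        return self._ages == other._ages

    def __repr__(self) -> str:
        return f"AgeAnnotation({len(self)} samples)"


def _infer_delimiter(path: str | Path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "\t" if str(path).endswith((".tsv", ".tab", ".txt")) else ","


def read_count_matrix(path: str | Path, delimiter: str | None = None,
                      transposed: bool = False) -> CountMatrix:
    """Load a count matrix from a delimited text file.

    The first column holds gene IDs and the header row sample IDs. Set
    ``transposed=True`` when the file stores samples as rows; orientation is
    never auto-detected.
    """
    sep = _infer_delimiter(path, delimiter)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").rstrip("\r")
    cols = header.split(sep)[1:]
    _check_unique(cols, "sample" if not transposed else "gene")
    try:
        df = pd.read_csv(path, sep=sep, index_col=0)
    except pd.errors.ParserError as exc:
        raise FormatError(f"malformed table in {path}: {exc}") from None
    if transposed:
        df = df.T
    _check_unique(list(df.index.astype(str)), "gene")
    values = df.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    if np.isnan(values).any():
        raise FormatError(f"non-numeric or missing cells in {path}")
    return CountMatrix(list(df.index.astype(str)),
                       list(df.columns.astype(str)), values)


def write_count_matrix(cm: CountMatrix, path: str | Path,
                       delimiter: str | None = None) -> None:
    sep = _infer_delimiter(path, delimiter)
    cm.to_frame().to_csv(path, sep=sep, index_label="gene_id")


def read_age_annotation(path: str | Path) -> AgeAnnotation:
    """Load sample ages from a CSV with ``sample_id`` and ``age_months``.

    Extra columns are ignored; rows whose age does not parse as a number are
    skipped.  A sample repeated with the same age is tolerated; conflicting
    ages raise :class:`ConsistencyError`.
    """
    df = pd.read_csv(path)
    required = {"sample_id", "age_months"}
    if not required.issubset(df.columns):
        raise FormatError(
            f"{path} must have columns sample_id and age_months; "
            f"found {list(df.columns)}")
    ages: dict[str, float] = {}
    for sid, raw in zip(df["sample_id"].astype(str), df["age_months"]):
        age = pd.to_numeric(raw, errors="coerce")
        if pd.isna(age):
            continue
        age = float(age)
        if age <= 0:
            raise ValueError(f"age for sample {sid!r} must be > 0, got {age}")
        if sid in ages and ages[sid] != age:
            raise ConsistencyError(
                f"sample {sid!r} annotated with conflicting ages "
                f"{ages[sid]} and {age}")
        ages[sid] = age
    return AgeAnnotation(ages)


def write_age_annotation(ann: AgeAnnotation, path: str | Path) -> None:
    pd.DataFrame(sorted(ann.items()),
                 columns=["sample_id", "age_months"]).to_csv(path, index=False)


def write_reference(model, path: str | Path) -> None:
    """Serialize a trained reference to commented TSV.

    Two leading ``#`` lines carry a magic string and a JSON header (schema
    version, tau, age grid, frequency floor); then one row per gene with its
    Spearman rho and fitted frequency at each grid age.  Frequencies use
    shortest round-trip float representation, so read(write(m)) is exact.
    """
    header = {
        "schema_version": _SCHEMA_VERSION,
        "tau": model.tau,
        "age_grid": [float(a) for a in model.age_grid],
        "freq_floor": model.freq_floor,
    }
    cols = "\t".join(f"freq_{a:g}" for a in model.age_grid)
    with open(path, "w") as fh:
        fh.write(f"{_REFERENCE_MAGIC} v{_SCHEMA_VERSION}\n")
        fh.write(f"# {json.dumps(header)}\n")
        fh.write(f"gene_id\trho\t{cols}\n")
        for i, g in enumerate(model.gene_ids):
            freqs = "\t".join(repr(float(v)) for v in model.fitted_freq[i])
            fh.write(f"{g}\t{repr(float(model.rho[i]))}\t{freqs}\n")


def read_reference(path: str | Path):
    """Load a reference written by :func:`write_reference`."""
    from .reference import ReferenceModel

    with open(path) as fh:
        lines = fh.read().splitlines()
    if len(lines) < 3 or not lines[0].startswith(_REFERENCE_MAGIC):
        raise FormatError(f"{path} is not a txclock reference file")
    try:
        header = json.loads(lines[1].lstrip("# "))
    except json.JSONDecodeError as exc:
        raise FormatError(f"bad reference header in {path}: {exc}") from None
    if header.get("schema_version") != _SCHEMA_VERSION:
        raise FormatError(
            f"unsupported reference schema version {header.get('schema_version')!r}"
            f" (expected {_SCHEMA_VERSION})")
    grid = np.asarray(header["age_grid"], dtype=float)
    n_cols = 2 + grid.size
    gene_ids: list[str] = []
    rho: list[float] = []
    rows: list[list[float]] = []
    for line in lines[3:]:
        if not line:
            continue
        parts = line.split("\t")
        if len(parts) != n_cols:
            raise FormatError(
                f"truncated or malformed reference row in {path}: {line[:60]!r}")
        gene_ids.append(parts[0])
        rho.append(float(parts[1]))
        rows.append([float(v) for v in parts[2:]])
    if not gene_ids:
        raise FormatError(f"reference file {path} contains no genes")
    return ReferenceModel(
        tau=float(header["tau"]), age_grid=grid, gene_ids=tuple(gene_ids),
        rho=np.asarray(rho, dtype=float),
        fitted_freq=np.asarray(rows, dtype=float),
        freq_floor=float(header["freq_floor"]))


def write_predictions(results, failures, path: str | Path) -> None:
    """Write per-sample age predictions plus the posterior over grid ages.

    ``results`` is a sequence of AgeLikelihood objects (with ``sample_id``
    set); failed samples are appended with empty numeric fields.
    """
    rows = []
    grid = None
    for r in results:
        grid = r.age_grid
        row = {"sample_id": r.sample_id,
               "predicted_age_months": r.point_estimate,
               "max_log_likelihood": float(np.max(r.log_lik)),
               "n_genes_used": r.n_genes_used}
        for a, p in zip(r.age_grid, r.posterior):
            row[f"posterior_{a:g}"] = p
        rows.append(row)
    for sid, msg in failures.items():
        rows.append({"sample_id": sid, "error": msg})
    df = pd.DataFrame(rows)
    lead = ["sample_id", "predicted_age_months", "max_log_likelihood",
            "n_genes_used"]
    post = [f"posterior_{a:g}" for a in grid] if grid is not None else []
    order = [c for c in lead + post + ["error"] if c in df.columns]
    df[order].to_csv(path, index=False)
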