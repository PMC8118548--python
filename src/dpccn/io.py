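"""Domain containers and TSV readers/writers.

Expression data are held as an individuals x genes matrix with gene names in
the header row.  All network code downstream assumes columns have been z-scored
on the full, non-truncated sample; :func:`standardize` performs that scaling
and stamps the matrix so the pipeline can check it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "PhenotypeVector",
    "SurvivalDataset",
    "EdgeRecord",
    "read_expression",
    "read_phenotype",
    "read_survival",
    "standardize",
    "write_edge_list",
    "read_edge_list",
]

EdgeLabel = Literal["type_I", "type_II", "none"]


@dataclass(frozen=True)
class ExpressionMatrix:
    """An individuals x genes expression matrix.

    Parameters
    ----------
    values
        Numeric matrix of shape ``(n_individuals, p_genes)`` with no missing
        entries.
    gene_names
        ``p`` unique gene identifiers (column header).
    sample_ids
        ``n`` unique sample identifiers.
    standardized
        True once every column has been z-scored on the full sample.
    """

    values: np.ndarray
    gene_names: tuple[str, ...]
    sample_ids: tuple[str, ...]
    standardized: bool = False

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "gene_names", tuple(self.gene_names))
        object.__setattr__(self, "sample_ids", tuple(self.sample_ids))
        n, p = values.shape
        if p < 2:
            raise ValueError(f"need at least 2 genes, got {p}")
        if n < 4:
            raise ValueError(f"need at least 4 individuals, got {n}")
        if len(self.gene_names) != p:
            raise ValueError("gene_names length does not match column count")
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length does not match row count")
        if len(set(self.gene_names)) != p:
            dupes = sorted({g for g in self.gene_names if self.gene_names.count(g) > 1})
            raise ValueError(f"duplicate gene names: {dupes}")
        if len(set(self.sample_ids)) != n:
            raise ValueError("duplicate sample ids")
        if not np.all(np.isfinite(values)):
            raise ValueError("expression matrix contains non-finite entries")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]

    def with_values(self, values: np.ndarray, standardized: bool | None = None) -> "ExpressionMatrix":
        return replace(
            self,
            values=values,
            standardized=self.standardized if standardized is None else standardized,
        )


@dataclass(frozen=True)
class PhenotypeVector:
    """A continuous phenotype, one value per individual."""

    values: np.ndarray
    name: str = "phenotype"

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float).ravel()
        object.__setattr__(self, "values", values)
        if not np.all(np.isfinite(values)):
            raise ValueError("phenotype contains non-finite values")

    def __len__(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class SurvivalDataset:
    """Right-censored survival outcomes: time on study plus an event flag.

    ``event`` is 1 when death was observed and 0 when the observation was
    right-censored.
    """

    time: np.ndarray
    event: np.ndarray

    def __post_init__(self) -> None:
        time = np.asarray(self.time, dtype=float).ravel()
        event = np.asarray(self.event, dtype=int).ravel()
        object.__setattr__(self, "time", time)
        object.__setattr__(self, "event", event)
        if time.shape != event.shape:
            raise ValueError("time and event lengths differ")
        if np.any(time < 0) or not np.all(np.isfinite(time)):
            raise ValueError("survival times must be finite and non-negative")
        if not np.isin(event, (0, 1)).all():
            raise ValueError("event indicator must be 0 or 1")

    def __len__(self) -> int:
        return self.time.shape[0]

    def uncensored(self) -> np.ndarray:
        """Boolean mask of observed (non-censored) rows."""
        return self.event == 1


@dataclass(frozen=True)
class EdgeRecord:
    """One differential-network edge with its interaction-type label."""

    gene_a: str
    gene_b: str
    q_value: float
    q_signed: float
    label: EdgeLabel

    def __post_init__(self) -> None:
        if self.gene_a == self.gene_b:
            raise ValueError("self-edges are not allowed")
        if self.q_value < 0:
            raise ValueError("q_value must be non-negative")
        sign = np.sign(self.q_signed)
        expected = {"type_I": 1.0, "type_II": -1.0, "none": 0.0}[self.label]
        if sign != expected:
            raise ValueError(
                f"label {self.label!r} inconsistent with q_signed={self.q_signed}"
            )
        if self.label != "none" and abs(abs(self.q_signed) - self.q_value) > 1e-9:
            raise ValueError("|q_signed| must equal q_value for labeled edges")


def read_expression(path: str | Path, delimiter: str = "\t") -> ExpressionMatrix:
    """Read an individuals x genes table with a header row of gene names.

    An optional first column named ``sample_id`` (or any non-numeric first
    column) supplies sample identifiers; otherwise rows are numbered.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(delimiter)
    dupes = sorted({h for h in header if header.count(h) > 1})
    if dupes:
        raise ValueError(f"duplicate gene names in header: {dupes}")
    df = pd.read_csv(path, sep=delimiter, header=0)
    if df.shape[1] >= 2 and df.iloc[:, 0].dtype == object:
        sample_ids = [str(s) for s in df.iloc[:, 0]]
        df = df.iloc[:, 1:]
    else:
        sample_ids = [str(i) for i in range(len(df))]
    bad = [c for c in df.columns if not np.issubdtype(df[c].dtype, np.number)]
    if bad:
        for c in bad:
            col = pd.to_numeric(df[c], errors="coerce")
            row = int(col.isna().idxmax())
            raise ValueError(f"non-numeric value in column {c!r}, row {row}")
    if df.isna().any().any():
        raise ValueError("missing values in expression table")
    return ExpressionMatrix(
        values=df.to_numpy(dtype=float),
        gene_names=[str(c) for c in df.columns],
        sample_ids=sample_ids,
    )


def read_phenotype(path: str | Path, delimiter: str = "\t") -> PhenotypeVector:
    """Read a one-column phenotype table (header row = phenotype name)."""
    df = pd.read_csv(Path(path), sep=delimiter, header=0)
    col = df.columns[-1]
    return PhenotypeVector(values=df[col].to_numpy(dtype=float), name=str(col))


def read_survival(path: str | Path, delimiter: str = "\t") -> SurvivalDataset:
    """Read a survival TSV with columns ``time`` and ``event``."""
    df = pd.read_csv(Path(path), sep=delimiter, header=0)
    return SurvivalDataset(
        time=df["time"].to_numpy(dtype=float),
        event=df["event"].to_numpy(dtype=int),
    )


def standardize(X: ExpressionMatrix) -> ExpressionMatrix:
    """Z-score every column on the full sample (n-1 denominator).

    Scaling always happens before any phenotypic truncation; group subsets are
    never re-standardized.  The input object is left untouched.
    """
    values = X.values
    sd = values.std(axis=0, ddof=1)
    constant = np.flatnonzero(sd == 0)
    if constant.size:
        names = [X.gene_names[i] for i in constant]
        raise ValueError(f"constant column(s) cannot be standardized: {names}")
    z = (values - values.mean(axis=0)) / sd
    return X.with_values(z, standardized=True)


def _edge_sort_key(e: EdgeRecord) -> tuple:
    return (-abs(e.q_signed), e.gene_a, e.gene_b)


def write_edge_list(edges: Sequence[EdgeRecord], path: str | Path) -> None:
    """Write edges as TSV, ordered by descending |Q_signed| then name pair."""
    rows = sorted(edges, key=_edge_sort_key)
    df = pd.DataFrame(
        {
            "gene_a": [e.gene_a for e in rows],
            "gene_b": [e.gene_b for e in rows],
            "Q": [e.q_value for e in rows],
            "Q_signed": [e.q_signed for e in rows],
            "type": [e.label for e in rows],
        }
    )
    df.to_csv(Path(path), sep="\t", index=False, float_format="%.12g")


def read_edge_list(path: str | Path) -> list[EdgeRecord]:
    df = pd.read_csv(Path(path), sep="\t", header=0)
    return [
        EdgeRecord(
            gene_a=str(r.gene_a),
            gene_b=str(r.gene_b),
            q_value=float(r.Q),
            q_signed=float(r.Q_signed),
            label=str(r.type),
        )
        for r in df.itertuples()
    ]
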