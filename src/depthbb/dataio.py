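"""Reading and writing count tables, sample sheets, models and result rows.

The on-disk dialect is deliberately plain: UTF-8 TSV with a header row.
A count table has the gene id in the first column, an optional ``length``
column (gene length in nucleotides) and one integer column per sequencing
run. A separate sample sheet maps each run to its biological sample,
library preparation and (optionally) flow-cell lane, so that
"same library, different lanes" and "different libraries" comparisons are
both expressible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, FormatError
from .model import OverdispersionModel

__all__ = [
    "CountMatrix",
    "GenePairCounts",
    "GeneResultRow",
    "RESULT_COLUMNS",
    "read_sample_sheet",
    "read_count_table",
    "write_count_table",
    "extract_pair",
    "write_results",
    "read_results",
    "write_model",
    "read_model",
]

SHEET_REQUIRED = ("run_id", "sample_id", "library_id")
SHEET_OPTIONAL = ("lane_id", "condition")
RESULT_COLUMNS = (
    "gene_id",
    "n",
    "m",
    "p_hat",
    "fold_change",
    "p_value",
    "method",
    "passed_min_count",
)
RESULT_METHODS = ("binomial", "betabinom", "ttest")


@dataclass
class CountMatrix:
    """Gene-by-run integer counts plus per-run metadata.

    ``counts`` has shape (n_genes, n_runs); ``run_meta`` is indexed by
    run id in column order and carries sample_id, library_id, lane_id and
    condition.
    """

    gene_ids: np.ndarray
    counts: np.ndarray
    run_meta: pd.DataFrame
    lengths: Optional[np.ndarray] = None

    def __post_init__(self):
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.counts = np.asarray(self.counts)
        if len(np.unique(self.gene_ids)) != len(self.gene_ids):
            raise FormatError("gene ids must be unique")
        if self.counts.shape != (len(self.gene_ids), len(self.run_meta)):
            raise FormatError("counts shape must be (n_genes, n_runs)")
        if np.any(np.asarray(self.counts, dtype=float) % 1 != 0):
            raise FormatError("counts must be integers")
        if np.any(self.counts < 0):
            raise FormatError("counts must be >= 0")
        self.counts = self.counts.astype(np.int64)
        if self.lengths is not None:
            self.lengths = np.asarray(self.lengths, dtype=np.int64)
            if self.lengths.shape != self.gene_ids.shape:
                raise FormatError("lengths must align with gene_ids")
            if np.any(self.lengths < 1):
                raise FormatError("gene lengths must be >= 1")
        for col in SHEET_REQUIRED[1:]:
            if col not in self.run_meta.columns:
                raise ConfigurationError(f"run_meta lacks required column {col!r}")
            if self.run_meta[col].isna().any():
                raise ConfigurationError(f"every run needs a {col}")

    @property
    def run_ids(self):
        return list(self.run_meta.index)

    @property
    def totals(self):
        """Total mapped tags per run."""
        return self.counts.sum(axis=0)

    def run_index(self, run_id: str) -> int:
        try:
            return self.run_meta.index.get_loc(run_id)
        except KeyError:
            raise KeyError(f"unknown run id {run_id!r}") from None


@dataclass
class GenePairCounts:
    """Per-gene paired counts (n_i, m_i) for one A-vs-B comparison."""

    gene_ids: np.ndarray
    n: np.ndarray
    m: np.ndarray

    def __post_init__(self):
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.n = np.asarray(self.n, dtype=np.int64)
        self.m = np.asarray(self.m, dtype=np.int64)
        if not (self.gene_ids.shape == self.n.shape == self.m.shape):
            raise FormatError("gene_ids, n and m must align")
        if np.any(self.n < 0) or np.any(self.m < 0):
            raise FormatError("counts must be >= 0")

    @property
    def N(self):
        """Per-gene total n + m."""
        return self.n + self.m

    def swapped(self) -> "GenePairCounts":
        """The same comparison with the two samples exchanged."""
        return GenePairCounts(self.gene_ids, self.m.copy(), self.n.copy())


@dataclass
class GeneResultRow:
    """One gene's differential-expression call for one comparison."""

    gene_id: str
    n: int
    m: int
    p_hat: float
    fold_change: float
    p_value: float
    method: str
    passed_min_count: bool

    def __post_init__(self):
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p_value out of [0,1]: {self.p_value}")
        if not (np.isfinite(self.fold_change) and self.fold_change > 0):
            raise ValueError("fold_change must be finite and > 0")
        if self.method not in RESULT_METHODS:
            raise ValueError(f"unknown method {self.method!r}")


def read_sample_sheet(path) -> pd.DataFrame:
    """Read a run-metadata TSV (run_id, sample_id, library_id[, lane_id,
    condition]); returns a DataFrame indexed by run_id."""
    sheet = pd.read_csv(path, sep="\t", dtype=str)
    for col in SHEET_REQUIRED:
        if col not in sheet.columns:
            raise FormatError(f"sample sheet lacks required column {col!r}")
    if sheet["run_id"].duplicated().any():
        raise FormatError("duplicate run_id in sample sheet")
    for col in SHEET_OPTIONAL:
        if col not in sheet.columns:
            sheet[col] = None
    return sheet.set_index("run_id")


def read_count_table(path, sample_sheet) -> CountMatrix:
    """Read a gene-by-run count table, validated against a sample sheet.

    ``sample_sheet`` may be a path or an already-read DataFrame indexed by
    run_id. Every count column must be declared in the sheet; counts must
    be non-negative integers; gene ids must be unique.
    """
    if not isinstance(sample_sheet, pd.DataFrame):
        sample_sheet = read_sample_sheet(sample_sheet)
    table = pd.read_csv(path, sep="\t")
    if table.shape[1] < 2:
        raise FormatError("count table needs a gene id column and >= 1 run")
    gene_col = table.columns[0]
    gene_ids = table[gene_col].astype(str).to_numpy(dtype=object)
    if pd.Series(gene_ids).duplicated().any():
        raise FormatError("duplicate gene id in count table")

    lengths = None
    run_cols = [c for c in table.columns[1:]]
    if "length" in run_cols:
        lengths = pd.to_numeric(table["length"], errors="coerce")
        if lengths.isna().any() or (lengths % 1 != 0).any() or (lengths < 1).any():
            raise FormatError("gene lengths must be positive integers")
        lengths = lengths.to_numpy(dtype=np.int64)
        run_cols.remove("length")

    missing = [c for c in run_cols if c not in sample_sheet.index]
    if missing:
        raise ConfigurationError(
            f"run column(s) {missing} absent from the sample sheet"
        )
    counts = table[run_cols].apply(pd.to_numeric, errors="coerce")
    if counts.isna().any().any():
        raise FormatError("counts must be numeric")
    vals = counts.to_numpy(dtype=float)
    if np.any(vals % 1 != 0):
        raise FormatError("counts must be integers")
    if np.any(vals < 0):
        raise FormatError("counts must be >= 0")
    meta = sample_sheet.loc[run_cols].copy()
    return CountMatrix(
        gene_ids=gene_ids,
        counts=vals.astype(np.int64),
        run_meta=meta,
        lengths=lengths,
    )


def write_count_table(cm: CountMatrix, path) -> None:
    """Write a CountMatrix back to TSV (inverse of :func:`read_count_table`)."""
    table = pd.DataFrame({"gene_id": cm.gene_ids})
    if cm.lengths is not None:
        table["length"] = cm.lengths
    for j, run in enumerate(cm.run_ids):
        table[run] = cm.counts[:, j]
    table.to_csv(path, sep="\t", index=False)


def write_sample_sheet(run_meta: pd.DataFrame, path) -> None:
    run_meta.reset_index(names="run_id").to_csv(path, sep="\t", index=False)


def extract_pair(cm: CountMatrix, run_a: str, run_b: str) -> GenePairCounts:
    """Pull one A-vs-B comparison out of a count matrix.

    Genes with zero total are retained (downstream operations filter on
    the total count). Unknown run ids raise ``KeyError``.
    """
    ia = cm.run_index(run_a)
    ib = cm.run_index(run_b)
    return GenePairCounts(
        gene_ids=cm.gene_ids.copy(),
        n=cm.counts[:, ia].copy(),
        m=cm.counts[:, ib].copy(),
    )


def write_results(rows: Sequence[GeneResultRow], path) -> None:
    """Write result rows as TSV with a fixed column order.

    Integers round-trip exactly; reals are written with 12 significant
    digits.
    """
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(RESULT_COLUMNS) + "\n")
        for r in rows:
            fh.write(
                f"{r.gene_id}\t{r.n}\t{r.m}\t{r.p_hat:.12g}\t"
                f"{r.fold_change:.12g}\t{r.p_value:.12g}\t{r.method}\t"
                f"{int(r.passed_min_count)}\n"
            )


def read_results(path) -> list:
    """Read a result TSV written by :func:`write_results`."""
    table = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    missing = [c for c in RESULT_COLUMNS if c not in table.columns]
    if missing:
        raise FormatError(f"result table lacks column(s) {missing}")
    return [
        GeneResultRow(
            gene_id=row.gene_id,
            n=int(row.n),
            m=int(row.m),
            p_hat=float(row.p_hat),
            fold_change=float(row.fold_change),
            p_value=float(row.p_value),
            method=row.method,
            passed_min_count=bool(row.passed_min_count),
        )
        for row in table.itertuples(index=False)
    ]


def write_model(model: OverdispersionModel, path) -> None:
    """Serialize a fitted model to JSON
    ({"gamma", "D", "loglik", "gamma_grid"})."""
    payload = {
        "gamma": model.gamma,
        "D": {g: float(d) for g, d in model.D.items()},
        "loglik": model.loglik,
        "gamma_grid": [[float(g), float(ll)] for g, ll in model.gamma_grid],
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=1)


def read_model(path) -> OverdispersionModel:
    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    return OverdispersionModel(
        gamma=float(payload["gamma"]),
        D={g: float(d) for g, d in payload["D"].items()},
        loglik=float(payload["loglik"]),
        gamma_grid=[(float(g), float(ll)) for g, ll in payload["gamma_grid"]],
    )
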