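"""Droplet-level processing: raw barcode matrices, cell calling, cell-line
assignment, median normalization and QC.

Cell calling follows the expected-cells heuristic used by early droplet
pipelines: with ``N`` expected cells, the robust maximum total UMI ``m`` is the
99th percentile of the top-``N`` barcode totals, and every barcode whose total
UMI exceeds ``m/10`` is called a cell.  The percentile is nearest-rank on the
descending-sorted top-``N`` totals so integer inputs give exact results.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from ._util import logger

# ---------------------------------------------------------------------------
# containers


@dataclass
class RawDropletMatrix:
    """Sparse barcode x gene UMI counts for one collection time point."""

    counts: sp.csr_matrix  # barcodes x genes, nonnegative integers
    barcodes: list[str]
    genes: pd.DataFrame  # columns: gene_id, symbol
    time_point: str = ""

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        if self.counts.shape != (len(self.barcodes), len(self.genes)):
            raise ValueError(
                f"matrix shape {self.counts.shape} inconsistent with "
                f"{len(self.barcodes)} barcodes x {len(self.genes)} genes"
            )
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValueError("negative counts in raw matrix")

    @property
    def total_umi(self) -> np.ndarray:
        return np.asarray(self.counts.sum(axis=1)).ravel()


@dataclass
class CellCallingConfig:
    expected_cells_N: int
    percentile: float = 99.0
    divisor: float = 10.0

    def __post_init__(self) -> None:
        if self.expected_cells_N < 1:
            raise ValueError("expected_cells_N must be >= 1")
        if not 0 < self.percentile <= 100:
            raise ValueError("percentile must be in (0, 100]")
        if self.divisor <= 0:
            raise ValueError("divisor must be positive")


@dataclass
class CellCallingResult:
    m: float
    threshold: float
    called_barcodes: list[str]
    n_candidates: int


@dataclass
class CellMatrix:
    """Called cells (possibly pooled over time points) with raw and
    median-normalized counts and per-cell annotations."""

    raw: sp.csr_matrix  # cells x genes
    genes: pd.DataFrame  # gene_id, symbol
    cell_table: pd.DataFrame  # barcode, time_point, cell_line, stage
    normalized: sp.csr_matrix | None = None

    @property
    def n_cells(self) -> int:
        return self.raw.shape[0]

    def gene_index(self, symbol: str) -> int:
        hits = np.flatnonzero(self.genes["symbol"].to_numpy() == symbol)
        if hits.size == 0:
            raise KeyError(f"gene symbol not present: {symbol!r}")
        return int(hits[0])

    def raw_gene(self, symbol: str) -> np.ndarray:
        """Raw UMI counts of one gene across cells (dense)."""
        j = self.gene_index(symbol)
        return np.asarray(self.raw[:, j].todense()).ravel()


# ---------------------------------------------------------------------------
# Matrix Market I/O (Cell Ranger v2 dialect: matrix stored genes x barcodes)


def read_mtx_dir(path: str | Path, time_point: str = "") -> RawDropletMatrix:
    path = Path(path)
    mat = scipy.io.mmread(path / "matrix.mtx")  # genes x barcodes
    counts = sp.csr_matrix(mat.T).astype(np.int64)
    barcodes = (path / "barcodes.tsv").read_text().split()
    genes = pd.read_csv(
        path / "genes.tsv", sep="\t", header=None, names=["gene_id", "symbol"]
    )
    return RawDropletMatrix(counts, barcodes, genes, time_point or path.name)


def write_mtx_dir(raw: RawDropletMatrix, path: str | Path) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    mat = sp.coo_matrix(raw.counts.T).astype(np.int64)  # genes x barcodes
    scipy.io.mmwrite(str(path / "matrix.mtx"), mat, field="integer")
    (path / "barcodes.tsv").write_text("\n".join(raw.barcodes) + "\n")
    raw.genes.to_csv(path / "genes.tsv", sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# operations


def call_cells(raw: RawDropletMatrix, cfg: CellCallingConfig) -> CellCallingResult:
    """Identify cell-containing droplets from total UMI per barcode.

    ``m`` is the ``cfg.percentile``-th percentile (nearest rank) of the top-N
    barcode totals; barcodes with total strictly greater than ``m/divisor``
    are called.  Ties at exactly the threshold are excluded.
    """
    totals = raw.total_umi
    if totals.max(initial=0) <= 0:
        raise ValueError("no candidate cells: all barcode totals are zero")
    n = len(totals)
    N = cfg.expected_cells_N
    if N > n:
        logger.warning(
            "expected_cells_N=%d exceeds %d available barcodes; clamping", N, n
        )
        N = n
    top = np.sort(totals)[::-1][:N]  # descending
    ascending = top[::-1]
    rank = max(1, math.ceil(cfg.percentile / 100.0 * N))  # nearest rank
    m = float(ascending[rank - 1])
    threshold = m / cfg.divisor
    mask = totals > threshold
    called = [b for b, keep in zip(raw.barcodes, mask) if keep]
    return CellCallingResult(m=m, threshold=threshold, called_barcodes=called,
                             n_candidates=n)


def build_cell_matrix(
    raws: list[RawDropletMatrix], callings: list[CellCallingResult]
) -> CellMatrix:
    """Pool called cells across time points into a single cells x genes matrix."""
    if len(raws) != len(callings):
        raise ValueError("one calling result required per raw matrix")
    ref_symbols = raws[0].genes["symbol"].tolist()
    blocks, tables = [], []
    for raw, res in zip(raws, callings):
        if raw.genes["symbol"].tolist() != ref_symbols:
            raise ValueError("gene lists differ between time points")
        keep = set(res.called_barcodes)
        idx = np.flatnonzero([b in keep for b in raw.barcodes])
        blocks.append(raw.counts[idx])
        tables.append(
            pd.DataFrame(
                {
                    "barcode": [raw.barcodes[i] for i in idx],
                    "time_point": raw.time_point,
                    "cell_line": "",
                    "stage": "",
                }
            )
        )
    table = pd.concat(tables, ignore_index=True)
    for tp, sub in table.groupby("time_point"):
        if sub["barcode"].duplicated().any():
            raise ValueError(f"duplicate barcodes within time point {tp}")
    return CellMatrix(
        raw=sp.csr_matrix(sp.vstack(blocks)),
        genes=raws[0].genes.copy(),
        cell_table=table,
    )


def assign_cell_line(cells: CellMatrix, sex_marker_symbol: str = "RPS4Y1") -> pd.DataFrame:
    """Assign each cell to a line from the Y-linked marker: cells with >= 1 raw
    UMI of the marker belong to line 1, the rest to line 2."""
    try:
        marker = cells.raw_gene(sex_marker_symbol)
    except KeyError:
        raise KeyError(
            f"sex marker symbol {sex_marker_symbol!r} absent from gene list"
        ) from None
    cells.cell_table["cell_line"] = np.where(marker >= 1, "line1", "line2")
    return cells.cell_table


def normalize_to_median(cells: CellMatrix) -> CellMatrix:
    """Scale each cell so its total UMI equals the median total over all cells.

    Idempotent up to floating point; the zero pattern is preserved because the
    operation is a positive per-cell scalar multiply.
    """
    totals = np.asarray(cells.raw.sum(axis=1)).ravel().astype(float)
    if (totals <= 0).any():
        bad = cells.cell_table["barcode"].to_numpy()[totals <= 0].tolist()
        raise ValueError(f"cells with zero total UMI cannot be normalized: {bad}")
    median = float(np.median(totals))
    scale = median / totals
    cells.normalized = sp.csr_matrix(sp.diags(scale) @ cells.raw.astype(float))
    return cells


def qc_summary(cells: CellMatrix) -> dict:
    """Basic per-cell QC: mean detected genes, mean total UMI, cells per day."""
    if cells.n_cells == 0:
        raise ValueError("QC requires at least one cell")
    genes_per_cell = np.diff(cells.raw.indptr)  # nnz per row
    totals = np.asarray(cells.raw.sum(axis=1)).ravel()
    per_tp = cells.cell_table.groupby("time_point", sort=False)["barcode"].size()
    return {
        "mean_genes_per_cell": float(genes_per_cell.mean()),
        "mean_umi_per_cell": float(totals.mean()),
        "cells_per_timepoint": per_tp.to_dict(),
        "total_cells": int(cells.n_cells),
    }
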