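"""Reading/writing expression matrices and markers, QC filters, normalization.

QC mirrors the two cell filters used on the real datasets: removal of cells
dominated by ERCC spike-in reads (fraction >= 0.2 of total counts) and
restriction to cells detecting between 200 and 3,000 genes. Library-size
scaling is provided as baseline plumbing; dedicated normalization methods
(SCnorm, scran) are out of scope and pre-normalized input is accepted.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .containers import NORMALIZED, RAW_COUNTS, ExpressionMatrix, MarkerSet

SPIKE_PREFIX = "ERCC-"


def _spike_flags_from_ids(gene_ids, prefix: str) -> np.ndarray:
    return np.array([str(g).startswith(prefix) for g in gene_ids], dtype=bool)


def read_expression(
    path,
    format: str = "csv",
    layer: str = RAW_COUNTS,
    spike_prefix: str = SPIKE_PREFIX,
) -> ExpressionMatrix:
    """Read a genes x cells matrix from CSV or MatrixMarket.

    CSV: first column gene IDs, header row cell IDs. MTX: coordinate file
    plus ``genes.tsv`` / ``barcodes.tsv`` sidecars in the same directory.
    Spike-in rows are flagged by gene-ID prefix (default ``"ERCC-"``).
    """
    path = Path(path)
    if format == "csv":
        try:
            df = pd.read_csv(path, index_col=0)
        except pd.errors.ParserError as exc:  # retains the offending line number
            raise ValueError(f"malformed CSV {path}: {exc}") from exc
        values = df.to_numpy(dtype=float)
        gene_ids, cell_ids = df.index.to_numpy(object), df.columns.to_numpy(object)
    elif format == "mtx":
        mat = scipy.io.mmread(path)
        values = np.asarray(mat.todense() if scipy.sparse.issparse(mat) else mat, dtype=float)
        gene_ids = pd.read_csv(path.parent / "genes.tsv", sep="\t", header=None)[0].to_numpy(object)
        cell_ids = pd.read_csv(path.parent / "barcodes.tsv", sep="\t", header=None)[0].to_numpy(object)
    else:
        raise ValueError(f"unknown format {format!r}")
    return ExpressionMatrix(
        values=values,
        gene_ids=gene_ids,
        cell_ids=cell_ids,
        layer=layer,
        spike_flags=_spike_flags_from_ids(gene_ids, spike_prefix),
    )


def write_expression(matrix: ExpressionMatrix, path, format: str = "csv") -> None:
    """Write a matrix as CSV (genes as rows) or MTX with ID sidecars."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if format == "csv":
        matrix.to_frame().to_csv(path, index_label="gene_id")
    elif format == "mtx":
        scipy.io.mmwrite(str(path), scipy.sparse.coo_matrix(matrix.values))
        pd.Series(matrix.gene_ids).to_csv(path.parent / "genes.tsv", sep="\t", header=False, index=False)
        pd.Series(matrix.cell_ids).to_csv(path.parent / "barcodes.tsv", sep="\t", header=False, index=False)
    else:
        raise ValueError(f"unknown format {format!r}")


def read_markers(path) -> MarkerSet:
    """Read a marker table: TSV with header ``gene_id`` and ``direction``."""
    return MarkerSet(pd.read_csv(path, sep="\t"))


def write_markers(markers: MarkerSet, path) -> None:
    markers.table.to_csv(path, sep="\t", index=False)


def filter_spikein_fraction(matrix: ExpressionMatrix, threshold: float = 0.2) -> ExpressionMatrix:
    """Drop cells whose spike-in counts make up ``threshold`` or more of their
    total counts. The boundary is inclusive: a cell at exactly 20% is removed.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must lie in (0, 1]")
    if matrix.layer != RAW_COUNTS:
        raise ValueError("spike-in filtering requires the raw-counts layer")
    if not matrix.spike_flags.any():
        warnings.warn("no spike-in genes flagged; matrix returned unchanged")
        return matrix.subset_cells(np.arange(matrix.n_cells))
    totals = matrix.values.sum(axis=0)
    spike = matrix.values[matrix.spike_flags].sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(totals > 0, spike / totals, 0.0)
    return matrix.subset_cells(np.flatnonzero(frac < threshold))


def filter_genes_detected_range(
    matrix: ExpressionMatrix, min_genes: int = 200, max_genes: int = 3000
) -> ExpressionMatrix:
    """Keep cells detecting between ``min_genes`` and ``max_genes`` genes,
    both bounds inclusive; "detected" means value strictly > 0."""
    if min_genes > max_genes:
        raise ValueError("min_genes must not exceed max_genes")
    detected = (matrix.values > 0).sum(axis=0)
    keep = (detected >= min_genes) & (detected <= max_genes)
    return matrix.subset_cells(np.flatnonzero(keep))


def normalize_library_size(matrix: ExpressionMatrix, scale: float = 1e4) -> ExpressionMatrix:
    """Scale every cell to the same total ``scale``; layer becomes normalized."""
    if matrix.layer != RAW_COUNTS:
        raise ValueError("normalization expects the raw-counts layer")
    totals = matrix.values.sum(axis=0)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        raise ValueError(
            f"all-zero cell(s): {', '.join(map(str, matrix.cell_ids[zero][:10]))}"
        )
    return ExpressionMatrix(
        values=matrix.values * (scale / totals),
        gene_ids=matrix.gene_ids,
        cell_ids=matrix.cell_ids,
        layer=NORMALIZED,
        spike_flags=matrix.spike_flags.copy(),
    )
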