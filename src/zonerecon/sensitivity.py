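"""Protocol sensitivity: detection fractions and the fold-change regression.

For two datasets A and B over one gene universe, each gene contributes
y = log2(nonzero-mean A / nonzero-mean B) against x = difference in
gene-level detection fractions. The OLS intercept — the log2 fold-change at
equal detection — measures the experiment-wide sensitivity gain of A over B;
its power of two is the fold-sensitivity (an intercept of 3.1 corresponds to
roughly a 9-fold gain).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix
from .simulate import ProtocolParams, SyntheticTruth, simulate_protocol_set


def detection_fractions(matrix: ExpressionMatrix, axis: str = "cell") -> np.ndarray:
    """Detection fraction per cell (genes with value > 0 / total genes) or
    per gene (cells with value > 0 / total cells)."""
    if matrix.n_genes == 0 or matrix.n_cells == 0:
        raise ValueError("empty matrix")
    nz = matrix.values > 0
    if axis == "cell":
        return nz.sum(axis=0) / matrix.n_genes
    if axis == "gene":
        return nz.sum(axis=1) / matrix.n_cells
    raise ValueError("axis must be 'cell' or 'gene'")


def nonzero_mean(matrix: ExpressionMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Per-gene mean over cells with value > 0. Genes never detected get NaN
    and are flagged undefined. Returns (means, defined_mask)."""
    nz = matrix.values > 0
    counts = nz.sum(axis=1)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, matrix.values.sum(axis=1) / np.maximum(counts, 1), np.nan)
    return means, counts > 0


@dataclass
class SensitivityFit:
    """Per-gene fold-change vs detection-difference points and their OLS fit;
    ``fold_sensitivity`` is exactly 2**intercept."""

    table: pd.DataFrame  # gene_id, log2_fc, detection_diff, used
    slope: float
    intercept: float
    fold_sensitivity: float
    n_genes_used: int


def sensitivity_regression(matrix_a: ExpressionMatrix, matrix_b: ExpressionMatrix) -> SensitivityFit:
    """OLS of per-gene log2 fold-change (A over B, nonzero means) on the
    difference in gene-level detection fractions. Only genes with a nonzero
    mean in BOTH datasets enter (the log-ratio is undefined otherwise)."""
    shared = [g for g in matrix_a.gene_ids if g in set(matrix_b.gene_ids)]
    if not shared:
        raise ValueError("no shared genes")
    ia, ib = matrix_a.gene_index(shared), matrix_b.gene_index(shared)
    mean_a, def_a = nonzero_mean(matrix_a)
    mean_b, def_b = nonzero_mean(matrix_b)
    det_a = detection_fractions(matrix_a, axis="gene")
    det_b = detection_fractions(matrix_b, axis="gene")

    used = def_a[ia] & def_b[ib]
    with np.errstate(invalid="ignore", divide="ignore"):
        y = np.log2(mean_a[ia] / mean_b[ib])
    x = det_a[ia] - det_b[ib]
    table = pd.DataFrame(
        {"gene_id": shared, "log2_fc": y, "detection_diff": x, "used": used}
    )
    xu, yu = x[used], y[used]
    if used.sum() < 3:
        raise ValueError("fewer than 3 usable genes for the regression")
    if np.var(xu) == 0:
        slope, intercept = 0.0, float(np.mean(yu))
    else:
        slope, intercept = np.polyfit(xu, yu, 1)
    return SensitivityFit(
        table=table,
        slope=float(slope),
        intercept=float(intercept),
        fold_sensitivity=float(2.0 ** intercept),
        n_genes_used=int(used.sum()),
    )


def depth_recovery_check(
    truth: SyntheticTruth,
    deep_params: ProtocolParams,
    shallow_params: ProtocolParams,
) -> dict:
    """Validation harness: simulate two regimes from one truth and check the
    recovered fold-sensitivity against the nominal depth ratio."""
    deep, shallow = simulate_protocol_set(truth, [deep_params, shallow_params])
    fit = sensitivity_regression(deep, shallow)
    nominal = deep_params.depth_mean / shallow_params.depth_mean
    return {
        "intercept": fit.intercept,
        "fold_sensitivity": fit.fold_sensitivity,
        "nominal_depth_ratio": nominal,
        "nominal_log2": float(np.log2(nominal)),
        "n_genes_used": fit.n_genes_used,
    }
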