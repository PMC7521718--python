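"""Wave-Crest pseudospace ordering: extended nearest insertion plus 2-opt.

Cells are ordered along a one-dimensional pericentral->periportal axis using
a panel of known zonation marker genes. Marker expression is standardized to
mean 0 / variance 1 (population convention), then cells are inserted one at a
time at the gap minimizing the regression objective, and the order is refined
by adjacent-exchange 2-opt. The objective for a proposed order is the sum
over markers of the mean squared residual from an ordinary least-squares fit
of expression against position index 1..n; it is invariant under order
reversal, so the final orientation is fixed by requiring pericentral markers
to decrease along the axis.

The per-marker residual for positions x = 1..m uses only the set of cells
(through sum y and sum y^2) and the order (through sum of t*y_t), which the
insertion and 2-opt loops exploit for O(genes x n) updates per step.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .containers import CellOrder, ExpressionMatrix, MarkerSet, PERICENTRAL


@dataclass
class OrderingObjective:
    """Total and per-marker mean squared residuals for a proposed order."""

    total_mse: float
    per_marker_mse: np.ndarray

    def __post_init__(self) -> None:
        self.per_marker_mse = np.asarray(self.per_marker_mse, dtype=float)
        if not np.isclose(self.total_mse, self.per_marker_mse.sum()):
            raise ValueError("total must equal the sum of per-marker terms")


def standardize_genes(matrix: ExpressionMatrix, gene_subset) -> np.ndarray:
    """Rescale each selected gene to mean 0 and variance 1 across cells
    (population variance). Returns a (len(subset) x n_cells) array."""
    rows = matrix.gene_index(gene_subset)
    vals = matrix.values[rows, :].astype(float)
    mean = vals.mean(axis=1, keepdims=True)
    var = vals.var(axis=1, keepdims=True)  # population convention
    zero = np.flatnonzero(var.ravel() == 0)
    if zero.size:
        names = ", ".join(str(gene_subset[i]) for i in zero[:10])
        raise ValueError(f"zero-variance gene(s) cannot be standardized: {names}")
    return (vals - mean) / np.sqrt(var)


def _mse_terms(y: np.ndarray) -> np.ndarray:
    """Per-row mean squared OLS residual of y (rows) on positions 1..m."""
    m = y.shape[1]
    x = np.arange(1, m + 1, dtype=float)
    var_x = (m**2 - 1) / 12.0
    mean_y = y.mean(axis=1)
    var_y = y.var(axis=1)
    cov = (y @ x) / m - x.mean() * mean_y
    return var_y - cov**2 / var_x


def ordering_objective(order: CellOrder, standardized: np.ndarray) -> OrderingObjective:
    """Sum over markers of the mean squared residual from OLS of expression
    on position 1..n under the proposed order."""
    if order.n_cells != standardized.shape[1]:
        raise ValueError("order does not cover the cells in the table")
    if order.n_cells < 3:
        raise ValueError("need at least 3 cells for a meaningful regression residual")
    per = _mse_terms(standardized[:, order.permutation])
    return OrderingObjective(total_mse=float(per.sum()), per_marker_mse=per)


def nearest_insertion(standardized: np.ndarray, seed: int = 0) -> CellOrder:
    """Extended nearest insertion: visit cells in a seeded random sequence and
    place each at the gap (ends included) minimizing the partial-order
    objective; objective ties are broken by the leftmost gap."""
    n_markers, n = standardized.shape
    if n < 2:
        raise ValueError("need at least 2 cells")
    if n_markers < 1:
        raise ValueError("empty marker set")
    rng = np.random.default_rng(seed)
    sequence = rng.permutation(n)

    order = list(sequence[:1])
    for cell in sequence[1:]:
        m = len(order)
        y = standardized[:, order]  # markers x m
        v = standardized[:, cell]  # markers
        if m < 2:
            order.insert(0, cell)  # any gap is optimal; leftmost by convention
            continue
        # For insertion at gap g (0-based, g in 0..m), new sum_t t*y_t is
        # W + suffix_sum(g) + (g+1)*v with W over the current order.
        t = np.arange(1, m + 1, dtype=float)
        W = y @ t
        suffix = np.concatenate(
            [np.cumsum(y[:, ::-1], axis=1)[:, ::-1], np.zeros((n_markers, 1))], axis=1
        )  # suffix[:, g] = sum over positions > g (0-based gap g)
        g = np.arange(m + 1, dtype=float)
        Wg = W[:, None] + suffix + (g[None, :] + 1.0) * v[:, None]

        mp = m + 1
        mean_x = (mp + 1) / 2.0
        var_x = (mp**2 - 1) / 12.0
        sum_y = y.sum(axis=1) + v
        sum_y2 = (y**2).sum(axis=1) + v**2
        mean_y = sum_y / mp
        cov = Wg / mp - mean_x * mean_y[:, None]
        mse = sum_y2[:, None] / mp - mean_y[:, None] ** 2 - cov**2 / var_x
        best = int(np.argmin(mse.sum(axis=0)))  # argmin takes the leftmost tie
        order.insert(best, cell)
    return CellOrder(np.array(order))


def two_opt_refine(
    order: CellOrder,
    standardized: np.ndarray,
    max_sweeps: int = 100,
    full: bool = False,
) -> CellOrder:
    """Hill-climb on the ordering objective. The default considers adjacent
    cell exchanges only, sweeping left to right and accepting a swap iff it
    strictly lowers the total objective, until a sweep makes no change or
    ``max_sweeps`` is reached. ``full=True`` additionally considers segment
    reversals (classic 2-opt moves)."""
    perm = list(order.permutation)
    n = len(perm)
    if n != standardized.shape[1]:
        raise ValueError("order does not cover the cells in the table")
    if n < 3:
        return CellOrder(np.array(perm), oriented=order.oriented)

    x = np.arange(1, n + 1, dtype=float)
    var_x = (n**2 - 1) / 12.0
    mean_x = (n + 1) / 2.0
    mean_y = standardized.mean(axis=1)

    y = standardized[:, perm].copy()
    cov = (y @ x) / n - mean_x * mean_y  # only order-dependent objective part

    for _ in range(max_sweeps):
        changed = False
        for j in range(n - 1):
            # swapping positions j, j+1 shifts sum t*y_t by y_j - y_{j+1}
            delta = (y[:, j] - y[:, j + 1]) / n
            new_cov = cov + delta
            if np.sum(new_cov**2) > np.sum(cov**2) + 1e-12:  # strictly lower MSE
                y[:, [j, j + 1]] = y[:, [j + 1, j]]
                perm[j], perm[j + 1] = perm[j + 1], perm[j]
                cov = new_cov
                changed = True
        if full:
            for i in range(n - 1):
                for j in range(i + 2, n + 1):
                    seg = y[:, i:j][:, ::-1]
                    t = x[i:j]
                    new_cov = cov + (seg @ t - y[:, i:j] @ t) / n
                    if np.sum(new_cov**2) > np.sum(cov**2) + 1e-12:
                        y[:, i:j] = seg
                        perm[i:j] = perm[i:j][::-1]
                        cov = new_cov
                        changed = True
        if not changed:
            break
    return CellOrder(np.array(perm), oriented=order.oriented)


def orient_order(order: CellOrder, matrix: ExpressionMatrix, markers: MarkerSet) -> CellOrder:
    """Fix the flip freedom: reverse the order iff the mean Pearson
    correlation of pericentral-marker expression with position is positive,
    so that pericentral cells end up at position 1. An exact-zero mean
    correlation keeps the input orientation."""
    pc_genes = [g for g in markers.by_direction(PERICENTRAL) if g in set(matrix.gene_ids)]
    if not pc_genes:
        raise ValueError("no pericentral markers present in the matrix")
    pos = order.positions().astype(float)
    rows = matrix.gene_index(pc_genes)
    corrs = []
    for r in rows:
        v = matrix.values[r, :]
        if v.std() == 0 or pos.std() == 0:
            continue
        corrs.append(np.corrcoef(v, pos)[0, 1])
    if not corrs:
        raise ValueError("all pericentral markers are constant; cannot orient")
    flipped = order.reversed() if np.mean(corrs) > 0 else order
    return CellOrder(flipped.permutation, oriented=True)


def wavecrest_order(
    matrix: ExpressionMatrix,
    markers: MarkerSet,
    seed: int = 0,
    max_sweeps: int = 100,
    full_two_opt: bool = False,
) -> CellOrder:
    """Full Wave-Crest pipeline: standardize markers, nearest insertion,
    2-opt refinement, pericentral-left orientation. Markers absent from the
    matrix or with zero variance are dropped with a warning."""
    present = set(matrix.gene_ids)
    usable = []
    for g in markers.gene_ids:
        if g not in present:
            warnings.warn(f"marker {g} absent from matrix; skipped")
            continue
        if matrix.values[matrix.gene_index([g])[0], :].var() == 0:
            warnings.warn(f"marker {g} has zero variance; skipped")
            continue
        usable.append(g)
    if not usable:
        raise ValueError("no usable marker genes")
    standardized = standardize_genes(matrix, usable)
    order = nearest_insertion(standardized, seed=seed)
    order = two_opt_refine(order, standardized, max_sweeps=max_sweeps, full=full_two_opt)
    return orient_order(order, matrix, markers)


def brute_force_order(standardized: np.ndarray) -> tuple[CellOrder, float]:
    """Exhaustive global minimum of the ordering objective (oracle; n <= 9).
    Only one of each reversal pair is enumerated since the objective is
    reversal-invariant."""
    from itertools import permutations

    n = standardized.shape[1]
    if n > 9:
        raise ValueError("brute force limited to n <= 9")
    best, best_obj = None, np.inf
    for perm in permutations(range(n)):
        if perm[0] > perm[-1]:
            continue  # reversal duplicate
        obj = _mse_terms(standardized[:, perm]).sum()
        if obj < best_obj:
            best, best_obj = perm, obj
    return CellOrder(np.array(best)), float(best_obj)
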