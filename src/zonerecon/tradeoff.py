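"""Cells-versus-depth trade-off: subsample cells or thin reads, rebuild the
scaled 9-group zonation profiles, and score the error against the full data.

Depth thinning follows the multinomial downsampler: per cell, the new total
is round(X * N_c) (half-to-even) and gene probabilities are the original
counts over the original total, so per-cell targets are hit exactly and the
per-gene marginal is binomial. The error statistic is the published form
MSE = sum_i sum_j (Z_ij - Zhat_ij)^2 / n_genes over a random sample of genes
(default 500), dividing by the gene count only. When the cell order is
recomputed per replicate (Wave-Crest datasets) the reconstructed axis can
come back flipped, so the MSE is evaluated on the returned order and its
reverse and the minimum kept.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
import pandas as pd

from .containers import CellOrder, ExpressionMatrix, MarkerSet, RAW_COUNTS, ZonationProfile
from .profiles import assign_groups, group_profile, posterior_weighted_profile, scale_profile
from .wavecrest import wavecrest_order


def subsample_cells(matrix: ExpressionMatrix, n: int, seed: int = 0) -> ExpressionMatrix:
    """Uniform sample of ``n`` cells without replacement, preserving the
    relative cell order."""
    if not 1 <= n <= matrix.n_cells:
        raise ValueError(f"n must lie in [1, {matrix.n_cells}]")
    rng = np.random.default_rng(seed)
    keep = np.sort(rng.choice(matrix.n_cells, size=n, replace=False))
    return matrix.subset_cells(keep)


def downsample_depth_multinomial(matrix: ExpressionMatrix, fraction: float, seed: int = 0) -> ExpressionMatrix:
    """Thin each cell to round(X * N_c) total counts via multinomial draws
    with probabilities counts / N_c. Genes at zero stay zero; an all-zero
    cell is kept all-zero with a warning."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    if matrix.layer != RAW_COUNTS:
        raise ValueError("depth downsampling requires the raw-counts layer")
    vals = matrix.values
    if not np.allclose(vals, np.round(vals)):
        raise ValueError("raw-counts layer must hold integers")
    rng = np.random.default_rng(seed)
    out = np.zeros_like(vals)
    totals = vals.sum(axis=0)
    for c in range(matrix.n_cells):
        n_c = totals[c]
        if n_c == 0:
            warnings.warn(f"cell {matrix.cell_ids[c]} has zero counts; kept all-zero")
            continue
        target = int(np.round(fraction * n_c))  # numpy rounds half to even
        if target == 0:
            continue
        out[:, c] = rng.multinomial(target, vals[:, c] / n_c)
    return ExpressionMatrix(
        values=out,
        gene_ids=matrix.gene_ids,
        cell_ids=matrix.cell_ids,
        layer=RAW_COUNTS,
        spike_flags=matrix.spike_flags.copy(),
    )


def profile_mse(
    reference: ZonationProfile,
    perturbed: ZonationProfile,
    gene_sample: int = 500,
    seed: int = 0,
    allow_reversal: bool = False,
) -> float:
    """MSE between two scaled profiles over a random gene sample:
    sum over sampled genes and the 9 groups of squared differences, divided
    by the number of sampled genes. With ``allow_reversal`` the perturbed
    profile's group axis may be flipped and the smaller MSE is returned."""
    if not (reference.scaled and perturbed.scaled):
        raise ValueError("profiles must be scaled")
    shared = [g for g in reference.gene_ids if g in set(perturbed.gene_ids)]
    if gene_sample > len(shared):
        raise ValueError("gene_sample exceeds the shared gene universe")
    rng = np.random.default_rng(seed)
    pick = rng.choice(len(shared), size=gene_sample, replace=False)
    genes = [shared[i] for i in pick]
    ir = {g: i for i, g in enumerate(reference.gene_ids)}
    ip = {g: i for i, g in enumerate(perturbed.gene_ids)}
    ref = reference.values[[ir[g] for g in genes]]
    per = perturbed.values[[ip[g] for g in genes]]
    mse = float(np.sum((ref - per) ** 2) / gene_sample)
    if allow_reversal:
        mse = min(mse, float(np.sum((ref - per[:, ::-1]) ** 2) / gene_sample))
    return mse


@dataclass
class SubsamplingScenario:
    """One trade-off scenario: subsample cells to ``level`` cells or thin
    depth to fraction ``level``; ``reorder`` recomputes the Wave-Crest order
    per replicate (marker-ordered datasets) instead of reusing the original
    order restricted to the sampled cells."""

    mode: str  # "cells" | "depth"
    level: float
    replicates: int = 25
    n_mse_genes: int = 500
    seed: int = 0
    reorder: bool = False
    statistic: str = "mean"

    def __post_init__(self) -> None:
        if self.mode not in ("cells", "depth"):
            raise ValueError("mode must be 'cells' or 'depth'")
        if self.mode == "cells" and (self.level < 1 or self.level != int(self.level)):
            raise ValueError("cells mode needs an integer level >= 1")
        if self.mode == "depth" and not 0 < self.level <= 1:
            raise ValueError("depth mode needs a fraction in (0, 1]")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


def _restrict_order(order: CellOrder, keep: np.ndarray) -> CellOrder:
    """Original order restricted to the kept cells, re-indexed to 0..n'-1."""
    keep = np.asarray(keep)
    rank = {cell: r for r, cell in enumerate(order.permutation)}
    sub = sorted(range(len(keep)), key=lambda i: rank[keep[i]])
    return CellOrder(np.array(sub), oriented=order.oriented)


def _scaled_profile(matrix: ExpressionMatrix, order: CellOrder, statistic: str) -> ZonationProfile:
    groups = assign_groups(order)
    return scale_profile(group_profile(matrix, groups, statistic=statistic))


def run_tradeoff_grid(
    matrix: ExpressionMatrix,
    scenarios,
    order: CellOrder | None = None,
    markers: MarkerSet | None = None,
    posterior: np.ndarray | None = None,
) -> pd.DataFrame:
    """Run every scenario x replicate and return tidy results
    (mode, level, replicate, mse).

    The full-data reference profile uses the supplied fixed ``order`` (or
    ``posterior`` for soft zone assignments). Scenarios with ``reorder=True``
    need ``markers`` to rerun Wave-Crest per replicate; the reversal-minimum
    rule then applies when scoring."""
    if posterior is not None:
        reference = scale_profile(posterior_weighted_profile(matrix, posterior))
    elif order is not None:
        reference = _scaled_profile(matrix, order, scenarios[0].statistic)
    else:
        raise ValueError("supply either a cell order or a posterior matrix")

    rows = []
    for scn in scenarios:
        if scn.reorder and markers is None:
            raise ValueError("reorder=True requires a MarkerSet")
        if order is not None and scn.statistic != reference.statistic:
            ref = _scaled_profile(matrix, order, scn.statistic)
        else:
            ref = reference
        for rep in range(scn.replicates):
            rep_seed = (scn.seed, 0 if scn.mode == "cells" else 1, rep)
            rng_seed = np.random.default_rng(rep_seed).integers(2**31)
            if scn.mode == "cells":
                rng = np.random.default_rng(rng_seed)
                keep = np.sort(rng.choice(matrix.n_cells, size=int(scn.level), replace=False))
                sub = matrix.subset_cells(keep)
                if posterior is not None:
                    post_sub = posterior[keep]
                    post_sub = post_sub / post_sub.sum(axis=1, keepdims=True)
                    perturbed = scale_profile(posterior_weighted_profile(sub, post_sub))
                    allow_rev = False
                elif scn.reorder:
                    new_order = wavecrest_order(sub, markers, seed=int(rng_seed))
                    perturbed = _scaled_profile(sub, new_order, scn.statistic)
                    allow_rev = True
                else:
                    perturbed = _scaled_profile(sub, _restrict_order(order, keep), scn.statistic)
                    allow_rev = False
            else:  # depth
                thinned = downsample_depth_multinomial(matrix, scn.level, seed=int(rng_seed))
                if posterior is not None:
                    perturbed = scale_profile(posterior_weighted_profile(thinned, posterior))
                    allow_rev = False
                elif scn.reorder:
                    new_order = wavecrest_order(thinned, markers, seed=int(rng_seed))
                    perturbed = _scaled_profile(thinned, new_order, scn.statistic)
                    allow_rev = True
                else:
                    perturbed = _scaled_profile(thinned, order, scn.statistic)
                    allow_rev = False
            mse = profile_mse(
                ref, perturbed,
                gene_sample=scn.n_mse_genes,
                seed=int(rng_seed),
                allow_reversal=allow_rev,
            )
            rows.append((scn.mode, scn.level, rep, mse))
    return pd.DataFrame(rows, columns=["mode", "level", "replicate", "mse"])


def summarize_tradeoff(results: pd.DataFrame) -> pd.DataFrame:
    """Mean/sd of the replicate MSEs per (mode, level)."""
    return (
        results.groupby(["mode", "level"])["mse"]
        .agg(["mean", "std", "count"])
        .reset_index()
        .rename(columns={"mean": "mse_mean", "std": "mse_sd", "count": "replicates"})
    )
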