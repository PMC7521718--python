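"""Nine-group zonation profiles, zonation tests, cross-dataset comparison.

Ordered cells are divided into nine contiguous, equally sized groups (group 1
pericentral) standing in for the nine lobule layers; per-gene group summaries
(mean or median, or posterior-probability-weighted means for soft zone
assignments) are scaled to [0,1] per gene so datasets with very different
dynamic ranges can be compared. Zonation calls use per-gene OLS of expression
on the cell order with a slope t-test and Benjamini-Hochberg adjustment, or a
Kruskal-Wallis test across groups; cross-dataset agreement is summarized by
per-gene Pearson correlation of the scaled profiles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.optimize
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .containers import CellOrder, ExpressionMatrix, ZonationProfile

N_ZONES = 9


def assign_groups(order: CellOrder, k: int = N_ZONES) -> np.ndarray:
    """Contiguous group label (1..k, 1 = pericentral) per cell, indexed by
    original cell index. With n = q*k + r, the first r groups get q+1 cells."""
    n = order.n_cells
    if n < k:
        raise ValueError(f"need at least {k} cells for {k} groups, got {n}")
    q, r = divmod(n, k)
    sizes = np.array([q + 1] * r + [q] * (k - r))
    labels_along_order = np.repeat(np.arange(1, k + 1), sizes)
    labels = np.empty(n, dtype=int)
    labels[order.permutation] = labels_along_order
    return labels


def group_profile(matrix: ExpressionMatrix, groups: np.ndarray, statistic: str = "mean") -> ZonationProfile:
    """Per-gene group summary (mean or median) over the cells of each group."""
    if statistic not in ("mean", "median"):
        raise ValueError("statistic must be 'mean' or 'median'")
    labels = np.unique(groups)
    out = np.empty((matrix.n_genes, len(labels)))
    for j, lab in enumerate(labels):
        cols = groups == lab
        if not cols.any():
            raise ValueError(f"group {lab} is empty")
        block = matrix.values[:, cols]
        out[:, j] = block.mean(axis=1) if statistic == "mean" else np.median(block, axis=1)
    return ZonationProfile(matrix.gene_ids, out, statistic=statistic, scaled=False)


def posterior_weighted_profile(matrix: ExpressionMatrix, posterior: np.ndarray) -> ZonationProfile:
    """Soft-assignment profile: Z_ij = sum_c P(c in j) x_ic / sum_c P(c in j).

    ``posterior`` is cells x zones with rows summing to 1; reduces to the
    mean group profile when the posterior is hard (0/1)."""
    posterior = np.asarray(posterior, dtype=float)
    if posterior.shape[0] != matrix.n_cells:
        raise ValueError("posterior rows must match cells")
    if not np.allclose(posterior.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("posterior rows must sum to 1 within 1e-6")
    mass = posterior.sum(axis=0)
    if np.any(mass == 0):
        raise ValueError("a zone has zero total posterior mass")
    values = (matrix.values @ posterior) / mass
    return ZonationProfile(matrix.gene_ids, values, statistic="posterior_weighted", scaled=False)


def scale_profile(profile: ZonationProfile) -> ZonationProfile:
    """Scale each gene's profile to [0, 1]; degenerate (constant) rows map to
    all zeros with a warning."""
    if profile.scaled:
        raise ValueError("profile is already scaled")
    lo = profile.values.min(axis=1, keepdims=True)
    hi = profile.values.max(axis=1, keepdims=True)
    span = hi - lo
    degenerate = span.ravel() == 0
    if degenerate.any():
        warnings.warn(f"{int(degenerate.sum())} constant profile row(s) scaled to all zeros")
    safe = np.where(span == 0, 1.0, span)
    values = np.where(span == 0, 0.0, (profile.values - lo) / safe)
    return ZonationProfile(profile.gene_ids, values, statistic=profile.statistic, scaled=True)


def _smoother_matrix(n: int, lam: float) -> np.ndarray:
    """Natural cubic smoothing-spline hat matrix (I + lam*K)^-1 on the
    equispaced knots 1..n (Green-Silverman penalty K = D' W^-1 D)."""
    h = 1.0
    D = np.zeros((n - 2, n))
    for i in range(n - 2):
        D[i, i], D[i, i + 1], D[i, i + 2] = 1 / h, -2 / h, 1 / h
    W = np.zeros((n - 2, n - 2))
    np.fill_diagonal(W, 2 * h / 3)
    idx = np.arange(n - 3)
    W[idx, idx + 1] = W[idx + 1, idx] = h / 6
    K = D.T @ np.linalg.solve(W, D)
    return np.linalg.inv(np.eye(n) + lam * K)


def smooth_profile(profile: ZonationProfile, effective_df: float = 4.0, tol: float = 0.1) -> np.ndarray:
    """Cubic smoothing spline over group indices with the smoothing parameter
    chosen so the trace of the hat matrix equals ``effective_df`` within
    ``tol`` (the smooth.spline df convention). Display/fitting only — never
    used in a statistical decision. Returns genes x groups fitted values."""
    n = profile.n_groups
    if not 1 < effective_df < n:
        raise ValueError(f"effective_df must lie in (1, {n})")
    if effective_df <= 2:
        raise ValueError("a cubic smoothing spline cannot reach effective df <= 2")
    if effective_df >= n - 1e-9:
        return profile.values.copy()

    def df_of(log_lam: float) -> float:
        return float(np.trace(_smoother_matrix(n, 10.0**log_lam)))

    lo, hi = -12.0, 12.0
    if df_of(lo) < effective_df:  # essentially interpolating already
        S = _smoother_matrix(n, 10.0**lo)
    else:
        log_lam = scipy.optimize.brentq(lambda t: df_of(t) - effective_df, lo, hi, xtol=1e-10)
        S = _smoother_matrix(n, 10.0**log_lam)
        if abs(np.trace(S) - effective_df) > tol:
            raise RuntimeError("could not match the target effective df")
    return profile.values @ S.T


def correlate_profiles(profile_a: ZonationProfile, profile_b: ZonationProfile, gene_subset=None):
    """Per-gene Pearson r over the paired group values of two scaled
    profiles, plus their median. Genes degenerate (constant) in either
    profile are dropped and reported.

    Returns (DataFrame[gene_id, r], median_r, dropped_gene_ids)."""
    if not (profile_a.scaled and profile_b.scaled):
        raise ValueError("both profiles must be scaled")
    shared = [g for g in profile_a.gene_ids if g in set(profile_b.gene_ids)]
    if gene_subset is not None:
        subset = set(gene_subset)
        shared = [g for g in shared if g in subset]
    if not shared:
        raise ValueError("no shared genes between the profiles")
    ia = {g: i for i, g in enumerate(profile_a.gene_ids)}
    ib = {g: i for i, g in enumerate(profile_b.gene_ids)}
    rows, dropped = [], []
    for g in shared:
        va, vb = profile_a.values[ia[g]], profile_b.values[ib[g]]
        if va.std() == 0 or vb.std() == 0:
            dropped.append(g)
            continue
        rows.append((g, float(np.corrcoef(va, vb)[0, 1])))
    table = pd.DataFrame(rows, columns=["gene_id", "r"])
    median_r = float(table["r"].median()) if len(table) else np.nan
    return table, median_r, dropped


def test_zonation_linear(matrix: ExpressionMatrix, order: CellOrder, alpha: float = 0.01) -> pd.DataFrame:
    """Per-gene OLS of expression on position 1..n with a two-sided t-test on
    the slope, BH adjustment across genes, and direction by slope sign for
    genes with adjusted p < ``alpha`` (positive = periportal). Constant genes
    get slope 0 / p 1; zero-residual fits saturate at the smallest
    representable p. The per-gene linear-fit MSE is recorded for ranking."""
    n = order.n_cells
    if n < 4:
        raise ValueError("need at least 4 cells to test slopes")
    x = np.arange(1, n + 1, dtype=float)
    y = matrix.values[:, order.permutation]
    sxx = np.sum((x - x.mean()) ** 2)
    ybar = y.mean(axis=1)
    slope = ((y - ybar[:, None]) @ (x - x.mean())) / sxx
    intercept = ybar - slope * x.mean()
    resid = y - (intercept[:, None] + slope[:, None] * x)
    ss_res = np.sum(resid**2, axis=1)
    fit_mse = ss_res / n

    tiny = np.finfo(float).tiny
    constant = y.std(axis=1) == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(ss_res / (n - 2) / sxx)
        t = slope / se
    p = 2.0 * scipy.stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.isnan(p) | (se == 0), tiny, p)  # exact fits saturate
    p = np.where(constant, 1.0, np.maximum(p, tiny))
    slope = np.where(constant, 0.0, slope)

    adj_p = multipletests(p, method="fdr_bh")[1]
    direction = np.where(
        adj_p < alpha, np.where(slope > 0, "periportal", "pericentral"), "none"
    )
    direction = np.where(constant, "none", direction)
    return pd.DataFrame(
        {
            "gene_id": matrix.gene_ids,
            "slope": slope,
            "p_value": p,
            "adj_p": adj_p,
            "direction": direction,
            "fit_mse": fit_mse,
        }
    )


def test_zonation_kruskal(matrix: ExpressionMatrix, groups: np.ndarray) -> pd.DataFrame:
    """Per-gene Kruskal-Wallis H (tie-corrected) across zonation groups with
    chi-square p on k-1 df. All-identical observations give H=0, p=1."""
    labels = np.unique(groups)
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    masks = [groups == lab for lab in labels]
    if any(not m.any() for m in masks):
        raise ValueError("empty group")
    H = np.empty(matrix.n_genes)
    p = np.empty(matrix.n_genes)
    for i in range(matrix.n_genes):
        samples = [matrix.values[i, m] for m in masks]
        if np.ptp(matrix.values[i, :]) == 0:
            H[i], p[i] = 0.0, 1.0  # all ties convention
            continue
        H[i], p[i] = scipy.stats.kruskal(*samples)
    return pd.DataFrame({"gene_id": matrix.gene_ids, "H": H, "p_value": p})


@dataclass
class ComparisonReport:
    """Cross-dataset zonation comparison: genes shared-significant in all
    datasets, per-ordered-pair exclusively detected genes, and profile
    correlations for the shared set."""

    shared: list
    exclusive: dict  # (A, B) -> genes significant in A, all-zero in B
    correlations: pd.DataFrame | None  # columns: pair, gene_id, r


def compare_datasets(
    results: dict,
    matrices: dict,
    profiles: dict | None = None,
    alpha: float = 0.1,
) -> ComparisonReport:
    """Compare zonation calls across datasets over a shared gene universe.

    ``results`` maps dataset name -> test table (gene_id, adj_p, ...);
    ``matrices`` maps name -> ExpressionMatrix (for zero-detection checks);
    ``profiles`` optionally maps name -> scaled ZonationProfile for per-gene
    correlations of the shared-significant set."""
    if len(results) < 2:
        raise ValueError("need at least two datasets")
    universes = [set(m.gene_ids) for m in matrices.values()]
    shared_universe = set.intersection(*universes)
    if not shared_universe:
        raise ValueError("datasets have disjoint gene universes")

    sig = {
        name: set(tab.loc[tab["adj_p"] < alpha, "gene_id"]) & shared_universe
        for name, tab in results.items()
    }
    shared = sorted(set.intersection(*sig.values()))

    zero_detect = {}
    for name, m in matrices.items():
        zero_rows = m.gene_ids[(m.values > 0).sum(axis=1) == 0]
        zero_detect[name] = set(zero_rows)
    exclusive = {}
    for a in results:
        for b in results:
            if a == b:
                continue
            exclusive[(a, b)] = sorted(sig[a] & zero_detect[b])

    corr = None
    if profiles is not None and shared:
        rows = []
        names = sorted(profiles)
        for i, a in enumerate(names):
            for b in names[i + 1 :]:
                table, _, _ = correlate_profiles(profiles[a], profiles[b], gene_subset=shared)
                table = table.assign(pair=f"{a}|{b}")
                rows.append(table)
        corr = pd.concat(rows, ignore_index=True)[["pair", "gene_id", "r"]]
    return ComparisonReport(shared=shared, exclusive=exclusive, correlations=corr)
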