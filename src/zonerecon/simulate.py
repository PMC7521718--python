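"""Synthetic zonated expression data for testing the reconstruction pipeline.

Cells carry a latent position z in [0,1] along the pericentral (0) to
periportal (1) axis. Each gene has a mean-profile shape over z:

    increasing: baseline + amplitude * z
    decreasing: baseline + amplitude * (1 - z)
    peaked:     baseline + amplitude * exp(-(z - center)^2 / (2 width^2))
    flat:       baseline

Counts are drawn per cell as multinomial(N_c, p_.c) with p proportional to the
profile means, N_c from a log-normal depth distribution, and optional gamma
perturbation of the per-cell probabilities giving negative-binomial-like
overdispersion. Two shipped protocol regimes emulate a deep full-length
protocol (few cells, high depth) and a shallow droplet/UMI protocol (many
cells, low depth).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .containers import (
    PERICENTRAL,
    PERIPORTAL,
    RAW_COUNTS,
    ExpressionMatrix,
    MarkerSet,
)

SHAPES = ("increasing", "decreasing", "peaked", "flat")


@dataclass
class ProtocolParams:
    """Sequencing-regime parameters: number of cells and per-cell depth.

    Depth is log-normal with the given mean and log-scale dispersion;
    ``overdispersion`` is the variance of the mean-1 gamma factor applied to
    each gene/cell probability (0 = pure multinomial sampling).
    """

    n_cells: int
    depth_mean: float
    depth_dispersion: float = 0.3
    overdispersion: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 2:
            raise ValueError("n_cells must be at least 2")
        if self.depth_mean <= 0:
            raise ValueError("depth_mean must be positive")
        if self.overdispersion < 0 or self.depth_dispersion < 0:
            raise ValueError("dispersions must be non-negative")


#: Shipped desk-scale regimes: "deep" emulates a Fluidigm C1/Smart-seq-like
#: run (66 cells, high depth); "shallow" a droplet/UMI-like run (606 cells,
#: 3-12k counts per cell). Depths are scaled down from real full-length data.
DEFAULT_REGIMES = {
    "deep": ProtocolParams(n_cells=66, depth_mean=1e5, depth_dispersion=0.3,
                           overdispersion=0.3, seed=11),
    "shallow": ProtocolParams(n_cells=606, depth_mean=5e3, depth_dispersion=0.3,
                              overdispersion=0.3, seed=12),
}


@dataclass
class SyntheticTruth:
    """Ground truth: latent cell positions plus per-gene profile parameters."""

    cell_positions: np.ndarray  # in [0,1]; 0 = pericentral
    gene_specs: pd.DataFrame  # gene_id, shape, baseline, amplitude, center, width, is_marker, direction, is_spike
    position_mode: str = "equispaced"

    def __post_init__(self) -> None:
        self.cell_positions = np.asarray(self.cell_positions, dtype=float)
        if np.any((self.cell_positions < 0) | (self.cell_positions > 1)):
            raise ValueError("cell positions must lie in [0, 1]")
        nonflat = self.gene_specs["shape"] != "flat"
        if np.any(self.gene_specs.loc[nonflat, "amplitude"] <= 0):
            raise ValueError("amplitudes must be positive")
        mk = self.gene_specs["is_marker"]
        bad = mk & ~self.gene_specs["shape"].isin(["increasing", "decreasing"])
        if bad.any():
            raise ValueError("marker genes must have monotone shapes")

    @property
    def n_genes(self) -> int:
        return len(self.gene_specs)

    @property
    def n_cells(self) -> int:
        return len(self.cell_positions)

    @property
    def gene_ids(self) -> np.ndarray:
        return self.gene_specs["gene_id"].to_numpy(object)

    def markers(self) -> MarkerSet:
        mk = self.gene_specs[self.gene_specs["is_marker"]]
        return MarkerSet(mk[["gene_id", "direction"]].reset_index(drop=True))

    def profile_means(self, z=None) -> np.ndarray:
        """Mean profile mu_i(z) for every gene at the given positions
        (default: the truth's own cell positions). Shape (genes, len(z))."""
        z = self.cell_positions if z is None else np.asarray(z, dtype=float)
        g = self.gene_specs
        base = g["baseline"].to_numpy()[:, None]
        amp = g["amplitude"].to_numpy()[:, None]
        mu = np.broadcast_to(base, (self.n_genes, z.size)).copy()
        shape = g["shape"].to_numpy()
        inc, dec, pk = shape == "increasing", shape == "decreasing", shape == "peaked"
        mu[inc] += amp[inc] * z[None, :]
        mu[dec] += amp[dec] * (1.0 - z[None, :])
        if pk.any():
            c = g["center"].to_numpy()[pk, None]
            w = g["width"].to_numpy()[pk, None]
            mu[pk] += amp[pk] * np.exp(-((z[None, :] - c) ** 2) / (2 * w**2))
        return mu

    def with_positions(self, positions: np.ndarray) -> "SyntheticTruth":
        return replace(self, cell_positions=np.asarray(positions, dtype=float))


def _draw_positions(n_cells: int, mode: str, rng: np.random.Generator) -> np.ndarray:
    if mode == "equispaced":
        return np.linspace(0.0, 1.0, n_cells)
    if mode == "uniform":
        return np.sort(rng.uniform(0.0, 1.0, size=n_cells))
    raise ValueError(f"unknown position mode {mode!r}")


def generate_truth(
    n_genes: int,
    n_cells: int,
    shape_mix: dict | None = None,
    seed: int = 0,
    n_markers: int = 15,
    n_spikes: int = 0,
    position_mode: str = "equispaced",
    marker_amplitude_boost: float = 5.0,
    marker_baseline_shrink: float = 0.2,
) -> SyntheticTruth:
    """Draw a reproducible ground truth.

    ``shape_mix`` maps shape names to proportions summing to 1 (default
    0.2/0.2/0.1/0.5 over increasing/decreasing/peaked/flat). Markers are drawn
    only from monotone genes, half periportal (increasing) and half
    pericentral (decreasing); with an odd count the periportal side gets the
    extra marker, matching the real 7+8 marker panel. Marker genes get a
    boosted amplitude and shrunken baseline so they are strongly zonated and
    well expressed, as canonical zonation markers are.
    """
    if n_genes < 1 or n_cells < 1:
        raise ValueError("n_genes and n_cells must be positive")
    shape_mix = shape_mix or {"increasing": 0.2, "decreasing": 0.2, "peaked": 0.1, "flat": 0.5}
    if set(shape_mix) - set(SHAPES):
        raise ValueError(f"unknown shapes: {set(shape_mix) - set(SHAPES)}")
    probs = np.array([shape_mix.get(s, 0.0) for s in SHAPES], dtype=float)
    if probs.min() < 0 or abs(probs.sum() - 1.0) > 1e-9:
        raise ValueError("shape_mix proportions must be non-negative and sum to 1")

    rng = np.random.default_rng(seed)
    shapes = rng.choice(SHAPES, size=n_genes, p=probs)

    baseline = rng.lognormal(mean=0.0, sigma=1.0, size=n_genes)
    amplitude = rng.lognormal(mean=1.0, sigma=0.5, size=n_genes)
    amplitude[shapes == "flat"] = 0.0
    center = rng.uniform(0.2, 0.8, size=n_genes)
    width = rng.uniform(0.1, 0.25, size=n_genes)

    n_pp = (n_markers + 1) // 2  # periportal (increasing) half, extra here
    n_pc = n_markers - n_pp
    inc_idx = np.flatnonzero(shapes == "increasing")
    dec_idx = np.flatnonzero(shapes == "decreasing")
    if len(inc_idx) < n_pp or len(dec_idx) < n_pc:
        raise ValueError("not enough monotone genes to designate markers")
    pp = rng.choice(inc_idx, size=n_pp, replace=False)
    pc = rng.choice(dec_idx, size=n_pc, replace=False)
    is_marker = np.zeros(n_genes, dtype=bool)
    is_marker[pp] = is_marker[pc] = True
    direction = np.full(n_genes, "", dtype=object)
    direction[pp], direction[pc] = PERIPORTAL, PERICENTRAL
    amplitude[is_marker] *= marker_amplitude_boost
    baseline[is_marker] *= marker_baseline_shrink

    is_spike = np.zeros(n_genes, dtype=bool)
    gene_ids = np.array([f"G{i:05d}" for i in range(n_genes)], dtype=object)
    if n_spikes:
        if n_spikes >= n_genes:
            raise ValueError("n_spikes must be smaller than n_genes")
        spike_idx = np.flatnonzero(~is_marker)[-n_spikes:]
        is_spike[spike_idx] = True
        shapes[spike_idx] = "flat"
        amplitude[spike_idx] = 0.0
        gene_ids[spike_idx] = [f"ERCC-{i:04d}" for i in range(n_spikes)]

    specs = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "shape": shapes,
            "baseline": baseline,
            "amplitude": amplitude,
            "center": np.where(shapes == "peaked", center, np.nan),
            "width": np.where(shapes == "peaked", width, np.nan),
            "is_marker": is_marker,
            "direction": direction,
            "is_spike": is_spike,
        }
    )
    positions = _draw_positions(n_cells, position_mode, rng)
    return SyntheticTruth(positions, specs, position_mode=position_mode)


def simulate_counts(truth: SyntheticTruth, params: ProtocolParams) -> ExpressionMatrix:
    """Draw a raw-count matrix: per cell, multinomial(N_c, p_.c) with
    p proportional to the (optionally gamma-perturbed) profile means."""
    rng = np.random.default_rng(params.seed)
    mu = truth.profile_means()  # genes x cells
    col_sums = mu.sum(axis=0)
    if np.any(col_sums <= 0):
        raise ValueError("degenerate probability vector: a cell has all-zero profile means")

    sigma = params.depth_dispersion
    log_mu = np.log(params.depth_mean) - sigma**2 / 2.0
    depths = np.maximum(1, np.round(rng.lognormal(log_mu, sigma, size=truth.n_cells))).astype(int)

    p = mu / col_sums
    if params.overdispersion > 0:
        k = 1.0 / params.overdispersion  # gamma(shape=k, scale=1/k): mean 1, var 1/k
        factors = rng.gamma(k, 1.0 / k, size=p.shape)
        p = p * factors
        p = p / p.sum(axis=0)

    counts = np.empty_like(p)
    for c in range(truth.n_cells):
        counts[:, c] = rng.multinomial(depths[c], p[:, c])
    cell_ids = [f"C{c:04d}" for c in range(truth.n_cells)]
    return ExpressionMatrix(
        values=counts,
        gene_ids=truth.gene_ids,
        cell_ids=cell_ids,
        layer=RAW_COUNTS,
        spike_flags=truth.gene_specs["is_spike"].to_numpy(bool),
    )


def simulate_protocol_set(truth: SyntheticTruth, params_list) -> list[ExpressionMatrix]:
    """Simulate several protocols over one gene universe; each protocol gets
    an independent draw of cell positions (different animals' cells)."""
    params_list = list(params_list)
    if len(params_list) < 2:
        raise ValueError("need at least two protocol parameter sets")
    out = []
    for params in params_list:
        rng = np.random.default_rng((params.seed, 0x5A11))
        pos = _draw_positions(params.n_cells, truth.position_mode, rng)
        out.append(simulate_counts(truth.with_positions(pos), params))
    genes0 = set(out[0].gene_ids)
    if any(set(m.gene_ids) != genes0 for m in out[1:]):
        raise ValueError("protocols must share one gene universe")
    return out


def inject_spikeins(matrix: ExpressionMatrix, spike_fraction, seed: int = 0) -> ExpressionMatrix:
    """Reallocate each cell's total so spike-in rows carry roughly the
    requested fraction of its counts; per-cell totals are preserved."""
    frac = np.broadcast_to(np.asarray(spike_fraction, dtype=float), (matrix.n_cells,))
    if np.any((frac < 0) | (frac >= 1)):
        raise ValueError("spike fractions must lie in [0, 1)")
    if matrix.layer != RAW_COUNTS:
        raise ValueError("spike injection requires raw counts")
    spike_rows = np.flatnonzero(matrix.spike_flags)
    if spike_rows.size == 0:
        raise ValueError("no spike-in rows flagged in the matrix")
    other_rows = np.flatnonzero(~matrix.spike_flags)

    rng = np.random.default_rng(seed)
    values = matrix.values.copy()
    for c in range(matrix.n_cells):
        total = int(round(values[:, c].sum()))
        target = int(round(frac[c] * total))
        values[spike_rows, c] = rng.multinomial(target, np.full(spike_rows.size, 1.0 / spike_rows.size))
        rest = values[other_rows, c]
        rest_total = rest.sum()
        if rest_total > 0:
            values[other_rows, c] = rng.multinomial(total - target, rest / rest_total)
        elif total - target > 0:
            raise ValueError(f"cell {matrix.cell_ids[c]} has no non-spike counts to rescale")
    return ExpressionMatrix(
        values=values,
        gene_ids=matrix.gene_ids,
        cell_ids=matrix.cell_ids,
        layer=RAW_COUNTS,
        spike_flags=matrix.spike_flags.copy(),
    )


def strongly_zonated_genes(truth: SyntheticTruth, min_contrast: float = 0.9) -> list:
    """Genes whose true profile is strongly zonated: monotone shape with the
    zonated component making up at least ``min_contrast`` of the dynamic
    range (amplitude / (amplitude + baseline)). The default 0.9 selects
    marker-grade genes — the synthetic analog of canonical highly regulated
    zonation genes like Cyp2e1 or Glul."""
    g = truth.gene_specs
    mono = g["shape"].isin(["increasing", "decreasing"])
    contrast = g["amplitude"] / (g["amplitude"] + g["baseline"])
    return list(g.loc[mono & (contrast >= min_contrast), "gene_id"])


def write_truth(truth: SyntheticTruth, cells_path, genes_path) -> None:
    """Write the ground truth as two TSVs (cell positions; gene specs)."""
    pd.DataFrame(
        {"cell_id": [f"C{c:04d}" for c in range(truth.n_cells)],
         "position": truth.cell_positions}
    ).to_csv(cells_path, sep="\t", index=False)
    truth.gene_specs.to_csv(genes_path, sep="\t", index=False)
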