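"""Core in-memory containers shared by every pipeline stage.

The canonical orientation throughout the package is genes x cells, matching
the on-disk CSV layout and the 10X MatrixMarket convention. Position / group
index 1 always denotes the pericentral end of the zonation axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

RAW_COUNTS = "raw_counts"
NORMALIZED = "normalized"

PERICENTRAL = "pericentral"
PERIPORTAL = "periportal"


def _as_str_array(ids) -> np.ndarray:
    return np.asarray(list(ids), dtype=object)


def _check_unique(ids: np.ndarray, axis: str) -> None:
    vals, counts = np.unique(ids.astype(str), return_counts=True)
    dups = vals[counts > 1]
    if dups.size:
        raise ValueError(f"duplicate {axis} IDs: {', '.join(map(str, dups[:10]))}")


@dataclass
class ExpressionMatrix:
    """A genes x cells expression matrix with IDs, a layer tag and spike flags.

    Parameters
    ----------
    values
        Non-negative array of shape (n_genes, n_cells).
    gene_ids, cell_ids
        Unique identifiers along each axis.
    layer
        ``"raw_counts"`` or ``"normalized"``.
    spike_flags
        Boolean per gene marking exogenous spike-in rows (e.g. ERCC).
    """

    values: np.ndarray
    gene_ids: np.ndarray
    cell_ids: np.ndarray
    layer: str = RAW_COUNTS
    spike_flags: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = _as_str_array(self.gene_ids)
        self.cell_ids = _as_str_array(self.cell_ids)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (genes x cells)")
        if self.values.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValueError(
                f"shape {self.values.shape} inconsistent with "
                f"{len(self.gene_ids)} genes / {len(self.cell_ids)} cells"
            )
        if np.any(self.values < 0):
            raise ValueError("expression values must be non-negative")
        if self.layer not in (RAW_COUNTS, NORMALIZED):
            raise ValueError(f"unknown layer tag {self.layer!r}")
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.cell_ids, "cell")
        if self.spike_flags is None:
            self.spike_flags = np.zeros(self.n_genes, dtype=bool)
        else:
            self.spike_flags = np.asarray(self.spike_flags, dtype=bool)
            if self.spike_flags.shape != (self.n_genes,):
                raise ValueError("spike_flags length must equal number of genes")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def gene_index(self, gene_ids) -> np.ndarray:
        """Integer row positions of the given gene IDs (error on missing)."""
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in gene_ids if g not in lookup]
        if missing:
            raise KeyError(f"genes not in matrix: {', '.join(map(str, missing[:10]))}")
        return np.array([lookup[g] for g in gene_ids], dtype=int)

    def subset_cells(self, idx) -> "ExpressionMatrix":
        idx = np.asarray(idx)
        return replace(
            self,
            values=self.values[:, idx],
            cell_ids=self.cell_ids[idx],
            spike_flags=self.spike_flags.copy(),
        )

    def subset_genes(self, idx) -> "ExpressionMatrix":
        idx = np.asarray(idx)
        return replace(
            self,
            values=self.values[idx, :],
            gene_ids=self.gene_ids[idx],
            spike_flags=self.spike_flags[idx],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.cell_ids)


@dataclass
class MarkerSet:
    """Zonation marker genes with their axis direction.

    Direction is ``"pericentral"`` (high near the central vein, so expression
    decreases along the pericentral->periportal axis) or ``"periportal"``.
    """

    table: pd.DataFrame  # columns: gene_id, direction

    def __post_init__(self) -> None:
        cols = {"gene_id", "direction"}
        if not cols.issubset(self.table.columns):
            raise ValueError(f"marker table needs columns {cols}")
        if self.table["gene_id"].duplicated().any():
            raise ValueError("duplicate marker gene IDs")
        bad = set(self.table["direction"]) - {PERICENTRAL, PERIPORTAL}
        if bad:
            raise ValueError(f"unknown marker direction(s): {bad}")
        for d in (PERICENTRAL, PERIPORTAL):
            if not (self.table["direction"] == d).any():
                raise ValueError(f"need at least one {d} marker for orientation")

    @classmethod
    def from_pairs(cls, pairs) -> "MarkerSet":
        return cls(pd.DataFrame(pairs, columns=["gene_id", "direction"]))

    @property
    def gene_ids(self) -> list:
        return list(self.table["gene_id"])

    def by_direction(self, direction: str) -> list:
        return list(self.table.loc[self.table["direction"] == direction, "gene_id"])


@dataclass
class CellOrder:
    """A permutation of cell indices; rank 1 along ``permutation`` is the
    pericentral end once ``oriented`` is set."""

    permutation: np.ndarray
    oriented: bool = False

    def __post_init__(self) -> None:
        self.permutation = np.asarray(self.permutation, dtype=int)
        n = len(self.permutation)
        if n and not np.array_equal(np.sort(self.permutation), np.arange(n)):
            raise ValueError("permutation must contain each cell index exactly once")

    @property
    def n_cells(self) -> int:
        return len(self.permutation)

    def positions(self) -> np.ndarray:
        """1-based position of each cell (indexed by original cell index)."""
        pos = np.empty(self.n_cells, dtype=int)
        pos[self.permutation] = np.arange(1, self.n_cells + 1)
        return pos

    def reversed(self) -> "CellOrder":
        return CellOrder(self.permutation[::-1].copy(), oriented=self.oriented)


@dataclass
class ZonationProfile:
    """Per-gene summaries over the nine zonation groups (group 1 pericentral)."""

    gene_ids: np.ndarray
    values: np.ndarray  # genes x n_groups
    statistic: str  # mean | median | posterior_weighted
    scaled: bool = False
    n_groups: int = field(init=False)

    def __post_init__(self) -> None:
        self.gene_ids = _as_str_array(self.gene_ids)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != len(self.gene_ids):
            raise ValueError("profile values must be genes x groups")
        if self.statistic not in ("mean", "median", "posterior_weighted"):
            raise ValueError(f"unknown statistic {self.statistic!r}")
        self.n_groups = self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        cols = [f"z{j}" for j in range(1, self.n_groups + 1)]
        return pd.DataFrame(self.values, index=self.gene_ids, columns=cols)
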