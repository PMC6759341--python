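"""Richness, Shannon-Wiener diversity, Bray-Curtis dissimilarity, rarefaction."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import CountTable, DataError

__all__ = [
    "DissimilarityMatrix",
    "otu_richness",
    "shannon_index",
    "diversity_table",
    "bray_curtis",
    "dissimilarity_matrix",
    "rarefaction_curve",
]


@dataclass
class DissimilarityMatrix:
    """Symmetric pairwise dissimilarities with a zero diagonal."""

    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.sample_ids)
        if v.shape != (n, n):
            raise DataError(f"dissimilarity matrix shape {v.shape} != ({n}, {n})")
        if not np.allclose(v, v.T):
            raise DataError("dissimilarity matrix is not symmetric")
        if not np.allclose(np.diag(v), 0):
            raise DataError("dissimilarity matrix diagonal is not zero")
        self.values = v

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    def condensed(self) -> np.ndarray:
        """Upper-triangle off-diagonal entries in row-major order."""
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.sample_ids)


def otu_richness(column: np.ndarray) -> int:
    """Number of OTUs with a positive count."""
    col = np.asarray(column)
    if col.size and col.min() < 0:
        raise DataError("counts must be non-negative")
    return int(np.count_nonzero(col))


def shannon_index(column: np.ndarray, base: float | None = None) -> float:
    """Shannon-Wiener index H = -sum p_i log p_i over positive cells.

    Natural log by default; pass ``base`` to change the unit.
    """
    col = np.asarray(column, dtype=float)
    if col.size and col.min() < 0:
        raise DataError("counts must be non-negative")
    total = col.sum()
    if total <= 0:
        raise DataError("cannot compute Shannon index of an all-zero column")
    p = col[col > 0] / total
    h = float(-(p * np.log(p)).sum())
    if base is not None:
        h /= np.log(base)
    return h


def diversity_table(table: CountTable, base: float | None = None) -> pd.DataFrame:
    """Per-sample richness and Shannon index as a data frame."""
    rows = []
    for s in table.sample_ids:
        col = table.column(s)
        rows.append(
            {
                "sample_id": s,
                "richness": otu_richness(col),
                "shannon": shannon_index(col, base=base) if col.sum() > 0 else 0.0,
            }
        )
    return pd.DataFrame(rows)


def bray_curtis(x: np.ndarray, y: np.ndarray) -> float:
    """Bray-Curtis dissimilarity: sum|x - y| / sum(x + y)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise DataError(f"length mismatch: {x.shape} vs {y.shape}")
    if (x.size and x.min() < 0) or (y.size and y.min() < 0):
        raise DataError("Bray-Curtis requires non-negative vectors")
    denom = (x + y).sum()
    if denom == 0:
        raise DataError("Bray-Curtis undefined for two all-zero vectors")
    return float(np.abs(x - y).sum() / denom)


def dissimilarity_matrix(table: CountTable) -> DissimilarityMatrix:
    """All pairwise Bray-Curtis dissimilarities among the table's samples."""
    n = len(table.sample_ids)
    if n < 2:
        raise DataError("need at least two samples")
    x = table.counts.astype(float)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = bray_curtis(x[:, i], x[:, j])
    return DissimilarityMatrix(list(table.sample_ids), out)


def rarefaction_curve(
    table: CountTable,
    mode: str,
    grid: list[int],
    reps: int = 100,
    seed: int | np.random.Generator | None = None,
) -> pd.DataFrame:
    """Mean OTU richness as a function of sampling effort.

    ``by_reads`` subsamples every sample's reads to each grid depth (without
    replacement) and averages richness over samples and replicates;
    ``by_samples`` accumulates pooled richness over random sample orderings.
    Returns a frame with columns ``effort`` and ``mean_richness``.
    """
    grid = sorted(int(g) for g in grid)
    if not grid or grid[0] < 1:
        raise DataError("grid must contain positive integers")
    if reps < 1:
        raise DataError("reps must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_samples = len(table.sample_ids)
    if mode == "by_reads":
        min_reads = int(table.column_sums().min())
        if grid[-1] > min_reads:
            raise DataError(
                f"grid point {grid[-1]} exceeds smallest sample depth {min_reads}"
            )
        means = []
        for g in grid:
            rich = []
            for j in range(n_samples):
                col = table.counts[:, j]
                if g == int(col.sum()):
                    rich.extend([otu_richness(col)] * reps)
                    continue
                for _ in range(reps):
                    sub = rng.multivariate_hypergeometric(col, g)
                    rich.append(otu_richness(sub))
            means.append(float(np.mean(rich)))
        return pd.DataFrame({"effort": grid, "mean_richness": means})
    if mode == "by_samples":
        if grid[-1] > n_samples:
            raise DataError(f"grid point {grid[-1]} exceeds {n_samples} samples")
        acc = np.zeros(len(grid))
        presence = (table.counts > 0)
        for _ in range(reps):
            order = rng.permutation(n_samples)
            pooled = np.cumsum(presence[:, order], axis=1) > 0
            rich_at = pooled.sum(axis=0)  # richness of first k samples
            acc += rich_at[np.asarray(grid) - 1]
        return pd.DataFrame({"effort": grid, "mean_richness": acc / reps})
    raise DataError(f"unknown rarefaction mode: {mode!r}")
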