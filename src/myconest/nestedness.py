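"""NODF nestedness: matrix packing, score, column-total-fixed null, z / p.

The score follows the nested-overlap-and-decreasing-fill definition: for an
ordered pair of lines with strictly decreasing positive marginal fills, the
paired score is 100 times the shared presences divided by the smaller fill;
pairs with equal fills, or whose smaller fill is zero, score 0. The statistic
is order-invariant, so packing matters only for display.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import CountTable, DataError

__all__ = [
    "PackedMatrix",
    "NestednessResult",
    "pack_matrix",
    "nodf",
    "null_column_fixed",
    "nodf_significance",
]


def _as_binary(m) -> np.ndarray:
    if isinstance(m, CountTable):
        m = m.counts
    arr = np.asarray(m)
    if arr.ndim != 2:
        raise DataError("expected a 2-D matrix")
    vals = np.unique(arr)
    if not np.all(np.isin(vals, (0, 1))):
        bad = [v for v in vals if v not in (0, 1)][0]
        raise DataError(f"matrix is not binary: found value {bad!r}")
    return arr.astype(np.int64)


@dataclass
class PackedMatrix:
    """Maximally stacked binary matrix plus the permutations that produced it."""

    matrix: np.ndarray
    row_order: np.ndarray  # original row index at each packed position
    column_order: np.ndarray
    row_occurrences: np.ndarray
    column_fills: np.ndarray

    def to_dataframe(self, otu_ids=None, sample_ids=None) -> pd.DataFrame:
        idx = (
            [otu_ids[i] for i in self.row_order]
            if otu_ids is not None
            else list(self.row_order)
        )
        cols = (
            [sample_ids[j] for j in self.column_order]
            if sample_ids is not None
            else list(self.column_order)
        )
        return pd.DataFrame(self.matrix, index=idx, columns=cols)


@dataclass
class NestednessResult:
    nodf_columns: float
    nodf_rows: float
    nodf_total: float
    z: float | None = None
    p: float | None = None
    null_mean: float | None = None
    null_sd: float | None = None
    n_null: int | None = None
    seed: int | None = None
    statistic: str | None = None
    observed: float | None = None


def pack_matrix(m) -> PackedMatrix:
    """Sort columns by fill and rows by occurrence, both descending, stably."""
    arr = _as_binary(m)
    col_order = np.argsort(-arr.sum(axis=0), kind="stable")
    row_order = np.argsort(-arr.sum(axis=1), kind="stable")
    packed = arr[np.ix_(row_order, col_order)]
    return PackedMatrix(
        matrix=packed,
        row_order=row_order,
        column_order=col_order,
        row_occurrences=packed.sum(axis=1),
        column_fills=packed.sum(axis=0),
    )


def _axis_scores(arr: np.ndarray) -> tuple[float, int]:
    """Sum of paired scores over column pairs of ``arr`` and the pair count."""
    fills = arr.sum(axis=0)
    n = len(fills)
    overlap = arr.T @ arr
    i, j = np.triu_indices(n, k=1)
    fi, fj = fills[i], fills[j]
    small = np.minimum(fi, fj)
    valid = (fi != fj) & (small > 0)
    safe = np.where(small > 0, small, 1)
    scores = np.where(valid, 100.0 * overlap[i, j] / safe, 0.0)
    return float(scores.sum()), len(i)


def _nodf_values(arr: np.ndarray) -> tuple[float, float, float]:
    col_sum, n_col_pairs = _axis_scores(arr)
    row_sum, n_row_pairs = _axis_scores(arr.T)
    return (
        col_sum / n_col_pairs,
        row_sum / n_row_pairs,
        (col_sum + row_sum) / (n_col_pairs + n_row_pairs),
    )


def nodf(m) -> NestednessResult:
    """NODF over columns, rows, and the whole matrix (each in [0, 100])."""
    arr = _as_binary(m)
    if arr.shape[0] < 2 or arr.shape[1] < 2:
        raise DataError("NODF needs at least 2 rows and 2 columns")
    arr = pack_matrix(arr).matrix  # order-invariant; packed per convention
    c, r, t = _nodf_values(arr)
    return NestednessResult(nodf_columns=c, nodf_rows=r, nodf_total=t)


def null_column_fixed(m, seed: int | np.random.Generator | None = None) -> np.ndarray:
    """Randomize a binary matrix keeping each column's total fixed.

    Each column's presences are reassigned to a uniformly random subset of
    rows of the same size; row totals are free.
    """
    arr = _as_binary(m)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_rows, n_cols = arr.shape
    fills = arr.sum(axis=0)
    out = np.zeros_like(arr)
    # one random permutation of rows per column via random-key argsort
    order = np.argsort(rng.random((n_rows, n_cols)), axis=0)
    for j in range(n_cols):
        out[order[: fills[j], j], j] = 1
    return out


def nodf_significance(
    m,
    n_null: int = 1_000,
    seed: int | None = None,
    statistic: str = "columns",
) -> NestednessResult:
    """Monte-Carlo test of NODF against the column-total-fixed null model.

    ``n_null`` independent null matrices are scored; z = (obs - null mean) /
    null SD, and the two-sided p counts null deviations from the null mean at
    least as large as the observed deviation, with the add-one convention.
    A significant positive z indicates nestedness, negative anti-nestedness.
    """
    if statistic not in ("columns", "rows", "total"):
        raise DataError(f"unknown statistic: {statistic!r}")
    arr = _as_binary(m)
    if arr.shape[0] < 2 or arr.shape[1] < 2:
        raise DataError("NODF needs at least 2 rows and 2 columns")
    pick = {"columns": 0, "rows": 1, "total": 2}[statistic]
    observed_all = _nodf_values(arr)
    observed = observed_all[pick]
    rng = np.random.default_rng(seed)
    null_vals = np.empty(n_null)
    for i in range(n_null):
        null_vals[i] = _nodf_values(null_column_fixed(arr, rng))[pick]
    null_mean = float(null_vals.mean())
    null_sd = float(null_vals.std(ddof=1))
    if null_sd == 0:
        raise DataError(
            "null distribution is degenerate (SD = 0); z undefined "
            f"(all {n_null} null values equal {null_mean:g})"
        )
    z = (observed - null_mean) / null_sd
    dev_obs = abs(observed - null_mean)
    count = int(np.sum(np.abs(null_vals - null_mean) >= dev_obs - 1e-12))
    p = (count + 1) / (n_null + 1)
    return NestednessResult(
        nodf_columns=observed_all[0],
        nodf_rows=observed_all[1],
        nodf_total=observed_all[2],
        z=float(z),
        p=float(p),
        null_mean=null_mean,
        null_sd=null_sd,
        n_null=n_null,
        seed=seed,
        statistic=statistic,
        observed=float(observed),
    )
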