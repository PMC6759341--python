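"""Correlation, Mantel, one-way PERMANOVA, Tukey HSD letters, logarithmic fit.

Permutation p-values follow the add-one convention (count + 1)/(n_perm + 1),
so the smallest attainable p is 1/(n_perm + 1).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import DataError
from .diversity import DissimilarityMatrix

__all__ = [
    "CorrelationResult",
    "MantelResult",
    "PermanovaResult",
    "LogFitResult",
    "TukeyResult",
    "pearson_correlation",
    "mantel_test",
    "permanova_oneway",
    "anova_tukey",
    "fit_log_model",
    "euclidean_distance_matrix",
]


@dataclass
class CorrelationResult:
    r: float
    p: float
    n: int


@dataclass
class MantelResult:
    r: float
    p: float
    n_perm: int
    seed: int | None
    alternative: str = "greater"
    method: str = "random"


@dataclass
class PermanovaResult:
    pseudo_f: float
    p: float
    df_between: int
    df_within: int
    n_perm: int
    seed: int | None


@dataclass
class LogFitResult:
    intercept: float
    slope: float
    r_squared: float
    p: float
    n: int


@dataclass
class TukeyResult:
    """Group summaries with compact letter display plus the pairwise table."""

    summary: pd.DataFrame  # group, n, mean, se, letters
    pairwise: pd.DataFrame  # group_a, group_b, diff, q, p
    alpha: float = 0.05
    f: float = float("nan")
    f_p: float = float("nan")

    def letters(self) -> dict[str, str]:
        return dict(zip(self.summary["group"], self.summary["letters"]))


def pearson_correlation(x, y) -> CorrelationResult:
    """Pearson r with a two-sided t-test on n - 2 degrees of freedom."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DataError("x and y must be 1-D vectors of equal length")
    if len(x) < 3:
        raise DataError("need at least 3 observations")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise DataError("inputs must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DataError("zero variance in input vector")
    r, p = stats.pearsonr(x, y)
    return CorrelationResult(r=float(r), p=float(p), n=len(x))


def _condensed_r(a: np.ndarray, b: np.ndarray, iu) -> float:
    va, vb = a[iu], b[iu]
    return float(np.corrcoef(va, vb)[0, 1])


def mantel_test(
    a: DissimilarityMatrix,
    b: DissimilarityMatrix,
    n_perm: int = 9_999,
    seed: int | None = None,
    alternative: str = "greater",
    method: str = "random",
) -> MantelResult:
    """Mantel correlation between two distance matrices with permutation p.

    r is the Pearson correlation of the upper-triangle entries; significance
    is assessed by permuting the sample labels of ``b``. ``method="exact"``
    enumerates all n! permutations (identity included) and reports the exact
    fraction as p.
    """
    if a.sample_ids != b.sample_ids:
        raise DataError("distance matrices must share the same sample ids in order")
    n = a.n
    if n < 4:
        raise DataError("Mantel test needs at least 4 samples")
    iu = np.triu_indices(n, k=1)
    if np.ptp(a.values[iu]) == 0 or np.ptp(b.values[iu]) == 0:
        raise DataError("constant distance matrix")
    if alternative not in ("greater", "two-sided"):
        raise DataError(f"unknown alternative: {alternative!r}")
    r_obs = _condensed_r(a.values, b.values, iu)

    def exceeds(r_perm: float) -> bool:
        if alternative == "greater":
            return r_perm >= r_obs - 1e-12
        return abs(r_perm) >= abs(r_obs) - 1e-12

    if method == "exact":
        count = 0
        total = 0
        for perm in itertools.permutations(range(n)):
            bp = b.values[np.ix_(perm, perm)]
            total += 1
            if exceeds(_condensed_r(a.values, bp, iu)):
                count += 1
        return MantelResult(
            r=r_obs, p=count / total, n_perm=total, seed=seed,
            alternative=alternative, method="exact",
        )
    if method != "random":
        raise DataError(f"unknown method: {method!r}")
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        bp = b.values[np.ix_(perm, perm)]
        if exceeds(_condensed_r(a.values, bp, iu)):
            count += 1
    p = (count + 1) / (n_perm + 1)
    return MantelResult(
        r=r_obs, p=p, n_perm=n_perm, seed=seed, alternative=alternative, method="random"
    )


def euclidean_distance_matrix(values, sample_ids: list[str]) -> DissimilarityMatrix:
    """Absolute-difference distance matrix of a single numeric variable."""
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or len(v) != len(sample_ids):
        raise DataError("values must be 1-D and match sample_ids")
    return DissimilarityMatrix(list(sample_ids), np.abs(v[:, None] - v[None, :]))


def _permanova_f(d2: np.ndarray, labels: np.ndarray, groups: np.ndarray) -> float:
    n = d2.shape[0]
    a = len(groups)
    iu = np.triu_indices(n, k=1)
    ss_total = d2[iu].sum() / n
    ss_within = 0.0
    for g in groups:
        idx = np.flatnonzero(labels == g)
        sub = d2[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(len(idx), k=1)].sum() / len(idx)
    ss_between = ss_total - ss_within
    if ss_within == 0:
        return float("inf") if ss_between > 0 else 0.0
    return (ss_between / (a - 1)) / (ss_within / (n - a))


def permanova_oneway(
    d: DissimilarityMatrix,
    groups,
    n_perm: int = 9_999,
    seed: int | None = None,
) -> PermanovaResult:
    """One-way PERMANOVA: pseudo-F from squared distances, p by label permutation.

    SS_total = (1/N) sum_{i<j} d_ij^2, SS_within sums (1/n_g) within-group
    squared distances, and pseudo-F = (SS_between/(a-1)) / (SS_within/(N-a)).
    """
    labels = np.asarray(groups)
    if labels.ndim != 1 or len(labels) != d.n:
        raise DataError("group labels must match the distance matrix samples")
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise DataError("need at least two groups")
    singletons = uniq[counts < 2]
    if len(singletons):
        raise DataError(f"singleton group(s): {list(singletons)}")
    d2 = d.values ** 2
    f_obs = _permanova_f(d2, labels, uniq)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        if _permanova_f(d2, labels[rng.permutation(d.n)], uniq) >= f_obs - 1e-12:
            count += 1
    return PermanovaResult(
        pseudo_f=float(f_obs),
        p=(count + 1) / (n_perm + 1),
        df_between=len(uniq) - 1,
        df_within=d.n - len(uniq),
        n_perm=n_perm,
        seed=seed,
    )


def _compact_letters(groups: list[str], different: set[tuple[str, str]]) -> dict[str, str]:
    # insert-and-absorb: start from one letter spanning all groups, split on
    # each significant pair, drop letter sets contained in another.
    sets: list[set[str]] = [set(groups)]
    for a, b in different:
        new_sets: list[set[str]] = []
        for s in sets:
            if a in s and b in s:
                new_sets.extend([s - {a}, s - {b}])
            else:
                new_sets.append(s)
        sets = [s for s in new_sets if s]
    # absorb: keep only maximal, distinct sets
    uniq_sets: list[set[str]] = []
    for s in sets:
        if s not in uniq_sets and not any(s < t for t in sets):
            uniq_sets.append(s)
    # order letters by the position of their first group in the given order
    uniq_sets.sort(key=lambda s: min(groups.index(g) for g in s))
    letters = {g: "" for g in groups}
    for i, s in enumerate(uniq_sets):
        ch = chr(ord("a") + i)
        for g in groups:
            if g in s:
                letters[g] += ch
    return letters


def anova_tukey(values, groups, alpha: float = 0.05) -> TukeyResult:
    """One-way ANOVA with all-pairs Tukey HSD and a compact letter display.

    Uses the studentized-range distribution with the Tukey-Kramer standard
    error for unequal group sizes. Groups that share no letter differ at
    ``alpha``.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(groups)
    if values.ndim != 1 or values.shape != labels.shape:
        raise DataError("values and groups must be 1-D and aligned")
    uniq = list(pd.unique(labels))
    if len(uniq) < 2:
        raise DataError("need at least two groups")
    by_group = {g: values[labels == g] for g in uniq}
    for g, v in by_group.items():
        if len(v) < 2:
            raise DataError(f"group {g!r} has fewer than 2 observations")
    k = len(uniq)
    n_total = len(values)
    df_within = n_total - k
    ss_within = sum(((v - v.mean()) ** 2).sum() for v in by_group.values())
    if ss_within == 0:
        raise DataError("zero within-group variance everywhere; HSD undefined")
    msw = ss_within / df_within
    grand = values.mean()
    ss_between = sum(len(v) * (v.mean() - grand) ** 2 for v in by_group.values())
    f = (ss_between / (k - 1)) / msw
    f_p = float(stats.f.sf(f, k - 1, df_within))

    rows = []
    for a, b in itertools.combinations(uniq, 2):
        va, vb = by_group[a], by_group[b]
        se = math.sqrt(msw / 2 * (1 / len(va) + 1 / len(vb)))
        q = abs(va.mean() - vb.mean()) / se
        p = float(stats.studentized_range.sf(q, k, df_within))
        rows.append(
            {"group_a": a, "group_b": b, "diff": float(va.mean() - vb.mean()),
             "q": float(q), "p": p}
        )
    pairwise = pd.DataFrame(rows)
    different = {
        (r["group_a"], r["group_b"]) for _, r in pairwise.iterrows() if r["p"] < alpha
    }
    order = sorted(uniq, key=lambda g: -by_group[g].mean())
    letters = _compact_letters(order, different)
    summary = pd.DataFrame(
        [
            {
                "group": g,
                "n": len(by_group[g]),
                "mean": float(by_group[g].mean()),
                "se": float(by_group[g].std(ddof=1) / math.sqrt(len(by_group[g]))),
                "letters": letters[g],
            }
            for g in uniq
        ]
    )
    return TukeyResult(summary=summary, pairwise=pairwise, alpha=alpha, f=float(f), f_p=f_p)


def fit_log_model(x, y) -> LogFitResult:
    """Ordinary least squares of y on ln(x): y = intercept + slope * ln(x)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DataError("x and y must be 1-D vectors of equal length")
    if len(x) < 3:
        raise DataError("need at least 3 observations")
    if np.any(x <= 0):
        raise DataError("x must be strictly positive for a logarithmic fit")
    lx = np.log(x)
    if np.ptp(lx) == 0:
        raise DataError("constant x; logarithmic fit undefined")
    if np.ptp(y) == 0:
        # flat response: zero slope explains nothing of (zero) variance
        return LogFitResult(
            intercept=float(y[0]), slope=0.0, r_squared=0.0, p=1.0, n=len(x)
        )
    res = stats.linregress(lx, y)
    return LogFitResult(
        intercept=float(res.intercept),
        slope=float(res.slope),
        r_squared=float(res.rvalue) ** 2,
        p=float(res.pvalue),
        n=len(x),
    )
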