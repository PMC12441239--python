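"""Stand classification from structural diversity: log transform, redundancy
filtering, PCA, Ward clustering, and cross-type comparisons (ANOVA + Tukey).

The feature matrix has one row per plot and one column per diversity index
(a subset of W, U, M, C, CV, SK, GC, H).  The stages mirror the standard
ordination workflow: natural-log transform for normality (with a recorded
shift for columns that can be non-positive, such as skewness), drop one of
any near-collinear index pair (|Pearson r| ≥ 0.9; the Gini coefficient
outranks CV because the two are largely redundant descriptions of size
inequality), correlation-matrix PCA, Ward hierarchical clustering on the
leading PC scores, then per-variable one-way ANOVA with Tukey–Kramer
multiple comparisons and a compact letter display.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage

from standcarbon.errors import ValidationError

#: Column-priority order used when dropping redundant indices; earlier wins.
#: GC precedes CV so that a collinear (CV, GC) pair resolves to GC.  Among
#: spatial indices, crowding outranks the rest because it is the only one
#: carrying stand-density information; dominance ranks last since a
#: rank-based size-dominance mean carries almost no between-stand signal.
DEFAULT_PRIORITY = ("GC", "C", "W", "M", "SK", "H", "CV", "U")


def log_transform(matrix: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, float]]:
    """Natural-log transform every column, shifting non-positive columns first.

    Columns whose minimum is ≤ 0 (skewness can be negative) are shifted by
    ``1 − min`` before the log; the shifts applied are returned so the
    transform is invertible and auditable.
    """
    out = matrix.astype(float).copy()
    shifts: dict[str, float] = {}
    for col in out.columns:
        col_min = out[col].min()
        if col_min <= 0:
            shift = 1.0 - col_min
            out[col] = out[col] + shift
            shifts[col] = float(shift)
        out[col] = np.log(out[col])
    return out, shifts


def redundancy_filter(
    matrix: pd.DataFrame,
    threshold: float = 0.9,
    priority: Sequence[str] = DEFAULT_PRIORITY,
) -> tuple[pd.DataFrame, list[tuple[str, str, float]]]:
    """Drop the lower-priority column of every near-collinear pair.

    Pairs with |Pearson r| ≥ ``threshold`` are visited in descending |r|;
    if both columns are still present, the lower-priority one is dropped.
    Returns the filtered matrix and ``(dropped, kept, r)`` records.
    Idempotent: a second pass drops nothing.
    """
    if matrix.shape[1] < 2:
        return matrix.copy(), []
    rank = {c: i for i, c in enumerate(priority)}
    order = {c: rank.get(c, len(priority) + i) for i, c in enumerate(matrix.columns)}
    corr = matrix.corr()
    pairs = sorted(
        ((abs(corr.loc[a, b]), a, b) for a, b in combinations(matrix.columns, 2)),
        reverse=True,
    )
    alive = set(matrix.columns)
    dropped: list[tuple[str, str, float]] = []
    for r, a, b in pairs:
        if r < threshold:
            break
        if a in alive and b in alive:
            keep, drop = (a, b) if order[a] < order[b] else (b, a)
            alive.discard(drop)
            dropped.append((drop, keep, float(corr.loc[a, b])))
    kept_cols = [c for c in matrix.columns if c in alive]
    return matrix[kept_cols].copy(), dropped


@dataclass(frozen=True)
class PCAResult:
    """Correlation-matrix PCA of a plot × index feature matrix."""

    scores: pd.DataFrame  # plots × PCs
    loadings: pd.DataFrame  # variables × PCs, orthonormal columns
    explained_variance: np.ndarray  # eigenvalues, descending
    explained_ratio: np.ndarray  # eigenvalues / n_variables

    def n_pcs_for(self, retain_variance: float) -> int:
        """Smallest number of leading PCs whose shares sum to ≥ the target."""
        cum = np.cumsum(self.explained_ratio)
        return int(np.searchsorted(cum, retain_variance - 1e-12) + 1)


def pca(matrix: pd.DataFrame, standardize: bool = True) -> PCAResult:
    """PCA via eigen-decomposition of the correlation (or covariance) matrix.

    Columns are z-scored when ``standardize`` is true.  The sign of each
    loading vector is fixed so its largest-magnitude element is positive,
    making the decomposition deterministic.  ``scores @ loadings.T``
    reconstructs the standardized data exactly.
    """
    if matrix.shape[0] < 2 or matrix.shape[1] < 2:
        raise ValidationError("PCA needs at least 2 rows and 2 columns")
    X = matrix.astype(float).to_numpy()
    sd = X.std(axis=0, ddof=1)
    constant = [c for c, s in zip(matrix.columns, sd) if s == 0]
    if constant:
        raise ValidationError(f"constant column(s) cannot be standardized: {constant}")
    if standardize:
        X = (X - X.mean(axis=0)) / sd
    else:
        X = X - X.mean(axis=0)
    S = np.cov(X, rowvar=False, ddof=1)
    eigvals, eigvecs = np.linalg.eigh(S)
    idx = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[idx], 0.0, None)
    eigvecs = eigvecs[:, idx]
    # deterministic sign: largest-|loading| element of each PC positive
    for j in range(eigvecs.shape[1]):
        pivot = np.argmax(np.abs(eigvecs[:, j]))
        if eigvecs[pivot, j] < 0:
            eigvecs[:, j] = -eigvecs[:, j]
    pc_names = [f"PC{j + 1}" for j in range(eigvecs.shape[1])]
    scores = pd.DataFrame(X @ eigvecs, index=matrix.index, columns=pc_names)
    loadings = pd.DataFrame(eigvecs, index=matrix.columns, columns=pc_names)
    return PCAResult(
        scores=scores,
        loadings=loadings,
        explained_variance=eigvals,
        explained_ratio=eigvals / eigvals.sum(),
    )


def cluster_stands(
    scores: pd.DataFrame,
    k: int = 3,
    n_pcs: int | None = None,
    explained_ratio: np.ndarray | None = None,
    retain_variance: float = 0.9,
    method: Literal["ward", "kmeans"] = "ward",
    random_state: int = 0,
) -> pd.Series:
    """Cluster plots into ``k`` structural types on their leading PC scores.

    By default Ward-linkage hierarchical clustering cut at ``k`` groups,
    on the smallest PC set covering ``retain_variance`` of the variance
    (all columns when no shares are given).  Labels are 1..k, renumbered by
    descending cluster mean of the first PC so numbering is deterministic
    and independent of row order.
    """
    if k > scores.shape[0]:
        raise ValidationError(f"cannot form k={k} clusters from {scores.shape[0]} plots")
    if n_pcs is None:
        if explained_ratio is not None:
            cum = np.cumsum(explained_ratio)
            n_pcs = int(np.searchsorted(cum, retain_variance - 1e-12) + 1)
        else:
            n_pcs = scores.shape[1]
    X = scores.iloc[:, :n_pcs].to_numpy(dtype=float)
    if method == "ward":
        raw = fcluster(linkage(X, method="ward"), t=k, criterion="maxclust")
    elif method == "kmeans":
        from sklearn.cluster import KMeans

        raw = KMeans(n_clusters=k, n_init=10, random_state=random_state).fit_predict(X) + 1
    else:
        raise ValidationError(f"unknown clustering method {method!r}")
    pc1 = scores.iloc[:, 0].to_numpy(dtype=float)
    means = {lab: pc1[raw == lab].mean() for lab in np.unique(raw)}
    renumber = {lab: i + 1 for i, lab in enumerate(sorted(means, key=means.get, reverse=True))}
    labels = np.array([renumber[lab] for lab in raw])
    return pd.Series(labels, index=scores.index, name="type")


@dataclass(frozen=True)
class GroupComparison:
    """One-way ANOVA with Tukey–Kramer follow-up for one variable."""

    f_statistic: float
    p_value: float
    df_between: int
    df_within: int
    tukey: pd.DataFrame  # columns: group1, group2, mean_diff, p_adj
    letters: dict[object, str]  # compact letter display at the chosen alpha
    degenerate: bool = False  # all observations equal: F undefined


def _compact_letters(
    groups: Sequence[object],
    means: dict[object, float],
    sig_pairs: set[frozenset],
) -> dict[object, str]:
    """Insert-and-absorb compact letter display.

    Groups sharing a letter are not significantly different.
    """
    columns: list[set] = [set(groups)]
    for pair in sig_pairs:
        a, b = tuple(pair)
        new_cols: list[set] = []
        for col in columns:
            if a in col and b in col:
                new_cols.extend([col - {a}, col - {b}])
            else:
                new_cols.append(col)
        # absorb columns contained in another; drop duplicates
        pruned: list[set] = []
        for col in new_cols:
            if col and not any(col < other for other in new_cols) and col not in pruned:
                pruned.append(col)
        columns = pruned
    columns.sort(key=lambda col: -max(means[g] for g in col))
    letters = {g: "" for g in groups}
    for letter, col in zip("abcdefghijklmnopqrstuvwxyz", columns):
        for g in col:
            letters[g] += letter
    return {g: "".join(sorted(letters[g])) for g in groups}


def compare_groups(
    values: Sequence[float],
    labels: Sequence[object],
    alpha: float = 0.05,
) -> GroupComparison:
    """One-way ANOVA across groups plus Tukey–Kramer pairwise comparisons.

    ``values`` and ``labels`` are parallel per-plot vectors.  Requires at
    least two groups with at least two observations each.  When every
    observation is identical the F statistic is undefined and the result
    carries ``degenerate=True``.
    """
    y = np.asarray(values, dtype=float)
    lab = np.asarray(labels)
    groups = sorted(set(lab.tolist()))
    if len(groups) < 2:
        raise ValidationError("need at least 2 groups")
    samples = [y[lab == g] for g in groups]
    small = [g for g, s in zip(groups, samples) if s.size < 2]
    if small:
        raise ValidationError(f"group(s) with fewer than 2 observations: {small}")

    df_between = len(groups) - 1
    df_within = y.size - len(groups)
    if np.ptp(y) == 0:
        empty = pd.DataFrame(columns=["group1", "group2", "mean_diff", "p_adj"])
        return GroupComparison(
            f_statistic=float("nan"),
            p_value=float("nan"),
            df_between=df_between,
            df_within=df_within,
            tukey=empty,
            letters={g: "a" for g in groups},
            degenerate=True,
        )
    f_stat, p_val = stats.f_oneway(*samples)

    # Tukey–Kramer: studentized-range p-values valid for unequal group sizes
    mse = sum(((s - s.mean()) ** 2).sum() for s in samples) / df_within
    rows = []
    sig_pairs: set[frozenset] = set()
    means = {g: float(s.mean()) for g, s in zip(groups, samples)}
    sizes = {g: s.size for g, s in zip(groups, samples)}
    for g1, g2 in combinations(groups, 2):
        diff = means[g2] - means[g1]
        se = np.sqrt(mse / 2 * (1 / sizes[g1] + 1 / sizes[g2]))
        q = abs(diff) / se if se > 0 else np.inf
        p_adj = float(stats.studentized_range.sf(q, len(groups), df_within))
        rows.append({"group1": g1, "group2": g2, "mean_diff": diff, "p_adj": p_adj})
        if p_adj < alpha:
            sig_pairs.add(frozenset((g1, g2)))
    tukey = pd.DataFrame(rows, columns=["group1", "group2", "mean_diff", "p_adj"])
    letters = _compact_letters(groups, means, sig_pairs)
    return GroupComparison(
        f_statistic=float(f_stat),
        p_value=float(p_val),
        df_between=df_between,
        df_within=df_within,
        tukey=tukey,
        letters=letters,
    )
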