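"""Associations between structural diversity and carbon pools.

Two ingredients: a permutation Mantel test between plot-level distance
matrices (structure-space vs carbon-space), and the plain pairwise Pearson
correlation matrix with t-distribution significance.  Distances default to
Euclidean on z-scored variables; the Mantel null is built by permuting the
plot labels of one matrix (simultaneous row/column permutation), with
p = (1 + #{r_perm ≥ r_obs}) / (1 + n_perm) for the one-sided test.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations, permutations
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from standcarbon.errors import ValidationError


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric plot × plot dissimilarity matrix with provenance tags."""

    values: np.ndarray
    metric: str = "euclidean"
    variables: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValidationError(f"distance matrix must be square, got shape {v.shape}")
        if not np.allclose(v, v.T):
            raise ValidationError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0):
            raise ValidationError("distance matrix must have a zero diagonal")
        if np.any(v < 0):
            raise ValidationError("distances must be non-negative")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def condensed(self) -> np.ndarray:
        """Upper-triangle entries as a flat vector (scipy condensed order)."""
        return squareform(self.values, checks=False)


@dataclass(frozen=True)
class MantelResult:
    """Mantel statistic r, permutation p-value and reproducibility metadata."""

    r: float
    p_value: float
    n_perm: int
    seed: int | None
    tail: str


def distance_matrix(
    matrix: pd.DataFrame,
    metric: str = "euclidean",
    standardize: bool = True,
) -> DistanceMatrix:
    """Pairwise plot distances from a plots × variables feature matrix.

    Columns are z-scored first (so variables on different scales weigh
    equally) unless ``standardize`` is false.
    """
    X = matrix.astype(float).to_numpy()
    if np.isnan(X).any():
        raise ValidationError("feature matrix contains missing values")
    if standardize:
        sd = X.std(axis=0, ddof=1)
        constant = [c for c, s in zip(matrix.columns, sd) if s == 0]
        if constant:
            raise ValidationError(f"constant column(s) cannot be standardized: {constant}")
        X = (X - X.mean(axis=0)) / sd
    d = squareform(pdist(X, metric=metric))
    return DistanceMatrix(values=d, metric=metric, variables=tuple(map(str, matrix.columns)))


def _mantel_r(v1: np.ndarray, v2: np.ndarray) -> float:
    return float(np.corrcoef(v1, v2)[0, 1])


def mantel_test(
    d1: DistanceMatrix,
    d2: DistanceMatrix,
    n_perm: int = 999,
    seed: int | None = None,
    tail: Literal["greater", "less", "two-sided"] = "greater",
    exact: bool = False,
) -> MantelResult:
    """Permutation Mantel test between two plot distance matrices.

    The statistic is the Pearson correlation of the two upper-triangle
    vectors; the null distribution permutes the plot labels of ``d2``
    (rows and columns together).  ``exact=True`` enumerates all n!
    permutations instead of sampling (only sensible for tiny n).
    """
    if d1.n != d2.n:
        raise ValidationError(f"dimension mismatch: {d1.n} vs {d2.n}")
    if d1.n < 4:
        raise ValidationError(f"Mantel test needs at least 4 plots, got {d1.n}")
    if n_perm < 1 and not exact:
        raise ValidationError("n_perm must be at least 1")
    v1 = d1.condensed()
    if v1.std() == 0 or d2.condensed().std() == 0:
        raise ValidationError("degenerate distance matrix: zero variance of distances")
    r_obs = _mantel_r(v1, d2.condensed())

    def tail_count(r_perm: float) -> bool:
        if tail == "greater":
            return r_perm >= r_obs
        if tail == "less":
            return r_perm <= r_obs
        return abs(r_perm) >= abs(r_obs)

    if exact:
        perms = list(permutations(range(d2.n)))[1:]  # identity excluded
        hits = sum(
            tail_count(_mantel_r(v1, squareform(d2.values[np.ix_(p, p)], checks=False)))
            for p in perms
        )
        n_used = len(perms)
    else:
        rng = np.random.default_rng(seed)
        hits = 0
        for _ in range(n_perm):
            p = rng.permutation(d2.n)
            hits += tail_count(_mantel_r(v1, squareform(d2.values[np.ix_(p, p)], checks=False)))
        n_used = n_perm
    return MantelResult(
        r=r_obs,
        p_value=(1 + hits) / (1 + n_used),
        n_perm=n_used,
        seed=seed,
        tail=tail,
    )


def correlation_matrix(matrix: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson r with two-sided p-values (t distribution, n−2 df).

    Pairs involving a constant column get NaN r and p (flagged, not fatal).
    Returns ``(r, p)`` DataFrames with unit / zero diagonals.
    """
    if matrix.shape[0] < 3:
        raise ValidationError("correlation matrix needs at least 3 rows")
    cols = list(matrix.columns)
    n = matrix.shape[0]
    r = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    p = pd.DataFrame(np.zeros((len(cols), len(cols))), index=cols, columns=cols)
    X = matrix.astype(float)
    sd = X.std(ddof=1)
    for a, b in combinations(cols, 2):
        if sd[a] == 0 or sd[b] == 0:
            r_ab, p_ab = np.nan, np.nan
        else:
            r_ab = float(np.corrcoef(X[a], X[b])[0, 1])
            if abs(r_ab) >= 1.0:
                p_ab = 0.0
            else:
                t = r_ab * np.sqrt((n - 2) / (1 - r_ab**2))
                p_ab = float(2 * stats.t.sf(abs(t), n - 2))
        r.loc[a, b] = r.loc[b, a] = r_ab
        p.loc[a, b] = p.loc[b, a] = p_ab
    return r, p


def mantel_table(
    structure_sets: dict[str, pd.DataFrame],
    pool_vectors: pd.DataFrame,
    n_perm: int = 999,
    seed: int | None = None,
    metric: str = "euclidean",
    adjust: Literal["none", "bh"] = "none",
) -> pd.DataFrame:
    """Mantel tests of each structure variable set against each carbon pool.

    ``structure_sets`` maps a label (e.g. ``spatial``, ``nonspatial``) to a
    plots × variables matrix; ``pool_vectors`` holds one column per carbon
    pool.  Returns a tidy table (variable_set, pool, r, p[, p_adj]); the
    optional Benjamini–Hochberg adjustment spans the whole table.
    """
    rows = []
    rng = np.random.default_rng(seed)
    for set_name, feats in structure_sets.items():
        d_struct = distance_matrix(feats, metric=metric)
        for pool in pool_vectors.columns:
            d_pool = distance_matrix(pool_vectors[[pool]], metric=metric)
            sub_seed = int(rng.integers(0, 2**31 - 1))
            res = mantel_test(d_struct, d_pool, n_perm=n_perm, seed=sub_seed)
            rows.append({"variable_set": set_name, "pool": pool, "r": res.r, "p": res.p_value})
    table = pd.DataFrame(rows, columns=["variable_set", "pool", "r", "p"])
    if adjust == "bh":
        from statsmodels.stats.multitest import multipletests

        table["p_adj"] = multipletests(table["p"], method="fdr_bh")[1]
    return table
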