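"""Diameter-based (non-spatial) structural diversity of a stand.

Four statistics computed from the DBH list of a plot:

* CV — coefficient of variation of DBH (sample sd over mean),
* SK — skewness of the DBH distribution (moment estimator ``g1`` by
  default; ``b1`` and the bias-adjusted ``G1`` are selectable because
  statistics packages disagree on which one "skewness" means),
* GC — Gini coefficient of per-tree basal area, the inequality of how
  stand basal area is shared among stems,
* H — Shannon-Wiener diversity of occupied diameter classes (nats),
  5-cm classes anchored at the 5-cm eligibility threshold by default.
"""

from __future__ import annotations

import math
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats

from standcarbon.errors import ValidationError

#: Default diameter-class width (cm) for the Shannon size-diversity index.
DEFAULT_BIN_WIDTH = 5.0
#: Default class origin (cm); classes start at the DBH eligibility floor.
DEFAULT_BIN_ORIGIN = 5.0


def cv_index(dbh) -> float:
    """Coefficient of variation of DBH: sample (n−1) sd divided by the mean."""
    x = np.asarray(dbh, dtype=float)
    if x.size < 2:
        raise ValidationError(f"CV needs at least 2 trees, got {x.size}")
    mean = x.mean()
    if mean <= 0:
        raise ValidationError("CV undefined for non-positive mean DBH")
    return float(x.std(ddof=1) / mean)


def skewness_index(dbh, variant: Literal["g1", "b1", "G1"] = "g1") -> float:
    """Skewness of the DBH distribution.

    ``g1`` is the moment estimator m3 / m2^{3/2} with population (1/n)
    moments; ``b1 = g1 * ((n-1)/n)^{3/2}``; ``G1 = g1 * sqrt(n(n-1))/(n-2)``
    is the bias-adjusted form most spreadsheet and R defaults report.
    """
    x = np.asarray(dbh, dtype=float)
    n = x.size
    if n < 3:
        raise ValidationError(f"skewness needs at least 3 trees, got {n}")
    if np.var(x) == 0:
        raise ValidationError("degenerate distribution: zero variance")
    g1 = float(stats.skew(x, bias=True))
    if variant == "g1":
        return g1
    if variant == "b1":
        return g1 * ((n - 1) / n) ** 1.5
    if variant == "G1":
        return g1 * math.sqrt(n * (n - 1)) / (n - 2)
    raise ValidationError(f"unknown skewness variant {variant!r}")


def gini_index(values) -> float:
    """Gini coefficient of a non-negative sample (here: per-tree basal areas).

    Uses the sorted-index form ``sum((2i - n - 1) x_(i)) / (n sum x)``,
    which equals half the mean absolute pairwise difference divided by the
    mean.  Ranges from 0 (perfect equality) to (n−1)/n.
    """
    x = np.sort(np.asarray(values, dtype=float))
    n = x.size
    if n < 2:
        raise ValidationError(f"Gini needs at least 2 values, got {n}")
    if np.any(x < 0):
        raise ValidationError("Gini requires non-negative values")
    total = x.sum()
    if total == 0:
        raise ValidationError("Gini undefined for an all-zero sample")
    i = np.arange(1, n + 1)
    return float(((2 * i - n - 1) * x).sum() / (n * total))


def basal_area(dbh_cm) -> np.ndarray | float:
    """Cross-sectional stem area at breast height in m²: π (DBH/200)²."""
    x = np.asarray(dbh_cm, dtype=float)
    if np.any(x <= 0):
        raise ValidationError("basal area requires positive DBH")
    out = np.pi * (x / 200.0) ** 2
    return float(out) if out.ndim == 0 else out


def shannon_diameter(
    dbh,
    bin_width: float = DEFAULT_BIN_WIDTH,
    origin: float = DEFAULT_BIN_ORIGIN,
) -> float:
    """Shannon-Wiener diversity (nats) of occupied diameter classes.

    Classes are half-open intervals ``[origin + j w, origin + (j+1) w)``;
    H = −Σ p_j ln p_j over occupied classes.
    """
    x = np.asarray(dbh, dtype=float)
    if x.size == 0:
        raise ValidationError("Shannon index needs at least one tree")
    if np.any(x < origin):
        raise ValidationError(f"all DBH must be ≥ the class origin {origin} cm")
    classes = np.floor((x - origin) / bin_width).astype(int)
    counts = np.bincount(classes)
    p = counts[counts > 0] / x.size
    return float(-(p * np.log(p)).sum())


def shannon_species(species) -> float:
    """Shannon-Wiener diversity (nats) over species labels (optional mode)."""
    labels = pd.Series(list(species))
    if labels.empty:
        raise ValidationError("Shannon index needs at least one tree")
    p = labels.value_counts(normalize=True).to_numpy()
    return float(-(p * np.log(p)).sum())


def diameter_profile(
    dbh,
    bin_width: float = DEFAULT_BIN_WIDTH,
    origin: float = DEFAULT_BIN_ORIGIN,
    skew_variant: Literal["g1", "b1", "G1"] = "g1",
) -> dict[str, float]:
    """All four non-spatial indices for one plot's DBH list.

    Returns ``{"CV": ..., "SK": ..., "GC": ..., "H": ..., "n_trees": ...}``
    with GC computed on per-tree basal areas.
    """
    x = np.asarray(dbh, dtype=float)
    return {
        "CV": cv_index(x),
        "SK": skewness_index(x, skew_variant),
        "GC": gini_index(basal_area(x)),
        "H": shannon_diameter(x, bin_width, origin),
        "n_trees": int(x.size),
    }
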