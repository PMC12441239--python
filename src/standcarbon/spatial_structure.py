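"""Neighbor-based spatial structural diversity of mapped stands.

Four per-tree indices built from a reference tree and its k nearest
neighbors (k = 4 by default, the classic structural-group size):

* uniform angle W — fraction of angles between circularly adjacent
  neighbor rays smaller than the standard angle (72° for k = 4).
  Low W means a regular arrangement, high W a clustered one.
* dominance U — fraction of neighbors with strictly larger DBH than the
  reference tree (high U = reference suppressed by its neighborhood).
* mingling M — fraction of neighbors of a different species.
* crowding C — fraction of neighbors whose crowns overlap the reference
  crown, with crown radius predicted linearly from DBH.

Every per-tree value therefore lies on {0, 1/k, 2/k, ..., 1}; stand-level
values are arithmetic means over the reference trees admitted by the edge
policy (buffer strip, toroidal wrapping, or none).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

from standcarbon.errors import ConfigurationError, StandCarbonError, ValidationError
from standcarbon.stand_io import StemMap

DEFAULT_K = 4
#: Standard angle (degrees) against which adjacent-ray angles are judged;
#: 72° = 360°/5, the conventional choice for k = 4.
DEFAULT_ALPHA0 = 72.0


@dataclass(frozen=True)
class EdgePolicy:
    """How plot edges are handled when choosing reference trees.

    ``buffer``: trees within ``width`` m of any boundary are excluded as
    references but still serve as neighbors.  ``torus``: distances wrap
    around the plot, every tree is a reference.  ``none``: every tree is a
    reference and distances are plain Euclidean.
    """

    kind: Literal["buffer", "torus", "none"]
    width: float = 0.0

    @classmethod
    def buffer(cls, width: float = 5.0) -> "EdgePolicy":
        return cls("buffer", width)

    @classmethod
    def torus(cls) -> "EdgePolicy":
        return cls("torus")

    @classmethod
    def none(cls) -> "EdgePolicy":
        return cls("none")

    @classmethod
    def parse(cls, spec: str) -> "EdgePolicy":
        """Parse ``'buffer:5'``, ``'torus'`` or ``'none'``."""
        if spec.startswith("buffer"):
            width = float(spec.split(":", 1)[1]) if ":" in spec else 5.0
            return cls("buffer", width)
        if spec in ("torus", "none"):
            return cls(spec)  # type: ignore[arg-type]
        raise ConfigurationError(f"unknown edge policy {spec!r}")

    @property
    def wraps(self) -> bool:
        return self.kind == "torus"

    def eligible(self, stem_map: StemMap) -> np.ndarray:
        """Boolean mask of reference-tree eligibility, in stem-map order."""
        n = len(stem_map)
        if self.kind != "buffer":
            return np.ones(n, dtype=bool)
        w, h = stem_map.extent
        if self.width >= min(w, h) / 2:
            raise ConfigurationError(
                f"buffer width {self.width} m must be below half the plot extent {min(w, h) / 2} m"
            )
        x = np.array([t.x for t in stem_map.trees])
        y = np.array([t.y for t in stem_map.trees])
        return (
            (x >= self.width) & (x <= w - self.width) & (y >= self.width) & (y <= h - self.width)
        )


DEFAULT_EDGE_POLICY = EdgePolicy.buffer(5.0)


@dataclass(frozen=True)
class CrownModel:
    """Linear DBH-to-crown-radius model ``r_m = c0 + c1 * DBH_cm``."""

    c0: float = 0.5
    c1: float = 0.05

    def radius(self, dbh: np.ndarray) -> np.ndarray:
        r = self.c0 + self.c1 * np.asarray(dbh, dtype=float)
        if np.any(r <= 0):
            raise ConfigurationError(
                f"crown model (c0={self.c0}, c1={self.c1}) yields non-positive radius"
            )
        return r


@dataclass(frozen=True)
class NeighborSet:
    """The k nearest neighbors of one reference tree."""

    tree_id: str
    neighbor_ids: tuple[str, ...]
    distances: tuple[float, ...]
    azimuths: tuple[float, ...]


def _displacements(stem_map: StemMap, wraps: bool) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs displacement components (dx, dy), optionally torus-wrapped."""
    x = np.array([t.x for t in stem_map.trees])
    y = np.array([t.y for t in stem_map.trees])
    dx = x[None, :] - x[:, None]
    dy = y[None, :] - y[:, None]
    if wraps:
        w, h = stem_map.extent
        dx = (dx + w / 2) % w - w / 2
        dy = (dy + h / 2) % h - h / 2
    return dx, dy


def _neighbor_arrays(
    stem_map: StemMap, k: int, wraps: bool
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Indices, distances and azimuths of the k nearest neighbors per tree.

    Ties in distance are broken in favour of the lexicographically smaller
    tree id.  Azimuths are compass bearings (degrees clockwise from north)
    of the displacement from reference to neighbor.
    """
    n = len(stem_map)
    if n <= k:
        raise StandCarbonError(
            f"insufficient trees: plot {stem_map.plot_id!r} has {n} trees, need more than k={k}"
        )
    dx, dy = _displacements(stem_map, wraps)
    dist = np.hypot(dx, dy)

    ids = [t.tree_id for t in stem_map.trees]
    coincident = np.argwhere((dist == 0) & ~np.eye(n, dtype=bool))
    if coincident.size:
        i, j = coincident[0]
        raise ValidationError(
            f"coincident coordinates: trees {ids[i]!r} and {ids[j]!r} share a position"
        )

    # rank of each tree id under string ordering, used as the tie-break key
    id_rank = np.empty(n, dtype=int)
    id_rank[np.array(sorted(range(n), key=lambda i: ids[i]))] = np.arange(n)

    np.fill_diagonal(dist, np.inf)
    nn_idx = np.empty((n, k), dtype=int)
    for i in range(n):
        order = np.lexsort((id_rank, dist[i]))
        nn_idx[i] = order[:k]
    rows = np.arange(n)[:, None]
    nn_dist = dist[rows, nn_idx]
    nn_az = np.degrees(np.arctan2(dx[rows, nn_idx], dy[rows, nn_idx])) % 360.0
    return nn_idx, nn_dist, nn_az


def nearest_neighbors(
    stem_map: StemMap, k: int = DEFAULT_K, edge_policy: EdgePolicy = DEFAULT_EDGE_POLICY
) -> dict[str, NeighborSet]:
    """Return each tree's k nearest neighbors (distance ties broken by id).

    Under a torus edge policy distances wrap around the plot; otherwise
    they are plain Euclidean.  Raises if the plot has at most k trees or
    if two trees share coordinates.
    """
    nn_idx, nn_dist, nn_az = _neighbor_arrays(stem_map, k, edge_policy.wraps)
    ids = [t.tree_id for t in stem_map.trees]
    return {
        ids[i]: NeighborSet(
            tree_id=ids[i],
            neighbor_ids=tuple(ids[j] for j in nn_idx[i]),
            distances=tuple(nn_dist[i]),
            azimuths=tuple(nn_az[i]),
        )
        for i in range(len(ids))
    }


def _per_tree_series(stem_map: StemMap, values: np.ndarray, mask: np.ndarray) -> pd.Series:
    ids = [t.tree_id for t in stem_map.trees]
    return pd.Series(values[mask], index=pd.Index(np.array(ids)[mask], name="tree_id"))


def uniform_angle(
    stem_map: StemMap,
    k: int = DEFAULT_K,
    alpha0: float = DEFAULT_ALPHA0,
    edge_policy: EdgePolicy = DEFAULT_EDGE_POLICY,
) -> tuple[pd.Series, float]:
    """Uniform angle index W per eligible reference tree, and the stand mean.

    Neighbor azimuths are sorted; for each circularly adjacent ray pair the
    smaller angle between the rays (≤ 180°) is compared against ``alpha0``,
    counting 1 when below it.  W_i is the fraction of such small angles.
    """
    _, _, nn_az = _neighbor_arrays(stem_map, k, edge_policy.wraps)
    az = np.sort(nn_az, axis=1)
    gaps = np.diff(az, axis=1, append=(az[:, :1] + 360.0))
    angles = np.minimum(gaps, 360.0 - gaps)
    w_i = np.mean(angles < alpha0, axis=1)
    mask = edge_policy.eligible(stem_map)
    series = _per_tree_series(stem_map, w_i, mask)
    return series, float(series.mean())


def dominance(
    stem_map: StemMap,
    k: int = DEFAULT_K,
    edge_policy: EdgePolicy = DEFAULT_EDGE_POLICY,
    orientation: Literal["larger", "smaller"] = "larger",
) -> tuple[pd.Series, float]:
    """Dominance index U per eligible reference tree, and the stand mean.

    With the default ``larger`` orientation, U_i is the fraction of the k
    neighbors with DBH strictly greater than the reference tree's (equal
    DBH counts zero), so a high value marks a suppressed reference tree.
    ``smaller`` flips the comparison.
    """
    nn_idx, _, _ = _neighbor_arrays(stem_map, k, edge_policy.wraps)
    dbh = np.array([t.dbh for t in stem_map.trees])
    nb = dbh[nn_idx]
    ref = dbh[:, None]
    u_i = np.mean(nb > ref if orientation == "larger" else nb < ref, axis=1)
    mask = edge_policy.eligible(stem_map)
    series = _per_tree_series(stem_map, u_i, mask)
    return series, float(series.mean())


def mingling(
    stem_map: StemMap,
    k: int = DEFAULT_K,
    edge_policy: EdgePolicy = DEFAULT_EDGE_POLICY,
) -> tuple[pd.Series, float]:
    """Mingling index M (fraction of hetero-specific neighbors) and stand mean."""
    nn_idx, _, _ = _neighbor_arrays(stem_map, k, edge_policy.wraps)
    species = np.array([t.species for t in stem_map.trees], dtype=object)
    m_i = np.mean(species[nn_idx] != species[:, None], axis=1)
    mask = edge_policy.eligible(stem_map)
    series = _per_tree_series(stem_map, m_i, mask)
    return series, float(series.mean())


def crowding(
    stem_map: StemMap,
    k: int = DEFAULT_K,
    crown_model: CrownModel = CrownModel(),
    edge_policy: EdgePolicy = DEFAULT_EDGE_POLICY,
) -> tuple[pd.Series, float]:
    """Crowding index C (fraction of crown-overlapping neighbors) and stand mean.

    A neighbor counts as crowding when the horizontal distance is strictly
    below the sum of the two crown radii; a distance exactly equal to the
    radius sum does not count.
    """
    nn_idx, nn_dist, _ = _neighbor_arrays(stem_map, k, edge_policy.wraps)
    dbh = np.array([t.dbh for t in stem_map.trees])
    radii = crown_model.radius(dbh)
    c_i = np.mean(nn_dist < radii[:, None] + radii[nn_idx], axis=1)
    mask = edge_policy.eligible(stem_map)
    series = _per_tree_series(stem_map, c_i, mask)
    return series, float(series.mean())


def spatial_indices(
    stem_map: StemMap,
    k: int = DEFAULT_K,
    alpha0: float = DEFAULT_ALPHA0,
    crown_model: CrownModel = CrownModel(),
    edge_policy: EdgePolicy = DEFAULT_EDGE_POLICY,
    dominance_orientation: Literal["larger", "smaller"] = "larger",
) -> tuple[pd.DataFrame, dict[str, float]]:
    """All four spatial indices at once.

    Returns a per-tree DataFrame (columns W, U, M, C, indexed by tree id,
    eligible reference trees only) and the dict of stand means
    ``{"W": ..., "U": ..., "M": ..., "C": ...}``.
    """
    w_s, w_bar = uniform_angle(stem_map, k, alpha0, edge_policy)
    u_s, u_bar = dominance(stem_map, k, edge_policy, dominance_orientation)
    m_s, m_bar = mingling(stem_map, k, edge_policy)
    c_s, c_bar = crowding(stem_map, k, crown_model, edge_policy)
    per_tree = pd.DataFrame({"W": w_s, "U": u_s, "M": m_s, "C": c_s})
    means = {"W": w_bar, "U": u_bar, "M": m_bar, "C": c_bar}
    return per_tree, means
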