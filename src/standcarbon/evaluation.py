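"""End-to-end evaluation of the synthetic study: recovery diagnostics.

These helpers run the whole chain — generate a study, compute structural
profiles and carbon pools, classify — and score how well the analysis
recovers what the generator planted: the latent three-type partition
(adjusted Rand index), the sign of the understory–crowding coupling, and
the qualitative carbon pattern (the high-diversity type stores the most
total carbon but the least understory carbon).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import adjusted_rand_score

from standcarbon.carbon_accounting import plot_carbon_pools, pools_table
from standcarbon.nonspatial_structure import diameter_profile
from standcarbon.spatial_structure import EdgePolicy, crowding, spatial_indices
from standcarbon.stand_typing import cluster_stands, log_transform, pca, redundancy_filter
from standcarbon.synthetic_stands import CouplingConfig, StandConfig, StudyBundle, generate_ecosystem, generate_stand, generate_study

INDEX_ORDER = ["W", "U", "M", "C", "CV", "SK", "GC", "H"]


def study_profiles(bundle: StudyBundle, edge_policy: EdgePolicy = EdgePolicy.torus()) -> pd.DataFrame:
    """The eight structural diversity indices for every plot of a bundle."""
    rows = {}
    for sm in bundle.stem_maps:
        _, means = spatial_indices(sm, edge_policy=edge_policy)
        prof = diameter_profile([t.dbh for t in sm.trees])
        rows[sm.plot_id] = {**means, **{k: prof[k] for k in ("CV", "SK", "GC", "H")}}
    return pd.DataFrame(rows).T[INDEX_ORDER].rename_axis("plot_id")


def study_pools(bundle: StudyBundle) -> pd.DataFrame:
    """Per-plot carbon-pool table for a bundle (Mg C ha⁻¹)."""
    pools = [
        plot_carbon_pools(
            sm,
            bundle.harvests_for(sm.plot_id),
            bundle.soil_for(sm.plot_id),
            bundle.allometry,
            bundle.fractions,
        )
        for sm in bundle.stem_maps
    ]
    return pools_table(pools).set_index("plot_id")


def classify_study(profiles: pd.DataFrame, k: int = 3) -> pd.Series:
    """The full typing chain: log → redundancy filter → PCA → Ward cut."""
    logged, _ = log_transform(profiles)
    filtered, _ = redundancy_filter(logged)
    res = pca(filtered)
    return cluster_stands(res.scores, k=k, explained_ratio=res.explained_ratio)


def evaluate_recovery(seed: int) -> dict:
    """Run one synthetic study end to end and score what was recovered.

    Returns the adjusted Rand index between recovered and planted types,
    and whether the planted high-diversity type (Type 1) shows the highest
    mean total carbon and the lowest mean understory (shrub + herb) carbon.
    """
    bundle = generate_study(seed=seed)
    profiles = study_profiles(bundle)
    labels = classify_study(profiles)
    ari = adjusted_rand_score(bundle.true_types[labels.index], labels)

    pools = study_pools(bundle)
    by_type = pools.join(bundle.true_types).groupby("type").mean()
    understory = by_type["shrub"] + by_type["herb"]
    return {
        "ari": float(ari),
        "total_highest_in_type1": bool(by_type["total"].idxmax() == 1),
        "understory_lowest_in_type1": bool(understory.idxmin() == 1),
        "type_means_total": by_type["total"].to_dict(),
        "type_means_understory": understory.to_dict(),
    }


def fit_understory_coupling(
    n_stands: int = 200,
    seed: int = 0,
    coupling: CouplingConfig | None = None,
):
    """Regress log understory (shrub) biomass density on stand crowding.

    Stands span the three spatial patterns and the survey density range so
    the crowding covariate has spread; returns the scipy linregress result,
    to be compared against the planted slope ``beta_under``.
    """
    coupling = coupling or CouplingConfig()
    rng = np.random.default_rng(seed)
    c_bars, log_shrub = [], []
    patterns = ("poisson", "thomas", "lattice")
    for i in range(n_stands):
        cfg = StandConfig(
            pattern=patterns[i % 3],
            n_trees=int(rng.integers(28, 67)),
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        stand = generate_stand(cfg, plot_id=f"R{i:03d}")
        recs, _ = generate_ecosystem(stand, coupling, seed=int(rng.integers(0, 2**31 - 1)))
        _, c_bar = crowding(stand, edge_policy=EdgePolicy.torus())
        density = np.mean([r.dry_mass / r.subplot_area for r in recs if r.pool == "shrub"])
        c_bars.append(c_bar)
        log_shrub.append(np.log(density))
    return stats.linregress(c_bars, log_shrub)
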