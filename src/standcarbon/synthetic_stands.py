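"""Synthetic study generator: stem maps, understory harvests and soil profiles.

The generator emulates the sampling design of a 13-plot survey of
secondary Masson-pine-dominated stands: 20 m × 20 m plots, stem densities
between 700 and 1,650 ha⁻¹ (about 1,200 on average), DBH between 5 and
62 cm drawn from a shifted truncated Weibull, and roughly 35 woody species
with strongly concentrated abundances.  Three latent structural types are
planted through the point pattern and the diameter distribution:

* Type I — clustered (Thomas process), dense, strongly right-skewed wide
  DBH distribution: high spatial AND high non-spatial diversity;
* Type II — clustered and dense but with a narrow, symmetric DBH
  distribution: high spatial, low non-spatial diversity;
* Type III — jittered lattice at low density, narrow DBH distribution:
  low spatial, low non-spatial diversity.

Understory biomass is negatively coupled to stand crowding (dense, clumped
canopies shade out shrubs and herbs), litter mass tracks canopy leaf
biomass, and topsoil organic carbon is weakly positively coupled to herb
biomass.  All noise is log-normal so masses and concentrations stay
positive, matching the downstream log-transform step.  Every output is
reproducible bit-for-bit from its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from standcarbon.carbon_accounting import HarvestRecord, SoilLayer, SoilProfile
from standcarbon.errors import StandCarbonError, ValidationError
from standcarbon.spatial_structure import CrownModel, EdgePolicy, crowding
from standcarbon.stand_io import (
    AllometryEntry,
    AllometryTable,
    CarbonFractionTable,
    StemMap,
    Tree,
    write_allometry,
    write_carbon_fractions,
    write_stem_map,
)

#: Synthetic default allometry (kg, cm). These coefficients are a
#: constructed test set in the range of published subtropical models,
#: NOT fitted values for any real species.
DEFAULT_ALLOMETRY = AllometryTable(
    entries={
        "PINMAS": AllometryEntry(
            "PINMAS",
            a=0.044,
            b=2.45,
            components={"stem": (0.044, 2.45), "branch": (0.012, 2.30), "leaf": (0.009, 2.00)},
        ),
        "SCHSUP": AllometryEntry(
            "SCHSUP",
            a=0.052,
            b=2.40,
            components={"stem": (0.052, 2.40), "branch": (0.013, 2.28), "leaf": (0.010, 2.00)},
        ),
        "DEFAULT": AllometryEntry(
            "DEFAULT",
            a=0.050,
            b=2.40,
            components={"stem": (0.050, 2.40), "branch": (0.012, 2.30), "leaf": (0.010, 2.00)},
        ),
    }
)

#: Synthetic default carbon fractions per species / pool label.
DEFAULT_FRACTIONS = CarbonFractionTable(
    fractions={
        "PINMAS": 0.52,
        "SCHSUP": 0.49,
        "shrub": 0.45,
        "herb": 0.42,
        "litter": 0.46,
    },
    fallback=0.50,
)


@dataclass(frozen=True)
class StandConfig:
    """Configuration of one synthetic stem map.

    ``pattern`` selects the point process: ``poisson`` (complete spatial
    randomness), ``thomas`` (Poisson cluster process with ``parent_rate``
    parents per m², mean ``offspring`` points per parent and Gaussian
    dispersion ``sigma`` in metres, wrapped onto the plot torus) or
    ``lattice`` (near-square grid with Gaussian ``jitter``).  DBH marks are
    i.i.d. from a Weibull shifted to ``dbh_shift`` and truncated at
    ``dbh_max``.  Species come from a geometric-abundance pool of
    ``n_species`` labels; with probability ``mingling_control`` a tree
    copies the species of its nearest already-labelled neighbor instead of
    drawing fresh, which tunes conspecific clumping and hence mingling.
    """

    n_trees: int = 48
    extent: tuple[float, float] = (20.0, 20.0)
    pattern: Literal["poisson", "thomas", "lattice"] = "poisson"
    parent_rate: float = 0.01  # thomas: parents per m²
    offspring: float = 12.0  # thomas: mean points per parent
    sigma: float = 1.5  # thomas: offspring dispersion, m
    jitter: float = 0.5  # lattice: positional jitter sd, m
    dbh_shape: float = 1.1
    dbh_scale: float = 12.0
    dbh_shift: float = 5.0
    dbh_max: float = 62.0
    n_species: int = 35
    abundance_theta: float = 0.70  # geometric abundance decay; smaller = more dominant
    mingling_control: float = 0.3
    min_spacing: float = 0.3  # hardcore distance, m; 0 disables
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 5:
            raise ValidationError(f"n_trees must be ≥ 5, got {self.n_trees}")
        if self.dbh_shift < 5:
            raise ValidationError(f"dbh_shift must be ≥ 5 cm, got {self.dbh_shift}")
        for name in ("parent_rate", "offspring", "sigma", "dbh_shape", "dbh_scale"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if not 0 < self.abundance_theta < 1:
            raise ValidationError("abundance_theta must lie in (0, 1)")
        if not 0 <= self.mingling_control <= 1:
            raise ValidationError("mingling_control must lie in [0, 1]")


@dataclass(frozen=True)
class CouplingConfig:
    """How understory, litter and soil respond to stand structure.

    Understory (shrub, herb) log dry-mass density (kg·m⁻²) is linear in
    the stand crowding mean C̄ with slope ``beta_under`` (negative: crowded
    canopies suppress the understory).  Litter density is
    ``litter_per_leaf`` times the canopy leaf-biomass density.  Topsoil
    SOC (g·kg⁻¹) rises with herb biomass (Mg·ha⁻¹) at ``beta_soil``; the
    deeper layer carries half the coupling and a lower base.  Noise terms
    are log-normal sigmas on the natural-log scale.
    """

    beta_under: float = -2.0
    intercept_shrub: float = 0.0  # log kg·m⁻² at C̄ = 0
    intercept_herb: float = -0.8
    beta_soil: float = 2.0  # g·kg⁻¹ SOC per Mg·ha⁻¹ herb biomass
    soc_base: tuple[float, float] = (22.0, 12.0)  # g·kg⁻¹ for 0–20, 20–40 cm
    soc_layer2_coupling: float = 0.5
    bd: tuple[float, float] = (1.05, 1.25)  # g·cm⁻³ per layer
    litter_per_leaf: float = 0.8
    noise_sd_under: float = 0.20
    noise_sd_subplot: float = 0.15
    noise_sd_litter: float = 0.20
    noise_sd_soc: float = 0.10
    noise_sd_bd: float = 0.03

    def __post_init__(self) -> None:
        for name in (
            "noise_sd_under",
            "noise_sd_subplot",
            "noise_sd_litter",
            "noise_sd_soc",
            "noise_sd_bd",
        ):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")


def _truncated_weibull(
    rng: np.random.Generator, n: int, shape: float, scale: float, shift: float, upper: float
) -> np.ndarray:
    """Shifted Weibull truncated at ``upper`` via inverse-CDF sampling."""
    cap = 1.0 - np.exp(-(((upper - shift) / scale) ** shape))
    u = rng.uniform(0.0, cap, size=n)
    return shift + scale * (-np.log1p(-u)) ** (1.0 / shape)


def _points_poisson(rng: np.random.Generator, n: int, extent) -> np.ndarray:
    w, h = extent
    return np.column_stack([rng.uniform(0, w, n), rng.uniform(0, h, n)])


def _points_thomas(rng: np.random.Generator, cfg: StandConfig) -> np.ndarray:
    """Thomas cluster process wrapped onto the plot torus, thinned to n_trees."""
    w, h = cfg.extent
    pts: list[np.ndarray] = []
    # oversample rounds until enough points exist; wrap keeps stationarity
    for _ in range(200):
        n_parents = max(1, rng.poisson(cfg.parent_rate * w * h))
        parents = _points_poisson(rng, n_parents, cfg.extent)
        for px, py in parents:
            m = rng.poisson(cfg.offspring)
            if m == 0:
                continue
            offs = np.column_stack(
                [
                    (px + rng.normal(0, cfg.sigma, m)) % w,
                    (py + rng.normal(0, cfg.sigma, m)) % h,
                ]
            )
            pts.append(offs)
        if pts and sum(p.shape[0] for p in pts) >= cfg.n_trees:
            break
    allpts = np.vstack(pts)
    keep = rng.permutation(allpts.shape[0])[: cfg.n_trees]
    return allpts[keep]


def _points_lattice(rng: np.random.Generator, cfg: StandConfig) -> np.ndarray:
    w, h = cfg.extent
    cols = int(np.ceil(np.sqrt(cfg.n_trees * w / h)))
    rows = int(np.ceil(cfg.n_trees / cols))
    xs = (np.arange(cols) + 0.5) * (w / cols)
    ys = (np.arange(rows) + 0.5) * (h / rows)
    grid = np.array([(x, y) for y in ys for x in xs])
    chosen = grid[rng.choice(grid.shape[0], cfg.n_trees, replace=False)]
    jittered = chosen + rng.normal(0, cfg.jitter, chosen.shape) if cfg.jitter > 0 else chosen
    jittered[:, 0] %= w
    jittered[:, 1] %= h
    return jittered


def _enforce_spacing(
    rng: np.random.Generator, pts: np.ndarray, cfg: StandConfig
) -> np.ndarray:
    """Thin points violating the hardcore distance and refill from the process."""
    if cfg.min_spacing <= 0:
        return pts
    w, h = cfg.extent
    capacity = (w // cfg.min_spacing) * (h // cfg.min_spacing)
    if cfg.n_trees > capacity:
        raise StandCarbonError(
            f"infeasible target: {cfg.n_trees} trees cannot satisfy a "
            f"{cfg.min_spacing} m hardcore spacing on {w} m × {h} m"
        )
    kept: list[np.ndarray] = []
    pool = list(pts)
    attempts = 0
    while len(kept) < cfg.n_trees:
        if not pool:
            attempts += 1
            if attempts > 500:
                raise StandCarbonError(
                    f"infeasible target: could not place {cfg.n_trees} trees with "
                    f"{cfg.min_spacing} m spacing"
                )
            pool = list(_points_poisson(rng, cfg.n_trees, cfg.extent))
        cand = pool.pop(0)
        if all(np.hypot(*(cand - q)) >= cfg.min_spacing for q in kept):
            kept.append(cand)
    return np.array(kept)


def _assign_species(rng: np.random.Generator, pts: np.ndarray, cfg: StandConfig) -> list[str]:
    """Geometric-abundance draws with nearest-neighbor copying.

    Species ``SP01`` is the dominant (the Masson pine analogue).  With
    probability ``mingling_control`` a tree inherits the species of the
    nearest tree already labelled, producing conspecific patches.
    """
    probs = cfg.abundance_theta ** np.arange(cfg.n_species)
    probs /= probs.sum()
    names = [f"SP{i + 1:02d}" if i else "PINMAS" for i in range(cfg.n_species)]
    n = pts.shape[0]
    order = rng.permutation(n)
    species: list[str | None] = [None] * n
    assigned: list[int] = []
    for idx in order:
        if assigned and rng.uniform() < cfg.mingling_control:
            d = np.hypot(*(pts[assigned] - pts[idx]).T)
            species[idx] = species[assigned[int(np.argmin(d))]]
        else:
            species[idx] = names[int(rng.choice(cfg.n_species, p=probs))]
        assigned.append(idx)
    return [s for s in species]  # type: ignore[misc]


def generate_stand(cfg: StandConfig, plot_id: str = "S01") -> StemMap:
    """Draw one synthetic stem map from the configured point process.

    Points come from the chosen process clipped/wrapped to the extent, DBH
    marks i.i.d. from the shifted truncated Weibull, species by the
    mingling-control copy rule.  Identical seeds give identical maps.
    """
    rng = np.random.default_rng(cfg.seed)
    if cfg.pattern == "poisson":
        pts = _points_poisson(rng, cfg.n_trees, cfg.extent)
    elif cfg.pattern == "thomas":
        pts = _points_thomas(rng, cfg)
    elif cfg.pattern == "lattice":
        pts = _points_lattice(rng, cfg)
    else:
        raise ValidationError(f"unknown pattern {cfg.pattern!r}")
    pts = _enforce_spacing(rng, pts, cfg)
    dbh = _truncated_weibull(rng, cfg.n_trees, cfg.dbh_shape, cfg.dbh_scale, cfg.dbh_shift, cfg.dbh_max)
    species = _assign_species(rng, pts, cfg)
    trees = tuple(
        Tree(
            tree_id=f"{plot_id}_T{i + 1:03d}",
            x=float(pts[i, 0]),
            y=float(pts[i, 1]),
            species=species[i],
            dbh=float(dbh[i]),
        )
        for i in range(cfg.n_trees)
    )
    return StemMap(plot_id=plot_id, trees=trees, extent=cfg.extent)


def _leaf_biomass_density(stand: StemMap, allometry: AllometryTable) -> float:
    """Canopy leaf biomass per ground area, kg·m⁻²."""
    total = 0.0
    for t in stand.trees:
        entry = allometry.resolve(t.species)
        if entry.components and "leaf" in entry.components:
            a, b = entry.components["leaf"]
            total += a * t.dbh**b
        else:
            total += 0.05 * (entry.a * t.dbh**entry.b)
    return total / stand.area_m2


def generate_ecosystem(
    stand: StemMap,
    coupling: CouplingConfig | None = None,
    seed: int = 0,
    allometry: AllometryTable = DEFAULT_ALLOMETRY,
    crown_model: CrownModel = CrownModel(),
) -> tuple[list[HarvestRecord], SoilProfile]:
    """Simulate the understory harvest and soil profile coupled to one stand.

    Shrub and herb log biomass densities are linear in the stand crowding
    mean (torus edges, so the coupling covariate is stationary); litter
    tracks canopy leaf biomass; per-layer SOC rises with herb biomass.
    Three subplots per pool mimic the field design: 2 m × 2 m for shrubs,
    1 m × 1 m for herbs and litter.
    """
    coupling = coupling or CouplingConfig()
    rng = np.random.default_rng(seed)
    _, c_bar = crowding(stand, crown_model=crown_model, edge_policy=EdgePolicy.torus())

    log_shrub = coupling.intercept_shrub + coupling.beta_under * c_bar
    log_herb = coupling.intercept_herb + coupling.beta_under * c_bar
    shrub_density = float(np.exp(log_shrub + rng.normal(0, coupling.noise_sd_under)))
    herb_density = float(np.exp(log_herb + rng.normal(0, coupling.noise_sd_under)))
    litter_density = float(
        coupling.litter_per_leaf
        * _leaf_biomass_density(stand, allometry)
        * np.exp(rng.normal(0, coupling.noise_sd_litter))
    )

    subplot_plans = (("shrub", 4.0, shrub_density), ("herb", 1.0, herb_density), ("litter", 1.0, litter_density))
    records = [
        HarvestRecord(
            plot_id=stand.plot_id,
            pool=pool,
            subplot_area=area,
            dry_mass=float(density * area * np.exp(rng.normal(0, coupling.noise_sd_subplot))),
        )
        for pool, area, density in subplot_plans
        for _ in range(3)
    ]

    herb_mg_ha = herb_density * 10.0
    bounds = ((0.0, 20.0), (20.0, 40.0))
    layers = []
    for j, (top, bottom) in enumerate(bounds):
        scale = 1.0 if j == 0 else coupling.soc_layer2_coupling
        soc = (coupling.soc_base[j] + scale * coupling.beta_soil * herb_mg_ha) * float(
            np.exp(rng.normal(0, coupling.noise_sd_soc))
        )
        bd = coupling.bd[j] * float(np.exp(rng.normal(0, coupling.noise_sd_bd)))
        layers.append(SoilLayer(depth_top=top, depth_bottom=bottom, bd=bd, soc=soc))
    return records, SoilProfile(plot_id=stand.plot_id, layers=tuple(layers))


#: Per-type stand templates planting the three structural contrasts.
#: Densities are trees per plot on 400 m² (×25 = ha⁻¹), spanning the
#: 700–1,650 ha⁻¹ survey range.
TYPE_TEMPLATES: Mapping[int, dict] = {
    1: dict(  # high spatial + high non-spatial diversity; densest, tightest
        pattern="thomas",
        density_range=(56, 66),
        dbh_shape=0.9,
        dbh_scale=13.0,
        sigma=1.0,
        mingling_control=0.10,
    ),
    2: dict(  # high spatial, low non-spatial; clustered but looser and thinner
        pattern="thomas",
        density_range=(40, 52),
        dbh_shape=3.5,
        dbh_scale=13.0,
        sigma=2.2,
        mingling_control=0.50,
    ),
    3: dict(  # low spatial, low non-spatial
        pattern="lattice",
        density_range=(28, 40),
        dbh_shape=3.5,
        dbh_scale=13.0,
        jitter=0.5,
        mingling_control=0.85,
    ),
}


@dataclass(frozen=True)
class StudyBundle:
    """Everything one synthetic study emits: per-plot inputs plus configs."""

    stem_maps: tuple[StemMap, ...]
    harvests: tuple[HarvestRecord, ...]
    soils: tuple[SoilProfile, ...]
    true_types: pd.Series  # plot_id -> latent type (1..3)
    allometry: AllometryTable
    fractions: CarbonFractionTable

    def harvests_for(self, plot_id: str) -> list[HarvestRecord]:
        return [h for h in self.harvests if h.plot_id == plot_id]

    def soil_for(self, plot_id: str) -> SoilProfile:
        for s in self.soils:
            if s.plot_id == plot_id:
                return s
        raise KeyError(plot_id)

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        """Write the full input bundle as CSV files under ``out_dir``."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}
        for sm in self.stem_maps:
            p = out_dir / f"stem_map_{sm.plot_id}.csv"
            write_stem_map(sm, p)
            paths[f"stem_map_{sm.plot_id}"] = p

        harvest_df = pd.DataFrame(
            [
                {
                    "plot_id": h.plot_id,
                    "pool": h.pool,
                    "subplot_area_m2": h.subplot_area,
                    "dry_mass_kg": h.dry_mass,
                }
                for h in self.harvests
            ]
        )
        paths["harvest"] = out_dir / "harvest.csv"
        harvest_df.to_csv(paths["harvest"], index=False, lineterminator="\n", float_format="%.17g")

        soil_rows = [
            {
                "plot_id": s.plot_id,
                "depth_top_cm": l.depth_top,
                "depth_bottom_cm": l.depth_bottom,
                "bd_g_cm3": l.bd,
                "soc_g_kg": l.soc,
            }
            for s in self.soils
            for l in s.layers
        ]
        paths["soil"] = out_dir / "soil.csv"
        pd.DataFrame(soil_rows).to_csv(paths["soil"], index=False, lineterminator="\n", float_format="%.17g")

        paths["allometry"] = out_dir / "allometry.csv"
        write_allometry(self.allometry, paths["allometry"])
        paths["fractions"] = out_dir / "carbon_fractions.csv"
        write_carbon_fractions(self.fractions, paths["fractions"])

        paths["true_types"] = out_dir / "true_types.csv"
        self.true_types.rename_axis("plot_id").to_frame("type").to_csv(
            paths["true_types"], lineterminator="\n"
        )
        return paths


def generate_study(
    n_plots: int = 13,
    type_sizes: Sequence[int] = (4, 5, 4),
    seed: int = 0,
    coupling: CouplingConfig | None = None,
    templates: Mapping[int, dict] = TYPE_TEMPLATES,
    base_config: StandConfig | None = None,
) -> StudyBundle:
    """Generate a full synthetic study: stem maps, harvests and soil profiles.

    Plots are drawn from the three latent type templates (sizes default to
    4 + 5 + 4 = 13) with planted structural contrasts; each plot gets its
    own understory/litter/soil realisation through the coupling model.
    """
    if sum(type_sizes) != n_plots:
        raise ValidationError(f"type sizes {tuple(type_sizes)} must sum to n_plots={n_plots}")
    if len(type_sizes) != len(templates):
        raise ValidationError("one size per latent type required")
    coupling = coupling or CouplingConfig()
    base = base_config or StandConfig()
    rng = np.random.default_rng(seed)

    stem_maps: list[StemMap] = []
    harvests: list[HarvestRecord] = []
    soils: list[SoilProfile] = []
    types: dict[str, int] = {}
    plot_no = 0
    for latent_type, size in zip(sorted(templates), type_sizes):
        tmpl = dict(templates[latent_type])
        lo, hi = tmpl.pop("density_range")
        for _ in range(size):
            plot_no += 1
            plot_id = f"P{plot_no:02d}"
            n_trees = int(rng.integers(lo, hi + 1))
            cfg = replace(
                base,
                n_trees=n_trees,
                seed=int(rng.integers(0, 2**31 - 1)),
                **tmpl,
            )
            stand = generate_stand(cfg, plot_id=plot_id)
            recs, soil = generate_ecosystem(
                stand, coupling, seed=int(rng.integers(0, 2**31 - 1))
            )
            stem_maps.append(stand)
            harvests.extend(recs)
            soils.append(soil)
            types[plot_id] = latent_type
    return StudyBundle(
        stem_maps=tuple(stem_maps),
        harvests=tuple(harvests),
        soils=tuple(soils),
        true_types=pd.Series(types, name="type"),
        allometry=DEFAULT_ALLOMETRY,
        fractions=DEFAULT_FRACTIONS,
    )
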