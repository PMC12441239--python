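"""Carbon-pool accounting: tree, shrub, herb, litter and soil stocks per plot.

Tree carbon comes from species-specific power-law allometry
(biomass_kg = a · DBH^b, summed over stem/branch/leaf/root components when
the model is split) times a species carbon fraction, scaled from the plot
to a hectare.  Shrub, herb and litter pools come from destructive subplot
harvests: mean dry-mass density (kg·m⁻²) × 10 converts to Mg·ha⁻¹, times
the pool carbon fraction.  Soil carbon follows the layered stock equation

    C_s = Σ_i SOC_i · BD_i · D_i · 10      [g·m⁻²]

with SOC in g·kg⁻¹, bulk density BD in g·cm⁻³ and layer thickness D in cm;
dividing by 100 converts to Mg·ha⁻¹.  All pools are reported in Mg C ha⁻¹
and the total is their exact sum.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from standcarbon.errors import ValidationError
from standcarbon.stand_io import AllometryTable, CarbonFractionTable, StemMap, Tree

POOLS = ("tree", "shrub", "herb", "litter", "soil")


@dataclass(frozen=True)
class SoilLayer:
    """One sampled soil layer: depth bounds (cm), bulk density, SOC."""

    depth_top: float
    depth_bottom: float
    bd: float  # bulk density, g·cm⁻³
    soc: float  # organic carbon concentration, g·kg⁻¹

    def __post_init__(self) -> None:
        if not (self.depth_bottom > self.depth_top >= 0):
            raise ValidationError(
                f"soil layer bounds must satisfy bottom > top >= 0, got "
                f"({self.depth_top}, {self.depth_bottom})"
            )
        if not self.bd > 0:
            raise ValidationError(f"bulk density must be positive, got {self.bd}")
        if self.soc < 0:
            raise ValidationError(f"SOC must be non-negative, got {self.soc}")

    @property
    def thickness(self) -> float:
        """Layer thickness D in cm."""
        return self.depth_bottom - self.depth_top


@dataclass(frozen=True)
class SoilProfile:
    """Ordered, non-overlapping soil layers for one plot (default 0–20, 20–40 cm)."""

    plot_id: str
    layers: tuple[SoilLayer, ...]

    def __post_init__(self) -> None:
        ordered = sorted(self.layers, key=lambda l: l.depth_top)
        for upper, lower in zip(ordered, ordered[1:]):
            if lower.depth_top < upper.depth_bottom:
                raise ValidationError(
                    f"plot {self.plot_id!r}: overlapping soil layers "
                    f"({upper.depth_top}-{upper.depth_bottom}) and "
                    f"({lower.depth_top}-{lower.depth_bottom})"
                )


@dataclass(frozen=True)
class HarvestRecord:
    """Dry mass of one destructively harvested subplot (shrub, herb or litter)."""

    plot_id: str
    pool: Literal["shrub", "herb", "litter"]
    subplot_area: float  # m²
    dry_mass: float  # kg, constant-weight dry mass (above + below ground)

    def __post_init__(self) -> None:
        if self.pool not in ("shrub", "herb", "litter"):
            raise ValidationError(f"unknown harvest pool {self.pool!r}")
        if not self.subplot_area > 0:
            raise ValidationError(f"subplot area must be positive, got {self.subplot_area}")
        if self.dry_mass < 0:
            raise ValidationError(f"dry mass must be non-negative, got {self.dry_mass}")


@dataclass(frozen=True)
class CarbonPools:
    """Per-plot carbon storage by component, Mg C ha⁻¹; total is the exact sum."""

    plot_id: str
    tree: float
    shrub: float
    herb: float
    litter: float
    soil: float

    def __post_init__(self) -> None:
        for pool in POOLS:
            if getattr(self, pool) < 0:
                raise ValidationError(f"plot {self.plot_id!r}: negative {pool} pool")

    @property
    def total(self) -> float:
        return self.tree + self.shrub + self.herb + self.litter + self.soil

    def as_dict(self) -> dict[str, float]:
        d = {pool: getattr(self, pool) for pool in POOLS}
        d["total"] = self.total
        return d


def tree_biomass(tree: Tree, table: AllometryTable) -> float:
    """Dry biomass (kg) of one tree from its species allometry.

    Component-split entries are summed; unlisted species use the table's
    fallback entry.
    """
    entry = table.resolve(tree.species)
    if entry.components:
        return float(sum(a * tree.dbh**b for a, b in entry.components.values()))
    return float(entry.a * tree.dbh**entry.b)


def tree_pool_carbon(
    stem_map: StemMap,
    table: AllometryTable,
    fractions: CarbonFractionTable,
    plot_area: float | None = None,
) -> float:
    """Tree-layer carbon in Mg C ha⁻¹.

    Sums biomass × species carbon fraction over all trees, then scales by
    10,000 / plot_area (per-hectare) and kg → Mg.
    """
    area = stem_map.area_m2 if plot_area is None else plot_area
    if not area > 0:
        raise ValidationError(f"plot area must be positive, got {area}")
    carbon_kg = sum(tree_biomass(t, table) * fractions.resolve(t.species) for t in stem_map.trees)
    return float(carbon_kg * (10_000.0 / area) / 1_000.0)


def harvest_pool_carbon(
    records: Sequence[HarvestRecord], fractions: CarbonFractionTable
) -> dict[str, float]:
    """Carbon (Mg C ha⁻¹) for each harvested pool present in ``records``.

    Each record yields a dry-mass density (kg·m⁻²); densities are averaged
    over a pool's subplots, ×10 converts kg·m⁻² to Mg·ha⁻¹, and the pool's
    carbon fraction converts biomass to carbon.  Mixed subplot areas within
    a pool are handled by the per-record densities.
    """
    out: dict[str, float] = {}
    by_pool: dict[str, list[float]] = {}
    for rec in records:
        by_pool.setdefault(rec.pool, []).append(rec.dry_mass / rec.subplot_area)
    for pool, densities in by_pool.items():
        out[pool] = float(np.mean(densities) * 10.0 * fractions.resolve(pool))
    return out


def soil_carbon_stock(profile: SoilProfile) -> tuple[float, float]:
    """Soil carbon stock of a layered profile.

    Returns ``(g·m⁻², Mg·ha⁻¹)``; the areal stock is
    Σ SOC_i · BD_i · D_i · 10 over layers, and 1 g·m⁻² = 0.01 Mg·ha⁻¹.
    """
    g_m2 = sum(l.soc * l.bd * l.thickness * 10.0 for l in profile.layers)
    return float(g_m2), float(g_m2 / 100.0)


def assemble_pools(
    plot_id: str,
    tree: float | None = None,
    shrub: float | None = None,
    herb: float | None = None,
    litter: float | None = None,
    soil: float | None = None,
) -> CarbonPools:
    """Collect the five pool values into a CarbonPools record.

    Every pool must be supplied; a missing one raises naming it.
    """
    values = {"tree": tree, "shrub": shrub, "herb": herb, "litter": litter, "soil": soil}
    missing = [k for k, v in values.items() if v is None]
    if missing:
        raise ValidationError(f"plot {plot_id!r}: missing carbon pool(s): {missing}")
    return CarbonPools(plot_id=plot_id, **{k: float(v) for k, v in values.items()})


def plot_carbon_pools(
    stem_map: StemMap,
    harvest_records: Sequence[HarvestRecord],
    soil_profile: SoilProfile,
    allometry: AllometryTable,
    fractions: CarbonFractionTable,
) -> CarbonPools:
    """Full per-plot carbon accounting from raw field inputs."""
    harvested = harvest_pool_carbon(harvest_records, fractions)
    missing = [p for p in ("shrub", "herb", "litter") if p not in harvested]
    if missing:
        raise ValidationError(f"plot {stem_map.plot_id!r}: no harvest records for {missing}")
    _, soil_mg_ha = soil_carbon_stock(soil_profile)
    return assemble_pools(
        stem_map.plot_id,
        tree=tree_pool_carbon(stem_map, allometry, fractions),
        shrub=harvested["shrub"],
        herb=harvested["herb"],
        litter=harvested["litter"],
        soil=soil_mg_ha,
    )


def pools_table(pools: Iterable[CarbonPools]) -> pd.DataFrame:
    """Tidy per-plot carbon-pool table (one row per plot, Mg C ha⁻¹)."""
    rows = [{"plot_id": p.plot_id, **p.as_dict()} for p in pools]
    return pd.DataFrame(rows, columns=["plot_id", *POOLS, "total"])


def read_harvest_table(path) -> list[HarvestRecord]:
    """Read subplot harvest records from CSV.

    Columns: ``plot_id,pool,subplot_area_m2,dry_mass_kg``.
    """
    df = pd.read_csv(path, dtype={"plot_id": str, "pool": str}, float_precision="round_trip")
    required = ["plot_id", "pool", "subplot_area_m2", "dry_mass_kg"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing harvest column(s) {missing}")
    return [
        HarvestRecord(
            plot_id=str(r.plot_id),
            pool=str(r.pool),
            subplot_area=float(r.subplot_area_m2),
            dry_mass=float(r.dry_mass_kg),
        )
        for r in df.itertuples()
    ]


def read_soil_table(path) -> dict[str, SoilProfile]:
    """Read per-plot soil profiles from CSV.

    Columns: ``plot_id,depth_top_cm,depth_bottom_cm,bd_g_cm3,soc_g_kg``.
    Layers are ordered by depth within each plot.
    """
    df = pd.read_csv(path, dtype={"plot_id": str}, float_precision="round_trip")
    required = ["plot_id", "depth_top_cm", "depth_bottom_cm", "bd_g_cm3", "soc_g_kg"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing soil column(s) {missing}")
    profiles: dict[str, SoilProfile] = {}
    for plot_id, group in df.groupby("plot_id", sort=False):
        layers = tuple(
            SoilLayer(
                depth_top=float(r.depth_top_cm),
                depth_bottom=float(r.depth_bottom_cm),
                bd=float(r.bd_g_cm3),
                soc=float(r.soc_g_kg),
            )
            for r in group.sort_values("depth_top_cm").itertuples()
        )
        profiles[str(plot_id)] = SoilProfile(plot_id=str(plot_id), layers=layers)
    return profiles
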