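import numpy as np
import pandas as pd
import pytest

from conftest import make_stem_map
from standcarbon.errors import ValidationError
from standcarbon.carbon_accounting import (
    CarbonPools,
    HarvestRecord,
    SoilLayer,
    SoilProfile,
    assemble_pools,
    harvest_pool_carbon,
    plot_carbon_pools,
    pools_table,
    read_harvest_table,
    read_soil_table,
    soil_carbon_stock,
    tree_biomass,
    tree_pool_carbon,
)
from standcarbon.stand_io import AllometryEntry, AllometryTable, CarbonFractionTable, Tree


class TestTreeBiomass:
    def test_power_law(self, simple_allometry):
        tree = Tree("a", 1, 1, "PINMAS", 20.0)
        # 0.05 * 20^2.5 = 0.05 * 400 * sqrt(20)
        assert tree_biomass(tree, simple_allometry) == pytest.approx(0.05 * 400 * np.sqrt(20))
        assert tree_biomass(tree, simple_allometry) == pytest.approx(89.44, abs=0.01)

    def test_monotone_in_dbh(self, simple_allometry):
        small = Tree("a", 1, 1, "PINMAS", 20.0)
        big = Tree("b", 1, 1, "PINMAS", 30.0)
        assert tree_biomass(big, simple_allometry) > tree_biomass(small, simple_allometry)

    def test_component_split_sums(self):
        table = AllometryTable(
            entries={
                "DEFAULT": AllometryEntry(
                    "DEFAULT", 0.05, 2.4, components={"stem": (0.05, 2.4), "leaf": (0.01, 2.0)}
                )
            }
        )
        tree = Tree("a", 1, 1, "ANY", 10.0)
        assert tree_biomass(tree, table) == pytest.approx(0.05 * 10**2.4 + 0.01 * 100)

    def test_degenerate_exponent_rejected_at_construction(self):
        with pytest.raises(ValidationError):
            AllometryEntry("X", a=1.0, b=0.0)


class TestTreePoolCarbon:
    def test_empty_plot_is_zero(self, simple_allometry, half_fractions):
        sm = make_stem_map([], plot_id="E")
        assert tree_pool_carbon(sm, simple_allometry, half_fractions) == 0.0

    def test_unit_conversion(self, half_fractions):
        # one tree of exactly 100 kg biomass: a=1, b=1, dbh=100 won't fit in plot,
        # so use a=0.25, b=1, dbh=... simpler: a * dbh^b = 100 with dbh=20, b=1, a=5
        table = AllometryTable(entries={"DEFAULT": AllometryEntry("DEFAULT", a=5.0, b=1.0)})
        sm = make_stem_map([(10, 10)], dbh=[20.0])
        # 100 kg * 0.5 / 400 m2 -> *25 = 1250 kg/ha = 1.25 Mg/ha
        assert tree_pool_carbon(sm, table, half_fractions) == pytest.approx(1.25)

    def test_additive_over_subsets_and_order_invariant(self, simple_allometry, half_fractions):
        rng = np.random.default_rng(4)
        xy = [(float(x), float(y)) for x, y in rng.uniform(0, 20, (12, 2))]
        dbh = list(rng.uniform(5, 50, 12))
        sm = make_stem_map(xy, dbh=dbh)
        total = tree_pool_carbon(sm, simple_allometry, half_fractions)
        sm_a = make_stem_map(xy[:5], dbh=dbh[:5])
        sm_b = make_stem_map(xy[5:], dbh=dbh[5:])
        assert total == pytest.approx(
            tree_pool_carbon(sm_a, simple_allometry, half_fractions)
            + tree_pool_carbon(sm_b, simple_allometry, half_fractions)
        )
        shuffled = make_stem_map(xy[::-1], dbh=dbh[::-1])
        assert total == pytest.approx(tree_pool_carbon(shuffled, simple_allometry, half_fractions))


class TestHarvestPoolCarbon:
    def test_unit_conversion(self, half_fractions):
        records = [HarvestRecord("P", "litter", 1.0, 0.4) for _ in range(3)]
        # 0.4 kg/m2 * 10 * 0.5 = 2.0 Mg C/ha
        assert harvest_pool_carbon(records, half_fractions)["litter"] == pytest.approx(2.0)

    def test_zero_mass_is_zero(self, half_fractions):
        records = [HarvestRecord("P", "herb", 1.0, 0.0)]
        assert harvest_pool_carbon(records, half_fractions)["herb"] == 0.0

    def test_pooled_mean_equals_identical_subplots(self, half_fractions):
        three = [HarvestRecord("P", "shrub", 4.0, 1.2) for _ in range(3)]
        one = [HarvestRecord("P", "shrub", 4.0, 1.2)]
        assert harvest_pool_carbon(three, half_fractions) == harvest_pool_carbon(one, half_fractions)

    def test_mixed_subplot_areas_use_densities(self, half_fractions):
        records = [HarvestRecord("P", "herb", 1.0, 0.2), HarvestRecord("P", "herb", 4.0, 0.8)]
        # densities 0.2 and 0.2 kg/m2 -> mean 0.2 * 10 * 0.5 = 1.0
        assert harvest_pool_carbon(records, half_fractions)["herb"] == pytest.approx(1.0)

    def test_negative_mass_rejected(self):
        with pytest.raises(ValidationError):
            HarvestRecord("P", "herb", 1.0, -0.1)


class TestSoilCarbonStock:
    def test_printed_equation(self):
        profile = SoilProfile("P", (SoilLayer(0, 20, bd=1.2, soc=20.0),))
        g_m2, mg_ha = soil_carbon_stock(profile)
        assert g_m2 == pytest.approx(4800.0)
        assert mg_ha == pytest.approx(48.0)

    def test_zero_soc_is_zero(self):
        profile = SoilProfile("P", (SoilLayer(0, 20, bd=1.2, soc=0.0),))
        assert soil_carbon_stock(profile)[0] == 0.0

    def test_two_layers_sum(self):
        l1 = SoilLayer(0, 20, bd=1.2, soc=20.0)
        l2 = SoilLayer(20, 40, bd=1.4, soc=10.0)
        both, _ = soil_carbon_stock(SoilProfile("P", (l1, l2)))
        only1, _ = soil_carbon_stock(SoilProfile("P", (l1,)))
        only2, _ = soil_carbon_stock(SoilProfile("P", (l2,)))
        assert both == pytest.approx(only1 + only2)

    @pytest.mark.parametrize("factor", [0.5, 2.0, 3.7])
    def test_linear_in_each_factor(self, factor):
        base = SoilLayer(0, 20, bd=1.2, soc=20.0)
        g0 = soil_carbon_stock(SoilProfile("P", (base,)))[0]
        scaled_soc = SoilLayer(0, 20, bd=1.2, soc=20.0 * factor)
        scaled_bd = SoilLayer(0, 20, bd=1.2 * factor, soc=20.0)
        scaled_d = SoilLayer(0, 20 * factor, bd=1.2, soc=20.0)
        for layer in (scaled_soc, scaled_bd, scaled_d):
            assert soil_carbon_stock(SoilProfile("P", (layer,)))[0] == pytest.approx(g0 * factor)

    def test_overlapping_layers_rejected(self):
        with pytest.raises(ValidationError, match="overlap"):
            SoilProfile("P", (SoilLayer(0, 20, 1.2, 20.0), SoilLayer(15, 40, 1.2, 10.0)))


class TestAssemblePools:
    def test_total_is_component_sum(self):
        pools = assemble_pools("P", tree=50, shrub=1, herb=0.5, litter=2, soil=48)
        assert pools.total == pytest.approx(101.5)

    def test_all_zero(self):
        pools = assemble_pools("P", tree=0, shrub=0, herb=0, litter=0, soil=0)
        assert pools.total == 0.0

    def test_missing_pool_named(self):
        with pytest.raises(ValidationError, match="soil"):
            assemble_pools("P", tree=1, shrub=1, herb=1, litter=1)

    def test_conservation_relative(self):
        rng = np.random.default_rng(8)
        vals = rng.uniform(0.1, 200, 5)
        pools = assemble_pools("P", *vals)
        assert pools.total == pytest.approx(float(vals.sum()), rel=1e-9)


def test_unit_audit_plot_reproduces_hand_computed_pools(half_fractions):
    """A fully hand-computed plot: every pool must match to 1e-9."""
    table = AllometryTable(entries={"DEFAULT": AllometryEntry("DEFAULT", a=5.0, b=1.0)})
    sm = make_stem_map([(5, 5), (15, 15)], dbh=[20.0, 10.0])  # biomass 100 + 50 kg
    harvests = [
        HarvestRecord("T", "shrub", 4.0, 0.8),  # 0.2 kg/m2 -> 1.0 Mg C/ha
        HarvestRecord("T", "herb", 1.0, 0.1),  # 0.1 kg/m2 -> 0.5 Mg C/ha
        HarvestRecord("T", "litter", 1.0, 0.4),  # 0.4 kg/m2 -> 2.0 Mg C/ha
    ]
    soil = SoilProfile("T", (SoilLayer(0, 20, bd=1.2, soc=20.0),))  # 48 Mg/ha
    pools = plot_carbon_pools(sm, harvests, soil, table, half_fractions)
    # tree: 150 kg * 0.5 * 25 / 1000 = 1.875 Mg C/ha
    assert pools.tree == pytest.approx(1.875, rel=1e-9)
    assert pools.shrub == pytest.approx(1.0, rel=1e-9)
    assert pools.herb == pytest.approx(0.5, rel=1e-9)
    assert pools.litter == pytest.approx(2.0, rel=1e-9)
    assert pools.soil == pytest.approx(48.0, rel=1e-9)
    assert pools.total == pytest.approx(53.375, rel=1e-9)


def test_harvest_and_soil_tables_roundtrip(tmp_path):
    harvests = [
        HarvestRecord("P01", "shrub", 4.0, 1.25),
        HarvestRecord("P01", "litter", 1.0, 0.4),
        HarvestRecord("P02", "herb", 1.0, 0.11),
    ]
    hp = tmp_path / "harvest.csv"
    pd.DataFrame(
        [
            {"plot_id": h.plot_id, "pool": h.pool, "subplot_area_m2": h.subplot_area, "dry_mass_kg": h.dry_mass}
            for h in harvests
        ]
    ).to_csv(hp, index=False)
    assert read_harvest_table(hp) == harvests

    sp = tmp_path / "soil.csv"
    pd.DataFrame(
        [
            {"plot_id": "P01", "depth_top_cm": 0, "depth_bottom_cm": 20, "bd_g_cm3": 1.1, "soc_g_kg": 25.0},
            {"plot_id": "P01", "depth_top_cm": 20, "depth_bottom_cm": 40, "bd_g_cm3": 1.3, "soc_g_kg": 12.0},
        ]
    ).to_csv(sp, index=False)
    profiles = read_soil_table(sp)
    assert profiles["P01"].layers[1].soc == 12.0


def test_pools_table_columns():
    pools = [assemble_pools("P1", 1, 2, 3, 4, 5), assemble_pools("P2", 5, 4, 3, 2, 1)]
    df = pools_table(pools)
    assert list(df.columns) == ["plot_id", "tree", "shrub", "herb", "litter", "soil", "total"]
    assert df["total"].tolist() == [15.0, 15.0]
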