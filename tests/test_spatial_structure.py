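import math

import numpy as np
import pytest

from conftest import lattice_map, make_stem_map, random_map
from standcarbon.errors import ConfigurationError, StandCarbonError, ValidationError
from standcarbon.spatial_structure import (
    CrownModel,
    EdgePolicy,
    crowding,
    dominance,
    mingling,
    nearest_neighbors,
    spatial_indices,
    uniform_angle,
)

TORUS = EdgePolicy.torus()
NONE = EdgePolicy.none()


def brute_force_neighbors(stem_map, k):
    """Exhaustive all-pairs nearest-neighbor oracle with the id tie-break."""
    out = {}
    trees = stem_map.trees
    for ref in trees:
        cands = sorted(
            ((math.hypot(t.x - ref.x, t.y - ref.y), t.tree_id) for t in trees if t is not ref),
        )
        out[ref.tree_id] = tuple(tid for _, tid in cands[:k])
    return out


class TestNearestNeighbors:
    def test_collinear_symmetry(self):
        sm = make_stem_map([(0, 10), (1, 10), (2, 10), (3, 10), (4, 10)])
        nb = nearest_neighbors(sm, k=2, edge_policy=NONE)
        assert set(nb["t002"].neighbor_ids) == {"t001", "t003"}

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exhaustive_oracle(self, seed):
        sm = random_map(50, seed)
        nb = nearest_neighbors(sm, k=4, edge_policy=NONE)
        oracle = brute_force_neighbors(sm, 4)
        for tid, ns in nb.items():
            assert ns.neighbor_ids == oracle[tid]

    def test_distances_nondecreasing_and_positive(self):
        sm = random_map(40, 3)
        for ns in nearest_neighbors(sm, k=4, edge_policy=NONE).values():
            d = np.array(ns.distances)
            assert np.all(d > 0)
            assert np.all(np.diff(d) >= 0)

    def test_equidistant_tie_broken_by_smaller_id(self):
        # t001 and t002 both at distance 1 from t000; t001 must win
        sm = make_stem_map([(10, 10), (11, 10), (10, 11), (15, 15), (1, 1)])
        nb = nearest_neighbors(sm, k=1, edge_policy=NONE)
        assert nb["t000"].neighbor_ids == ("t001",)

    def test_insufficient_trees_error(self):
        sm = make_stem_map([(1, 1), (2, 2), (3, 3)])
        with pytest.raises(StandCarbonError, match="insufficient"):
            nearest_neighbors(sm, k=4)

    def test_coincident_coordinates_named(self):
        sm = make_stem_map([(1, 1), (1, 1), (3, 3), (4, 4), (5, 5), (6, 6)])
        with pytest.raises(ValidationError, match="t000.*t001"):
            nearest_neighbors(sm, k=4, edge_policy=NONE)


class TestUniformAngle:
    def test_interior_lattice_tree_is_zero(self):
        sm = lattice_map(spacing=5.0)
        per_tree, _ = uniform_angle(sm, edge_policy=EdgePolicy.buffer(5.0))
        assert (per_tree == 0).all()

    def test_all_neighbors_in_narrow_sector_is_one(self):
        # neighbors at azimuths 10, 20, 30, 40 degrees from the reference
        ref = (10.0, 10.0)
        neigh = [
            (10 + math.sin(math.radians(a)), 10 + math.cos(math.radians(a)))
            for a in (10, 20, 30, 40)
        ]
        far = [(1.0, 1.0), (19.0, 1.0), (1.0, 19.0)]
        sm = make_stem_map([ref] + neigh + far)
        per_tree, _ = uniform_angle(sm, edge_policy=NONE)
        assert per_tree["t000"] == 1.0

    def test_values_on_five_point_grid(self):
        sm = random_map(60, 11)
        per_tree, mean = uniform_angle(sm, edge_policy=TORUS)
        assert set(np.round(per_tree * 4).astype(int)) <= {0, 1, 2, 3, 4}
        assert 0 <= mean <= 1

    def test_csr_band(self):
        from standcarbon.synthetic_stands import StandConfig, generate_stand

        means = [
            uniform_angle(
                generate_stand(
                    StandConfig(n_trees=500, pattern="poisson", min_spacing=0.0, seed=s), f"C{s}"
                ),
                edge_policy=TORUS,
            )[1]
            for s in range(20)
        ]
        assert 0.45 <= np.mean(means) <= 0.55


class TestDominance:
    def test_largest_tree_is_zero_smallest_is_one(self):
        dbh = [50.0, 10.0, 20.0, 30.0, 40.0, 5.0]
        sm = make_stem_map([(10, 10), (11, 10), (10, 11), (9, 10), (10, 9), (11, 11)], dbh=dbh)
        per_tree, _ = dominance(sm, edge_policy=NONE)
        assert per_tree["t000"] == 0.0  # plot maximum
        assert per_tree["t005"] == 1.0  # plot minimum

    def test_equal_dbh_counts_zero(self):
        sm = make_stem_map([(10, 10), (11, 10), (10, 11), (9, 10), (10, 9)], dbh=[10.0] * 5)
        per_tree, mean = dominance(sm, edge_policy=NONE)
        assert mean == 0.0

    def test_rank_statistic_invariant_under_monotone_transform(self):
        sm = random_map(80, 5)
        _, u1 = dominance(sm, edge_policy=TORUS)
        sm2 = make_stem_map(
            [(t.x, t.y) for t in sm.trees],
            species=[t.species for t in sm.trees],
            dbh=[t.dbh**2 / 10 for t in sm.trees],
        )
        _, u2 = dominance(sm2, edge_policy=TORUS)
        assert u1 == pytest.approx(u2)

    def test_random_permutation_of_sizes_near_half(self):
        rng = np.random.default_rng(0)
        means = []
        for s in range(10):
            sm = random_map(300, 100 + s)
            means.append(dominance(sm, edge_policy=TORUS)[1])
        assert abs(np.mean(means) - 0.5) < 0.02

    def test_orientation_flag_flips_comparison(self):
        sm = random_map(50, 9)
        s1, _ = dominance(sm, edge_policy=TORUS, orientation="larger")
        s2, _ = dominance(sm, edge_policy=TORUS, orientation="smaller")
        # with continuous DBH there are no ties, so the two must sum to 1
        assert np.allclose(s1 + s2, 1.0)


class TestMingling:
    def test_monoculture_is_zero(self):
        sm = random_map(40, 2)
        mono = make_stem_map([(t.x, t.y) for t in sm.trees], dbh=[t.dbh for t in sm.trees])
        _, m = mingling(mono, edge_policy=TORUS)
        assert m == 0.0

    def test_checkerboard_interior_is_one(self):
        xs = np.arange(1.0, 20.0, 2.0)
        xy = [(x, y) for y in xs for x in xs]
        species = [("A" if (i + j) % 2 == 0 else "B") for j in range(10) for i in range(10)]
        sm = make_stem_map(xy, species=species)
        per_tree, _ = mingling(sm, edge_policy=EdgePolicy.buffer(3.0))
        assert (per_tree == 1.0).all()

    def test_random_two_species_labeling_near_half(self):
        rng = np.random.default_rng(1)
        sm = random_map(400, 42)
        labels = ["A" if u < 0.5 else "B" for u in rng.uniform(size=400)]
        sm2 = make_stem_map([(t.x, t.y) for t in sm.trees], species=labels, dbh=[t.dbh for t in sm.trees])
        _, m = mingling(sm2, edge_policy=TORUS)
        assert abs(m - 0.5) < 0.05


class TestCrowding:
    def test_wide_spacing_is_zero(self):
        sm = lattice_map(spacing=5.0, dbh=[10.0] * 64)  # crown radius 1 m, spacing 5 m
        _, c = crowding(sm, edge_policy=NONE)
        assert c == 0.0

    def test_tight_cluster_is_one(self):
        xy = [(10 + 0.3 * i, 10 + 0.2 * j) for i in range(3) for j in range(2)]
        sm = make_stem_map(xy, dbh=[30.0] * 6)
        _, c = crowding(sm, edge_policy=NONE)
        assert c == 1.0

    def test_exact_touching_crowns_do_not_count(self):
        # radius = 0.5 + 0.05*10 = 1.0 each; distance exactly 2.0
        sm = make_stem_map([(9, 10), (11, 10), (9, 14), (11, 14), (10, 2)], dbh=[10.0] * 5)
        per_tree, _ = crowding(sm, k=1, edge_policy=NONE)
        assert per_tree["t000"] == 0.0

    def test_negative_crown_radius_rejected(self):
        sm = random_map(10, 0)
        with pytest.raises(ConfigurationError):
            crowding(sm, crown_model=CrownModel(c0=-2.0, c1=0.001), edge_policy=NONE)


class TestEdgePolicy:
    def test_buffer_restricts_to_inner_square(self):
        sm = lattice_map(spacing=2.0)
        mask = EdgePolicy.buffer(5.0).eligible(sm)
        xs = np.array([t.x for t in sm.trees])
        ys = np.array([t.y for t in sm.trees])
        inner = (xs >= 5) & (xs <= 15) & (ys >= 5) & (ys <= 15)
        assert (mask == inner).all()

    def test_buffer_too_wide_rejected(self):
        sm = lattice_map(spacing=2.0)
        with pytest.raises(ConfigurationError):
            EdgePolicy.buffer(10.0).eligible(sm)

    def test_torus_translation_invariance(self):
        sm = random_map(100, 7)
        w, h = sm.extent
        shifted = make_stem_map(
            [((t.x + 7.3) % w, (t.y + 3.1) % h) for t in sm.trees],
            species=[t.species for t in sm.trees],
            dbh=[t.dbh for t in sm.trees],
        )
        for fn in (uniform_angle, mingling):
            _, a = fn(sm, edge_policy=TORUS)
            _, b = fn(shifted, edge_policy=TORUS)
            assert a == pytest.approx(b)

    def test_rotation_invariance_with_buffer(self):
        sm = random_map(120, 13)
        w, h = sm.extent
        # rotate 90 degrees about the plot center
        rotated = make_stem_map(
            [(w - t.y, t.x) for t in sm.trees],
            species=[t.species for t in sm.trees],
            dbh=[t.dbh for t in sm.trees],
        )
        for fn in (uniform_angle, mingling):
            _, a = fn(sm, edge_policy=EdgePolicy.buffer(5.0))
            _, b = fn(rotated, edge_policy=EdgePolicy.buffer(5.0))
            assert a == pytest.approx(b)

    def test_none_policy_boundary_trees_blur_lattice_contrast(self):
        sm = lattice_map(spacing=4.0)
        _, w_buffer = uniform_angle(sm, edge_policy=EdgePolicy.buffer(5.0))
        _, w_none = uniform_angle(sm, edge_policy=NONE)
        assert w_buffer == 0.0
        assert w_none > w_buffer


def test_spatial_indices_bundle_matches_individual_calls():
    sm = random_map(60, 21)
    per_tree, means = spatial_indices(sm, edge_policy=TORUS)
    assert list(per_tree.columns) == ["W", "U", "M", "C"]
    assert means["W"] == pytest.approx(uniform_angle(sm, edge_policy=TORUS)[1])
    assert means["C"] == pytest.approx(crowding(sm, edge_policy=TORUS)[1])
    assert all(0 <= v <= 1 for v in means.values())
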