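"""Voxel lattice: occupancy rules, neighborhoods, entry points, window."""
import numpy as np
import pytest

from spatialqsp.lattice import (
    Grid,
    OccupancyError,
    init_grid,
    neighborhood,
    place_entry_points,
    place_entry_points_stratified,
    populate_tumor,
    shift_window,
)
from spatialqsp.lineage import steady_fractions


class TestInitAndGeometry:
    def test_voxel_counts(self):
        assert init_grid((50, 50, 50)).n_voxels == 125_000
        # a 10 x 10 x 0.2 mm slab at 20 um resolution
        assert init_grid((500, 500, 10)).n_voxels == 2_500_000

    def test_one_mm_cube_is_50_voxels_per_edge(self):
        g = init_grid((50, 50, 50), voxel_size=20.0)
        assert g.volume_mm3 == pytest.approx(1.0)

    def test_zero_dimension_rejected(self):
        with pytest.raises(ValueError):
            init_grid((0, 10, 10))

    def test_same_seed_same_entry_points(self):
        layouts = []
        for _ in range(2):
            g = init_grid((20, 20, 20), seed=99)
            place_entry_points(g, 500.0)
            layouts.append(g.entry_points.copy())
        np.testing.assert_array_equal(*layouts)


class TestNeighborhoods:
    @pytest.mark.parametrize(
        "voxel,kind,expected",
        [
            ((5, 5, 5), "Moore", 26),
            ((5, 5, 5), "vonNeumann", 6),
            ((0, 0, 0), "vonNeumann", 3),
            ((0, 0, 0), "Moore", 7),
            ((0, 5, 5), "vonNeumann", 5),
            ((0, 0, 5), "Moore", 11),
        ],
    )
    def test_sizes(self, voxel, kind, expected):
        g = init_grid((11, 11, 11))
        assert len(neighborhood(g, voxel, kind)) == expected

    def test_out_of_range_rejected(self):
        g = init_grid((5, 5, 5))
        with pytest.raises(ValueError):
            neighborhood(g, (5, 0, 0))


class TestOccupancy:
    def test_tcell_cap_without_cancer_is_eight(self):
        g = init_grid((3, 3, 3))
        for _ in range(8):
            g.add_agent("CD8", "effector", (1, 1, 1))
        assert not g.can_place_tcell((1, 1, 1))
        with pytest.raises(OccupancyError):
            g.add_agent("CD8", "effector", (1, 1, 1))

    def test_tcell_cap_with_cancer_is_one(self):
        g = init_grid((3, 3, 3))
        g.add_agent("cancer", "csc", (1, 1, 1))
        g.add_agent("CD8", "effector", (1, 1, 1))
        with pytest.raises(OccupancyError):
            g.add_agent("Treg", "treg", (1, 1, 1))

    def test_single_cancer_slot(self):
        g = init_grid((3, 3, 3))
        g.add_agent("cancer", "csc", (0, 0, 0))
        with pytest.raises(OccupancyError):
            g.add_agent("cancer", "progenitor", (0, 0, 0))

    def test_cancer_blocked_by_crowded_tcells(self):
        g = init_grid((3, 3, 3))
        g.add_agent("CD8", "effector", (1, 1, 1))
        g.add_agent("CD8", "effector", (1, 1, 1))
        assert not g.can_place_cancer((1, 1, 1))

    def test_randomized_insertions_never_violate_caps(self, rng):
        g = init_grid((6, 6, 6), seed=0)
        for _ in range(3000):
            vox = tuple(int(v) for v in rng.integers(0, 6, size=3))
            kind = "cancer" if rng.random() < 0.3 else "CD8"
            try:
                g.add_agent(kind, "csc" if kind == "cancer" else "effector", vox)
            except OccupancyError:
                pass
        cancer_mask = g.cancer_id >= 0
        assert np.all(g.t_count[cancer_mask] <= 1)
        assert np.all(g.t_count[~cancer_mask] <= 8)

    def test_creation_ledger_balances(self, rng):
        g = init_grid((6, 6, 6), seed=0)
        for _ in range(300):
            vox = tuple(int(v) for v in rng.integers(0, 6, size=3))
            try:
                g.add_agent("cancer", "csc", vox)
            except OccupancyError:
                pass
        removed = 0
        for agent in list(g.agents.values())[:50]:
            g.remove_agent(agent)
            removed += 1
        assert g.counts["created"] == len(g.agents) + removed


class TestPopulate:
    def test_fill_zero_empty(self, rates):
        g = init_grid((10, 10, 10), seed=1)
        populate_tumor(g, steady_fractions(rates), 0.0)
        assert len(g.agents) == 0

    def test_fill_one_full(self, rates):
        g = init_grid((6, 6, 6), seed=1)
        populate_tumor(g, steady_fractions(rates), 1.0)
        assert len(g.agents) == 216

    def test_half_fill_lower_z_only(self, rates):
        g = init_grid((6, 6, 8), region_type="front", seed=1)
        populate_tumor(g, steady_fractions(rates), 1.0, half_fill=True)
        zs = {a.position[2] for a in g.agents.values()}
        assert max(zs) == 3  # nz // 2 - 1

    def test_unnormalized_fractions_rejected(self):
        g = init_grid((4, 4, 4))
        with pytest.raises(ValueError):
            populate_tumor(g, [0.5, 0.2], 0.5)

    def test_subtype_mix_binomially_consistent(self, rates):
        fr = steady_fractions(rates)
        g = init_grid((20, 20, 20), seed=5)
        populate_tumor(g, fr, 1.0)
        n = len(g.agents)
        n_csc = sum(1 for a in g.agents.values() if a.state == "csc")
        n_sen = sum(1 for a in g.agents.values() if a.state == "senescent")
        for count, frac in ((n_csc, fr[0]), (n_sen, fr[-1])):
            sigma = np.sqrt(n * frac * (1 - frac))
            assert abs(count - n * frac) < 3 * sigma


class TestEntryPoints:
    def test_zero_density(self):
        g = init_grid((10, 10, 10), seed=0)
        place_entry_points(g, 0.0)
        assert len(g.entry_points) == 0

    def test_poisson_mean_matches_density(self):
        density = 800.0  # per mm^3
        counts = []
        for seed in range(100):
            g = init_grid((10, 10, 10), voxel_size=20.0, seed=seed)
            place_entry_points(g, density)
            counts.append(len(g.entry_points))
        expected = density * g.volume_mm3
        sem = np.sqrt(expected / len(counts))
        assert abs(np.mean(counts) - expected) < 3 * sem

    def test_tenfold_density_ratio_realized(self):
        lo, hi = [], []
        for seed in range(60):
            g1 = init_grid((10, 10, 10), seed=seed)
            place_entry_points(g1, 200.0)
            lo.append(len(g1.entry_points))
            g2 = init_grid((10, 10, 10), seed=1000 + seed)
            place_entry_points(g2, 2000.0)
            hi.append(len(g2.entry_points))
        assert np.mean(hi) / np.mean(lo) == pytest.approx(10.0, rel=0.2)

    def test_stratified_densities_respect_midplane(self):
        g = init_grid((10, 10, 10), seed=3)
        place_entry_points_stratified(g, density_low_z=2000.0, density_high_z=0.0)
        assert len(g.entry_points) > 0
        assert np.all(g.entry_points[:, 2] < 5)


class TestWindowShifting:
    def _front_grid(self, rates, seed=7):
        g = init_grid((8, 8, 12), region_type="front", seed=seed)
        populate_tumor(g, steady_fractions(rates), 1.0, half_fill=True)
        return g

    def test_centered_com_is_identity(self, rates):
        g = self._front_grid(rates)
        before = {a.id: a.position for a in g.agents.values()}
        assert shift_window(g, steady_fractions(rates)) == 0
        assert {a.id: a.position for a in g.agents.values()} == before

    def test_uniform_drift_translates_contents(self, rates):
        g = self._front_grid(rates)
        # push every cancer cell up 2 voxels (simulate upward growth drift)
        for a in sorted(g.agents.values(), key=lambda a: -a.position[2]):
            x, y, z = a.position
            g.cancer_id[a.position] = -1
            a.position = (x, y, z + 2)
            g.cancer_id[a.position] = a.id
        positions_before = {a.id: a.position for a in g.agents.values()}
        shift = shift_window(g, steady_fractions(rates))
        assert shift == -2
        for a in g.agents.values():
            x, y, z = positions_before[a.id]
            assert a.position == (x, y, z - 2)

    def test_shift_preserves_pairwise_geometry(self, rates):
        g = self._front_grid(rates)
        ids = list(g.agents)[:20]
        rel_before = {
            (i, j): tuple(
                np.subtract(g.agents[i].position, g.agents[j].position)
            )
            for i in ids
            for j in ids
        }
        for a in sorted(g.agents.values(), key=lambda a: -a.position[2]):
            x, y, z = a.position
            g.cancer_id[a.position] = -1
            a.position = (x, y, z + 1)
            g.cancer_id[a.position] = a.id
        shift_window(g, steady_fractions(rates))
        for (i, j), rel in rel_before.items():
            if i in g.agents and j in g.agents:
                assert tuple(np.subtract(g.agents[i].position, g.agents[j].position)) == rel

    def test_shrink_repopulates_tumor_side(self, rates):
        g = self._front_grid(rates)
        # cells die at the interface (high z of the filled half): the center
        # of mass drops, so the window tracks back toward the tumor side
        for a in list(g.agents.values()):
            if a.position[2] >= 2:
                g.remove_agent(a)
        fr = steady_fractions(rates)
        shift = shift_window(g, fr, fill_probability=1.0)
        assert shift > 0
        # tumor-side voxels reopened and repopulated
        assert (g.cancer_id[:, :, 0] >= 0).any()

    def test_core_region_rejected(self, rates):
        g = init_grid((6, 6, 6), region_type="core", seed=0)
        populate_tumor(g, steady_fractions(rates), 1.0)
        with pytest.raises(ValueError):
            shift_window(g, steady_fractions(rates))
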