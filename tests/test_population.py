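"""Dasymetric mapping, contour rasterization and regional summary tests."""

from __future__ import annotations

import numpy as np
import pytest
from shapely.geometry import Point, Polygon, box

import _oracles
from noisepop import curves as cv
from noisepop import population as pp
from noisepop.grids import GridSpec, Raster


def spec_10x10(cell=30.0):
    return GridSpec(x0=0.0, y0=10 * cell, cell=cell, nrows=10, ncols=10)


class TestImperviousMask:
    def test_all_transport_excluded(self):
        spec = spec_10x10()
        lc = Raster(values=np.full(spec.shape, 2.0), spec=spec)
        assert not pp.impervious_mask(lc, {1, 2}, {2}).any()

    def test_checkerboard(self):
        spec = spec_10x10()
        vals = np.indices(spec.shape).sum(axis=0) % 2
        lc = Raster(values=vals.astype(float), spec=spec)
        mask = pp.impervious_mask(lc, {1})
        assert np.array_equal(mask, vals == 1)

    def test_hand_counted_fixture(self):
        spec = GridSpec(x0=0, y0=150, cell=30, nrows=5, ncols=5)
        vals = np.array(
            [
                [0, 1, 2, 1, 0],
                [1, 1, 2, 0, 0],
                [2, 2, 2, 1, 1],
                [0, 1, 1, 1, 2],
                [1, 0, 0, 1, 1],
            ],
            dtype=float,
        )
        lc = Raster(values=vals, spec=spec)
        mask = pp.impervious_mask(lc, {1, 2}, {2})
        assert int(mask.sum()) == 12  # hand count of class-1 cells


class TestDistributePopulation:
    def test_equal_split(self):
        spec = spec_10x10()
        block = pp.CensusBlock("B1", box(0, 0, 300, 300), 100.0)
        mask = np.zeros(spec.shape, dtype=bool)
        mask[2, 2] = mask[2, 3] = mask[3, 2] = mask[3, 3] = True
        pop = pp.distribute_population([block], mask, spec)
        assert pop.values[mask].tolist() == [25.0] * 4
        assert pop.values.sum() == pytest.approx(100.0)

    def test_zero_impervious_uniform_fallback(self, caplog):
        spec = spec_10x10()
        block = pp.CensusBlock("B1", box(0, 0, 300, 300), 100.0)
        mask = np.zeros(spec.shape, dtype=bool)
        with caplog.at_level("INFO", logger="noisepop.population"):
            pop = pp.distribute_population([block], mask, spec)
        assert "fallback" in caplog.text
        assert np.allclose(pop.values, 1.0)  # 100 persons over 100 cells

    def test_mass_conservation_random_fixtures(self):
        """Raster total equals block totals on random Voronoi fixtures."""
        from noisepop.synth import gen_census

        spec = GridSpec(x0=0, y0=40 * 30.0, cell=30.0, nrows=40, ncols=40)
        for seed in range(10):
            census = gen_census(spec, n_blocks=8, seed=seed, total_population=5000)
            mask = pp.impervious_mask(census.landcover, {1}, {2})
            pop = pp.distribute_population(census.blocks, mask, spec)
            target = sum(b.population for b in census.blocks)
            assert pop.values.sum() == pytest.approx(target, rel=1e-9)
            assert (pop.values >= 0).all()

    def test_per_block_sums_equal_inputs(self):
        spec = spec_10x10()
        left = pp.CensusBlock("A", box(0, 0, 150, 300), 70.0)
        right = pp.CensusBlock("B", box(150, 0, 300, 300), 30.0)
        mask = np.ones(spec.shape, dtype=bool)
        pop = pp.distribute_population([left, right], mask, spec)
        in_left = pp.cells_in_geometry(spec, box(0, 0, 149, 300))
        assert pop.values[in_left].sum() == pytest.approx(70.0)
        assert pop.values.sum() == pytest.approx(100.0)

    def test_zero_area_block_rejected(self):
        spec = spec_10x10()
        with pytest.raises(ValueError, match="Z"):
            pp.CensusBlock("Z", Polygon([(0, 0), (10, 0), (0, 0)]), 5.0)
        # a block that dodges construction-time validation is still caught
        import dataclasses

        hollow = dataclasses.replace(
            pp.CensusBlock("Z2", box(0, 0, 10, 10), 5.0),
            geometry=box(0, 0, 10, 10).intersection(box(20, 20, 30, 30)),
        )
        with pytest.raises(ValueError, match="Z2"):
            pp.distribute_population([hollow], np.ones(spec.shape, bool), spec)


class TestRasterizeContours:
    def test_single_polygon_fills_grid(self):
        spec = spec_10x10()
        surf = pp.rasterize_contours([(45.0, box(-10, -10, 310, 310))], spec)
        assert np.all(surf.values == 45.0)
        assert not surf.mask.any()

    def test_nested_rings_match_point_in_polygon_oracle(self):
        spec = spec_10x10()
        rings = [
            (45.0, box(0, 0, 300, 300)),
            (50.0, box(60, 60, 240, 240)),
            (55.0, box(120, 120, 180, 180)),
        ]
        surf = pp.rasterize_contours(rings, spec)
        X, Y = spec.cell_centers()
        for r in range(10):
            for c in range(10):
                pt = Point(X[r, c], Y[r, c])
                expected = None
                for level, geom in rings:
                    if geom.covers(pt):
                        expected = max(expected or level, level)
                if expected is None:
                    assert surf.mask[r, c]
                else:
                    assert surf.values[r, c] == expected

    def test_boundary_center_goes_to_higher_contour(self):
        spec = GridSpec(x0=0, y0=60, cell=30, nrows=2, ncols=2)
        # the shared edge x=45 passes exactly through the right cells' centers
        surf = pp.rasterize_contours(
            [(45.0, box(0, 0, 45, 60)), (50.0, box(45, 0, 60, 60))], spec
        )
        assert surf.values[0, 1] == 50.0 and surf.values[1, 1] == 50.0

    def test_metric_tag(self):
        spec = spec_10x10()
        surf = pp.rasterize_contours(
            [(40.0, box(0, 0, 300, 300))], spec, metric="Lnight"
        )
        assert surf.metric == "Lnight"


class TestPopulationByLevel:
    def _uniform(self, level):
        spec = spec_10x10()
        pop = pp.PopulationRaster(values=np.full(spec.shape, 2.0), spec=spec)
        surf = pp.NoiseSurface(
            values=np.full(spec.shape, level), spec=spec, metric="Ldn"
        )
        return pop, surf

    def test_uniform_surface_single_bin(self):
        pop, surf = self._uniform(46.0)
        hist = pp.population_by_level(pop, surf)
        assert len(hist) == 1
        assert hist.bin_lo_db[0] == 45.0
        assert hist.persons[0] == pytest.approx(200.0)

    def test_two_level_surface(self):
        spec = spec_10x10()
        pop = pp.PopulationRaster(values=np.full(spec.shape, 1.0), spec=spec)
        vals = np.full(spec.shape, 47.0)
        vals[:5] = 58.0
        surf = pp.NoiseSurface(values=vals, spec=spec, metric="Ldn")
        hist = pp.population_by_level(pop, surf)
        by_lo = dict(zip(hist.bin_lo_db, hist.persons))
        assert by_lo[45.0] == pytest.approx(50.0)
        assert by_lo[55.0] == pytest.approx(50.0)

    def test_total_invariant_to_bin_width(self):
        rng = np.random.default_rng(6)
        spec = spec_10x10()
        pop = pp.PopulationRaster(values=rng.uniform(0, 5, spec.shape), spec=spec)
        surf = pp.NoiseSurface(
            values=rng.uniform(40, 90, spec.shape), spec=spec, metric="Ldn"
        )
        totals = {
            w: pp.population_by_level(pop, surf, w).persons.sum()
            for w in (1.0, 2.5, 5.0, 10.0)
        }
        assert np.allclose(list(totals.values()), pop.values.sum())

    def test_fully_masked_surface_is_empty(self):
        spec = spec_10x10()
        pop = pp.PopulationRaster(values=np.ones(spec.shape), spec=spec)
        surf = pp.NoiseSurface(
            values=np.zeros(spec.shape),
            spec=spec,
            mask=np.ones(spec.shape, bool),
            metric="Ldn",
        )
        assert pp.population_by_level(pop, surf).empty

    def test_misaligned_grids_rejected(self):
        pop, _ = self._uniform(46.0)
        other = GridSpec(x0=15.0, y0=300.0, cell=30.0, nrows=10, ncols=10)
        surf = pp.NoiseSurface(
            values=np.full(other.shape, 50.0), spec=other, metric="Ldn"
        )
        with pytest.raises(ValueError):
            pp.population_by_level(pop, surf)


class TestRegionSummary:
    def _world(self):
        spec = spec_10x10()
        pop = pp.PopulationRaster(values=np.full(spec.shape, 3.0), spec=spec)
        vals = np.full(spec.shape, 30.0)
        vals[:, 5:] = 50.0  # east half exposed
        surf = pp.NoiseSurface(values=vals, spec=spec, metric="Ldn")
        west = pp.Region("west", box(0, 0, 150, 300), kind="county")
        east = pp.Region("east", box(150, 0, 300, 300), kind="county")
        tribal = pp.Region("tribal", box(150, 0, 300, 150), kind="tribal")
        return pop, surf, [west, east, tribal]

    def test_threshold_counts_and_tribal_overlap(self):
        pop, surf, regions = self._world()
        table = pp.region_summary(pop, {"Ldn": surf}, regions)
        rows = table.set_index("region_id")
        assert rows.loc["east", "exposed"] == pytest.approx(150.0)
        assert rows.loc["west", "exposed"] == pytest.approx(0.0)
        # tribal cells counted both in their own row and in the county row
        assert rows.loc["tribal", "exposed"] == pytest.approx(75.0)
        assert rows.loc["Total", "exposed"] == pytest.approx(150.0)
        assert rows.loc["east", "exposed_pct"] == pytest.approx(100.0)

    def test_matches_brute_force_oracle(self):
        pop, surf, regions = self._world()
        table = pp.region_summary(pop, {"Ldn": surf}, regions)
        total = table.set_index("region_id").loc["Total"]
        expected = _oracles.brute_exposed(pop.values, surf.values, surf.mask, 45.0)
        assert total["exposed"] == pytest.approx(expected)

    def test_additive_over_disjoint_counties(self):
        pop, surf, regions = self._world()
        table = pp.region_summary(pop, {"Ldn": surf}, regions).set_index("region_id")
        counties = table[table.kind == "county"]
        assert counties["exposed"].sum() == pytest.approx(table.loc["Total", "exposed"])
        assert counties["population"].sum() == pytest.approx(
            table.loc["Total", "population"]
        )

    def test_region_outside_extent_warns_and_zeroes(self, caplog):
        pop, surf, _ = self._world()
        faraway = pp.Region("nowhere", box(10_000, 10_000, 10_300, 10_300))
        with caplog.at_level("WARNING", logger="noisepop.population"):
            table = pp.region_summary(pop, {"Ldn": surf}, [faraway])
        assert "nowhere" in caplog.text
        row = table.set_index("region_id").loc["nowhere"]
        assert row["population"] == 0.0 and row["exposed"] == 0.0

    def test_missing_metric_yields_nan(self):
        pop, surf, regions = self._world()
        table = pp.region_summary(pop, {"Ldn": surf}, regions)
        assert table["sleep_risk"].isna().all()
        thresholds = cv.ThresholdSet(hearing_leq24=45.0)
        table2 = pp.region_summary(
            pop, {"Leq24": pp.NoiseSurface(values=surf.values, spec=surf.spec,
                                           metric="Leq24")},
            regions, thresholds,
        )
        assert table2.set_index("region_id").loc["Total", "hearing_risk"] > 0
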