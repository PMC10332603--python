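import itertools
import math

import numpy as np
import pytest

from isoassign import (
    CalibrationModel,
    GeoGrid,
    GridGeometry,
    RegionMask,
    UncertaintySurface,
    assign_cohort,
    combined_sigma,
    odds_region,
    parse_odds,
    probability_surface,
    region_centroid_distance,
    stack_regions,
)
from isoassign.assignment import ProbabilitySurface, region_centroid
from isoassign.geodesy import haversine_km
from isoassign.grid import AlignmentError, GridError


def model(sd_resid=12.8, slope=0.93, intercept=-31.6):
    return CalibrationModel(intercept=intercept, slope=slope,
                            sd_resid=sd_resid, r2_adj=0.7, n=73)


def make_grid(values, west=0.0, north=None, cw=1.0, ch=1.0, units="permil"):
    values = np.asarray(values, dtype=float)
    north = north if north is not None else float(values.shape[0])
    geom = GridGeometry(values.shape[0], values.shape[1], west, north, cw, ch)
    return GeoGrid(geometry=geom, values=values, units=units)


def three_cell_surface():
    """The hand-checked 1x3 fixture: mu = (-80, -100, -120), sigma = 10,
    observation -100."""
    feather = make_grid([[-80.0, -100.0, -120.0]])
    sigma = make_grid(np.full((1, 3), 10.0))
    return probability_surface(-100.0, feather, sigma, individual_id="toy")


class TestParseOdds:
    def test_ratio_strings(self):
        assert parse_odds("2:1") == pytest.approx(2.0 / 3.0)
        assert parse_odds("3:1") == pytest.approx(0.75)

    def test_fractions(self):
        assert parse_odds(0.5) == 0.5
        assert parse_odds("0.9") == 0.9

    def test_invalid(self):
        with pytest.raises(ValueError):
            parse_odds(0.0)
        with pytest.raises(ValueError):
            parse_odds("0:1")


class TestCombinedSigma:
    def test_no_uncertainty_collapses_to_sd_resid(self, small_geometry):
        out = combined_sigma(model(sd_resid=12.8), None, small_geometry)
        np.testing.assert_allclose(out.values, 12.8)

    def test_pure_isoscape_error(self, small_geometry):
        unc = UncertaintySurface(
            GeoGrid(small_geometry, np.full((3, 3), 5.0), units="permil")
        )
        out = combined_sigma(model(sd_resid=0.0, slope=1.0), unc)
        np.testing.assert_allclose(out.values, 5.0)

    def test_quadrature_3_4_5(self, small_geometry):
        unc = UncertaintySurface(
            GeoGrid(small_geometry, np.full((3, 3), 8.0), units="permil")
        )
        out = combined_sigma(model(sd_resid=3.0, slope=0.5), unc)
        np.testing.assert_allclose(out.values, 5.0)

    def test_unscaled_variant(self, small_geometry):
        unc = UncertaintySurface(
            GeoGrid(small_geometry, np.full((3, 3), 4.0), units="permil")
        )
        out = combined_sigma(model(sd_resid=3.0, slope=0.5), unc,
                             scale_by_slope=False)
        np.testing.assert_allclose(out.values, 5.0)

    def test_sigma_never_below_sd_resid(self, small_geometry):
        rng = np.random.default_rng(0)
        unc = UncertaintySurface(
            GeoGrid(small_geometry, rng.uniform(0, 10, (3, 3)),
                    units="permil")
        )
        out = combined_sigma(model(sd_resid=7.0), unc)
        assert np.all(out.values >= 7.0 - 1e-12)


class TestProbabilitySurface:
    def test_uniform_limit(self):
        feather = make_grid(np.full((4, 5), -100.0))
        sigma = make_grid(np.full((4, 5), 10.0))
        surface = probability_surface(-90.0, feather, sigma)
        np.testing.assert_allclose(surface.grid.values, 1.0 / 20.0)

    def test_three_cell_brute_force(self):
        surface = three_cell_surface()
        dens = np.exp(-0.5 * ((np.array([-80.0, -100.0, -120.0]) + 100.0)
                              / 10.0) ** 2) / (10.0 * math.sqrt(2 * math.pi))
        expected = dens / dens.sum()
        np.testing.assert_allclose(surface.grid.values[0], expected, rtol=1e-12)
        np.testing.assert_allclose(
            surface.grid.values[0], [0.1065, 0.7870, 0.1065], atol=5e-5
        )

    def test_sums_to_one(self, synthetic_world):
        isoscape, unc = synthetic_world
        m = model(sd_resid=14.0, slope=0.8, intercept=-60.0)
        from isoassign import predict_feather_isoscape

        feather = predict_feather_isoscape(isoscape, m)
        sigma = combined_sigma(m, unc)
        for value in (-150.0, -100.0, -50.0):
            surface = probability_surface(value, feather, sigma)
            assert abs(np.nansum(surface.grid.values) - 1.0) < 1e-9

    def test_mask_zeroes_excluded_cells(self):
        feather = make_grid(np.full((2, 4), -100.0))
        sigma = make_grid(np.full((2, 4), 10.0))
        mask = RegionMask.from_bounds(0.0, 0.0, 2.0, 2.0, "west-half")
        surface = probability_surface(-100.0, feather, sigma, mask=mask)
        assert np.isnan(surface.grid.values[:, 2:]).all()
        np.testing.assert_allclose(surface.grid.values[:, :2], 0.25)

    def test_scaling_densities_leaves_surface_invariant(self):
        # Normalization divides by the domain sum, so any positive rescaling
        # of the unnormalized densities yields the same surface; sigma /= 2
        # with mu == y rescales every density by the same factor.
        feather = make_grid(np.full((3, 3), -100.0))
        a = probability_surface(-100.0, feather, make_grid(np.full((3, 3), 10.0)))
        b = probability_surface(-100.0, feather, make_grid(np.full((3, 3), 5.0)))
        np.testing.assert_allclose(a.grid.values, b.grid.values, rtol=1e-12)

    def test_empty_domain_errors(self):
        feather = make_grid(np.full((2, 2), np.nan))
        sigma = make_grid(np.full((2, 2), 10.0))
        with pytest.raises(GridError, match="empty"):
            probability_surface(-100.0, feather, sigma)

    def test_zero_sigma_errors(self):
        feather = make_grid(np.full((2, 2), -100.0))
        sigma = make_grid(np.zeros((2, 2)))
        with pytest.raises(GridError, match="sigma"):
            probability_surface(-100.0, feather, sigma)

    def test_misaligned_grids_error(self):
        feather = make_grid(np.full((2, 2), -100.0))
        sigma = make_grid(np.full((2, 2), 10.0), west=1.0)
        with pytest.raises(AlignmentError):
            probability_surface(-100.0, feather, sigma)


class TestOddsRegion:
    def test_uniform_ten_cells(self):
        surface = ProbabilitySurface(
            make_grid(np.full((2, 5), 0.1), units="probability")
        )
        region = odds_region(surface, 2.0 / 3.0)
        assert region.cell_count == 7  # ceil(10 * 2/3)
        assert region.achieved_mass == pytest.approx(0.7)

    def test_three_cell_region_is_center(self):
        region = odds_region(three_cell_surface(), 2.0 / 3.0)
        np.testing.assert_array_equal(region.included,
                                      [[False, True, False]])
        assert region.achieved_mass == pytest.approx(0.786986, abs=1e-5)

    def test_odds_one_includes_all_valid(self):
        values = np.full((3, 3), 1.0 / 8.0)
        values[1, 1] = np.nan
        surface = ProbabilitySurface(make_grid(values, units="probability"))
        region = odds_region(surface, 1.0)
        assert region.cell_count == 8
        assert not region.included[1, 1]

    def test_tie_break_row_major(self):
        surface = ProbabilitySurface(
            make_grid(np.full((1, 4), 0.25), units="probability")
        )
        region = odds_region(surface, 0.5)
        np.testing.assert_array_equal(region.included,
                                      [[True, True, False, False]])

    def test_minimality(self):
        rng = np.random.default_rng(17)
        for _ in range(50):
            values = rng.random((5, 6))
            values /= values.sum()
            surface = ProbabilitySurface(make_grid(values, units="probability"))
            region = odds_region(surface)
            probs = surface.grid.values[region.included]
            assert region.achieved_mass >= 2.0 / 3.0 - 1e-12
            assert region.achieved_mass - probs.min() < 2.0 / 3.0

    def test_exhaustive_small_grid_oracle(self):
        # On <= 12 cells the greedy prefix must match the smallest subset
        # with mass >= 2/3 found by exhaustive search.
        rng = np.random.default_rng(23)
        for _ in range(25):
            n = int(rng.integers(3, 13))
            values = rng.random(n)
            values /= values.sum()
            surface = ProbabilitySurface(
                make_grid(values.reshape(1, n), units="probability")
            )
            region = odds_region(surface)
            best = min(
                (
                    len(subset)
                    for k in range(1, n + 1)
                    for subset in itertools.combinations(range(n), k)
                    if values[list(subset)].sum() >= 2.0 / 3.0 - 1e-12
                ),
            )
            assert region.cell_count == best

    def test_monotone_in_odds_fraction(self):
        surface = three_cell_surface()
        inner = odds_region(surface, 0.5)
        outer = odds_region(surface, 0.95)
        assert np.all(outer.included[inner.included])

    def test_flattening_with_larger_sigma(self):
        feather = make_grid(np.linspace(-140, -60, 25).reshape(5, 5))
        previous = None
        for scale in (1.0, 2.0, 4.0, 8.0):
            sigma = make_grid(np.full((5, 5), 10.0 * scale))
            surface = probability_surface(-100.0, feather, sigma)
            peak = np.nanmax(surface.grid.values)
            if previous is not None:
                assert peak <= previous + 1e-12
            previous = peak


class TestStackAndCentroids:
    def test_stack_single_region(self):
        region = odds_region(three_cell_surface())
        stack = stack_regions([region])
        np.testing.assert_array_equal(stack.values, region.included)

    def test_stack_identical_regions(self):
        region = odds_region(three_cell_surface())
        stack = stack_regions([region] * 5)
        assert set(np.unique(stack.values)) <= {0.0, 5.0}

    def test_stack_disjoint_regions(self):
        a = odds_region(ProbabilitySurface(
            make_grid([[1.0, 0.0]], units="probability")), 0.9)
        b = odds_region(ProbabilitySurface(
            make_grid([[0.0, 1.0]], units="probability")), 0.9)
        stack = stack_regions([a, b])
        assert stack.values.max() == 1.0

    def test_identical_regions_zero_distance(self):
        region = odds_region(three_cell_surface())
        assert region_centroid_distance(region, region) == 0.0

    def test_one_degree_longitude_at_equator(self):
        def single_cell_region(west):
            geom = GridGeometry(1, 1, west, 0.5, 1.0, 1.0)
            surface = ProbabilitySurface(
                GeoGrid(geom, np.array([[1.0]]), units="probability")
            )
            return odds_region(surface, 0.9)

        d = region_centroid_distance(single_cell_region(-0.5),
                                     single_cell_region(0.5))
        assert d == pytest.approx(111.19, abs=0.01)

    def test_symmetric_region_centroid_on_meridian(self):
        geom = GridGeometry(3, 5, -2.5, 40.0, 1.0, 1.0)
        included = np.zeros((3, 5), dtype=bool)
        included[1, :] = True  # symmetric about lon 0
        region = odds_region(
            ProbabilitySurface(
                GeoGrid(geom, included / included.sum(), units="probability")
            ),
            0.99,
        )
        lon, lat = region_centroid(region)
        assert lon == pytest.approx(0.0, abs=1e-9)


class TestAssignCohort:
    def setup_method(self):
        rows = np.linspace(-150.0, -60.0, 30)
        self.feather = make_grid(np.repeat(rows[:, None], 30, axis=1),
                                 west=-120.0, north=60.0, cw=0.5, ch=0.5)
        self.sigma = make_grid(np.full((30, 30), 12.0),
                               west=-120.0, north=60.0, cw=0.5, ch=0.5)

    def test_cohort_of_one_stack_is_indicator(self):
        result = assign_cohort([-100.0], self.feather, self.sigma)
        np.testing.assert_array_equal(result.stack.values,
                                      result.regions[0].included)

    def test_equal_values_identical_regions(self):
        result = assign_cohort([-100.0, -100.0], self.feather, self.sigma)
        np.testing.assert_array_equal(result.regions[0].included,
                                      result.regions[1].included)

    def test_shifted_value_moves_centroid_finite_distance(self):
        base, up, down = assign_cohort(
            [-110.0, -110.0 + 6.8, -110.0 - 6.8], self.feather, self.sigma
        ).regions
        for other in (up, down):
            d = region_centroid_distance(base, other)
            assert 0.0 < d < 2000.0

    def test_summary_table(self):
        result = assign_cohort([-100.0, -120.0], self.feather, self.sigma,
                               ids=["a", "b"])
        assert list(result.summary["id"]) == ["a", "b"]
        assert (result.summary["achieved_mass"] >= 2.0 / 3.0).all()
        assert (result.summary["region_cells"] > 0).all()

    def test_range_mask_limits_regions(self):
        mask = RegionMask.from_bounds(-120.0, 45.0, -105.0, 60.0, "range")
        result = assign_cohort([-130.0], self.feather, self.sigma,
                               range_mask=mask)
        rows, _ = np.nonzero(result.regions[0].included)
        # Masked to the northern half: no included cell south of lat 45.
        assert rows.max() < 30
        lat_of_lowest = 60.0 - (rows.max() + 0.5) * 0.5
        assert lat_of_lowest >= 45.0
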