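"""Generator contracts: climate structure, ground truth, sampling, CO2, pollen."""

import numpy as np
import pandas as pd
import pytest

import paleoveg as pv
from paleoveg.grids import TEMPERATURE_VARS, PRECIPITATION_VARS
from paleoveg.pollen import EXCLUDED_WETLAND
from paleoveg.synthetic import (
    DEFAULT_NICHES,
    default_precip_scale,
    default_temp_anomaly,
)


class TestClimateStack:
    def test_temperature_follows_lapse_rate(self, small_spec, small_stack):
        """Mean annual temperature is an exact affine function of elevation:
        a 1000 m cell under a 0.6 deg/100 m lapse and 28 deg at sea level
        must sit at 22.0 deg."""
        t = small_stack.layer("annual_mean_temp")
        elev = small_stack.elevation
        expected = small_spec.sea_level_temp - small_spec.lapse_rate * elev / 100.0
        np.testing.assert_allclose(t, expected, atol=1e-12)
        slope, intercept = np.polyfit(elev.ravel(), t.ravel(), 1)
        assert intercept + slope * 1000.0 == pytest.approx(22.0, abs=1e-9)

    @pytest.mark.parametrize("var", TEMPERATURE_VARS)
    def test_lapse_regression_recovers_rate_for_every_temperature_layer(
        self, small_spec, var
    ):
        stack = pv.generate_climate_stack(small_spec, 0.0, full_bioclim=True)
        slope = np.polyfit(stack.elevation.ravel(), stack.layer(var).ravel(), 1)[0]
        assert slope == pytest.approx(-small_spec.lapse_rate / 100.0, abs=1e-6)

    def test_same_seed_gives_bit_identical_stacks(self, small_spec):
        a = pv.generate_climate_stack(small_spec, 5.0, full_bioclim=True)
        b = pv.generate_climate_stack(small_spec, 5.0, full_bioclim=True)
        for var in a.var_names:
            np.testing.assert_array_equal(a.layer(var), b.layer(var))
        np.testing.assert_array_equal(a.elevation, b.elevation)

    def test_temperature_anomaly_is_exactly_additive(self, small_spec):
        base = pv.generate_climate_stack(small_spec, 0.0, temp_anomaly=0.0,
                                         precip_scale=1.0, full_bioclim=True)
        cold = pv.generate_climate_stack(small_spec, 0.0, temp_anomaly=-4.0,
                                         precip_scale=1.0, full_bioclim=True)
        for var in TEMPERATURE_VARS:
            np.testing.assert_allclose(
                cold.layer(var), base.layer(var) - 4.0, atol=1e-12
            )
        np.testing.assert_array_equal(
            cold.layer("annual_precip"), base.layer("annual_precip")
        )

    def test_precipitation_scales_multiplicatively_and_stays_non_negative(
        self, small_spec
    ):
        base = pv.generate_climate_stack(small_spec, 0.0, temp_anomaly=0.0,
                                         precip_scale=1.0)
        dry = pv.generate_climate_stack(small_spec, 0.0, temp_anomaly=0.0,
                                        precip_scale=0.5)
        for var in set(PRECIPITATION_VARS) & set(base.var_names):
            np.testing.assert_allclose(dry.layer(var), 0.5 * base.layer(var),
                                       rtol=1e-12)
            assert dry.layer(var).min() >= 0

    def test_invalid_spec_rejected(self):
        with pytest.raises(pv.InvalidSpecError):
            pv.LandscapeSpec(n_rows=4)
        with pytest.raises(pv.InvalidSpecError):
            pv.LandscapeSpec(cell_size_km=0.0)
        with pytest.raises(pv.InvalidSpecError):
            pv.generate_climate_stack(pv.LandscapeSpec(), 0.0, precip_scale=0.0)

    def test_default_anomaly_schedule_is_cold_and_dry_at_glacial_peak(self):
        assert default_temp_anomaly(22.0) == pytest.approx(-6.0)
        assert default_precip_scale(22.0) == pytest.approx(0.8)
        assert default_temp_anomaly(0.0) == 0.0
        assert default_precip_scale(0.0) == 1.0


class TestTrueVegetation:
    def test_single_permissive_niche_claims_every_cell(self, small_stack):
        niche = pv.NicheDefinition(
            "X", {"annual_mean_temp": 15.0}, {"annual_mean_temp": 1e6}
        )
        vm = pv.generate_true_vegetation(small_stack, [niche])
        assert (vm.codes == 0).all()

    def test_unreachable_niche_leaves_only_no_analog(self, small_stack):
        niche = pv.NicheDefinition(
            "X", {"annual_mean_temp": 500.0}, {"annual_mean_temp": 0.1}
        )
        vm = pv.generate_true_vegetation(small_stack, [niche])
        assert (vm.codes == pv.NO_ANALOG).all()

    def test_argmax_matches_per_cell_brute_force(self, small_stack):
        niches = list(DEFAULT_NICHES[:3])
        vm = pv.generate_true_vegetation(small_stack, niches)
        suits = np.stack([n.suitability(small_stack) for n in niches])
        for idx in np.ndindex(8, 8):  # spot-check a sub-block cell by cell
            cell = tuple(i * 5 for i in idx)
            s = suits[(slice(None), *cell)]
            expected = s.argmax() if s.max() >= 0.1 else pv.NO_ANALOG
            assert vm.codes[cell] == expected

    def test_two_niche_boundary_is_an_elevation_contour(self, small_stack):
        lo = pv.NicheDefinition("LO", {"annual_mean_temp": 24.0},
                                {"annual_mean_temp": 6.0})
        hi = pv.NicheDefinition("HI", {"annual_mean_temp": 8.0},
                                {"annual_mean_temp": 6.0})
        vm = pv.generate_true_vegetation(small_stack, [lo, hi])
        elev = small_stack.elevation
        if vm.mask("LO").any() and vm.mask("HI").any():
            assert elev[vm.mask("HI")].min() > elev[vm.mask("LO")].max() - 1e-9

    def test_altitudinal_belt_ordering(self, small_stack, small_truth):
        elev = small_stack.elevation
        means = {u: elev[small_truth.mask(u)].mean() for u in ("AA", "EB", "DAF")}
        assert means["AA"] > means["EB"] > means["DAF"]

    def test_empty_niche_list_rejected(self, small_stack):
        with pytest.raises(ValueError):
            pv.generate_true_vegetation(small_stack, [])


class TestPresenceSampling:
    def test_points_fall_inside_unit_cells(self, small_truth):
        occ = pv.sample_presences(small_truth, "DAF", 500, seed=3)
        assert len(occ) == 500
        row, col = small_truth.geometry.cell_of(occ.x, occ.y)
        assert small_truth.mask("DAF")[row, col].all()

    def test_same_seed_reproduces_point_set(self, small_truth):
        a = pv.sample_presences(small_truth, "EB", 50, seed=5)
        b = pv.sample_presences(small_truth, "EB", 50, seed=5)
        np.testing.assert_array_equal(a.x, b.x)
        np.testing.assert_array_equal(a.y, b.y)

    def test_single_cell_unit_contains_its_point(self):
        geom = pv.GridGeometry(8, 8, 1.0)
        codes = np.zeros((8, 8), dtype=np.int64)
        codes[3, 4] = 1
        vm = pv.VegetationUnitMap(geom, codes, ("A", "B"))
        occ = pv.sample_presences(vm, "B", 1, seed=0)
        row, col = geom.cell_of(occ.x, occ.y)
        assert (row[0], col[0]) == (3, 4)

    def test_absent_unit_raises_empty_extent(self):
        geom = pv.GridGeometry(8, 8, 1.0)
        vm = pv.VegetationUnitMap(geom, np.zeros((8, 8), dtype=np.int64), ("A", "B"))
        with pytest.raises(pv.EmptyExtentError):
            pv.sample_presences(vm, "B", 10, seed=0)


class TestCO2Series:
    def test_endpoints_and_monotonicity(self):
        ages = list(range(22, -1, -1))
        series = pv.generate_co2_series(ages)
        assert series.at(22.0) == pytest.approx(185.0)
        assert series.at(0.0) == pytest.approx(280.0)
        assert 185.0 < series.at(11.0) < 280.0
        conc = np.array(series.co2_ppm)  # oldest first -> non-decreasing
        assert (np.diff(conc) >= 0).all()

    def test_empty_ages_rejected(self):
        with pytest.raises(ValueError):
            pv.generate_co2_series([])


def _toy_grouping():
    rows = [("a1", "A"), ("a2", "A"), ("b1", "B"), ("w1", EXCLUDED_WETLAND)]
    return pv.load_taxa_grouping(
        pd.DataFrame(rows, columns=["taxon", "assignment"]), units=("A", "B")
    )


class TestPollenGenerator:
    def _map_all(self, label_codes, units, age):
        geom = pv.GridGeometry(10, 10, 1.0)
        return pv.VegetationUnitMap(geom, label_codes, units, age_ka=age)

    def test_site_inside_only_present_unit_gets_full_assignable_share(self):
        codes = np.zeros((10, 10), dtype=np.int64)  # everything is A
        vm = self._map_all(codes, ("A", "B"), 1.0)
        rec = pv.generate_pollen_record(
            (5.0, 5.0), [vm], _toy_grouping(), counts_per_sample=4000, seed=1
        )
        counts = rec.counts.iloc[0]
        assert counts["b1"] == 0  # B absent from the map entirely
        assert counts[["a1", "a2"]].sum() > 0

    def test_zero_counts_rejected(self):
        codes = np.zeros((10, 10), dtype=np.int64)
        vm = self._map_all(codes, ("A", "B"), 1.0)
        with pytest.raises(ValueError):
            pv.generate_pollen_record((5.0, 5.0), [vm], _toy_grouping(),
                                      counts_per_sample=0)

    def test_off_grid_site_rejected(self):
        codes = np.zeros((10, 10), dtype=np.int64)
        vm = self._map_all(codes, ("A", "B"), 1.0)
        with pytest.raises(pv.OffGridError):
            pv.generate_pollen_record((50.0, 5.0), [vm], _toy_grouping())

    def test_multinomial_proportions_recover_specified_mixture(self):
        # A on the left half, B on the right; site on the A side.
        codes = np.zeros((10, 10), dtype=np.int64)
        codes[:, 5:] = 1
        vm = self._map_all(codes, ("A", "B"), 0.0)
        site = (2.5, 5.5)
        rec = pv.generate_pollen_record(
            site, [vm], _toy_grouping(), counts_per_sample=10_000, seed=2,
            decay_km=20.0, wetland_prop=0.08, ambiguous_prop=0.05,
        )
        d_b = pv.habitat_distance(vm, site, "B")
        w = np.array([1.0, np.exp(-d_b / 20.0)])
        expected = 0.92 * w / w.sum()  # wetland background takes 8%
        counts = rec.counts.iloc[0]
        total = counts.sum()
        got = np.array(
            [counts[["a1", "a2"]].sum() / total, counts["b1"] / total]
        )
        np.testing.assert_allclose(got, expected, atol=0.02)

    def test_group_share_decreases_with_habitat_distance(self):
        codes = np.zeros((10, 10), dtype=np.int64)
        codes[:, 8:] = 1  # B far right
        vm = self._map_all(codes, ("A", "B"), 0.0)
        shares = []
        for x in (7.5, 1.5):  # near B, then far from B
            rec = pv.generate_pollen_record(
                (x, 5.5), [vm], _toy_grouping(), counts_per_sample=20_000, seed=3
            )
            c = rec.counts.iloc[0]
            shares.append(c["b1"] / c.sum())
        assert shares[0] > shares[1]
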