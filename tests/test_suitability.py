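"""THS scoring, raster projection, classification and scenario deltas."""

import numpy as np
import pytest
import xarray as xr

from thermoniche.models import RR_PARAMS, TPCParameters
from thermoniche.suitability import (
    SuitabilityError,
    SuitabilityRaster,
    annual_report,
    classify,
    project,
    read_raster,
    scenario_delta,
    ths_score,
    write_raster,
)
from thermoniche.tpc import TPCFit


def _grid(values, name="sst"):
    values = np.asarray(values, dtype=float)
    ny, nx = values.shape
    return xr.DataArray(
        values,
        dims=("lat", "lon"),
        coords={"lat": np.linspace(30, 46, ny), "lon": np.linspace(0, 10, nx)},
        name=name,
    )


def _suit(values, month=1, scenario="current"):
    return SuitabilityRaster(grid=_grid(values, "ths"), month=month, scenario=scenario)


@pytest.fixture(scope="module")
def shallow():
    return _grid(np.full((4, 5), 10.0), "depth")


class TestScore:
    def test_unity_at_the_optimum(self, rr_curve):
        assert ths_score(RR_PARAMS.t_opt, rr_curve) == pytest.approx(1.0, abs=1e-9)

    def test_winter_temperature_score(self, rr_curve):
        # frozen closed-form ratio: rate(12)/rate(t_opt) = 0.1603
        assert ths_score(12.0, rr_curve) == pytest.approx(0.1603, abs=1e-3)

    def test_beyond_ctmax_collapses(self, rr_curve):
        assert ths_score(45.0, rr_curve) < 0.05

    def test_scale_free_in_rate_units(self, rr_curve):
        scaled = TPCFit.from_parameters(
            TPCParameters(
                r_tref=RR_PARAMS.r_tref * 37.0,
                e=RR_PARAMS.e,
                eh=RR_PARAMS.eh,
                t_opt=RR_PARAMS.t_opt,
            )
        )
        t = np.linspace(0.0, 45.0, 50)
        assert np.allclose(ths_score(t, rr_curve), ths_score(t, scaled), atol=1e-12)

    def test_nan_propagates(self, rr_curve):
        out = ths_score(np.array([20.0, np.nan]), rr_curve)
        assert np.isfinite(out[0]) and np.isnan(out[1])


class TestProject:
    def test_uniform_optimum_gives_all_ones(self, rr_curve, shallow):
        sst = _grid(np.full((4, 5), RR_PARAMS.t_opt))
        out = project(sst, shallow, rr_curve)
        assert np.allclose(out.grid.values, 1.0)

    def test_deep_cells_fully_masked(self, rr_curve):
        sst = _grid(np.full((4, 5), 20.0))
        deep = _grid(np.full((4, 5), 500.0), "depth")
        out = project(sst, deep, rr_curve)
        assert np.all(np.isnan(out.grid.values))
        with pytest.raises(SuitabilityError, match="no unmasked"):
            classify(out)

    def test_depth_cutoff_and_land_masking(self, rr_curve):
        sst = _grid(np.full((2, 3), 20.0))
        depth = _grid(np.array([[np.nan, 10.0, 49.9], [50.0, 50.1, 400.0]]), "depth")
        out = project(sst, depth, rr_curve, depth_cutoff=50.0)
        finite = np.isfinite(out.grid.values)
        assert finite.tolist() == [[False, True, True], [True, False, False]]

    def test_gradient_is_unimodal_with_peak_near_t_opt(self, rr_curve):
        t = np.linspace(5.0, 40.0, 71)
        sst = _grid(np.tile(t, (2, 1)))
        depth = _grid(np.full((2, 71), 10.0), "depth")
        out = project(sst, depth, rr_curve)
        row = out.grid.values[0]
        peak = int(np.argmax(row))
        assert abs(t[peak] - RR_PARAMS.t_opt) <= (t[1] - t[0])
        assert np.all(np.diff(row[: peak + 1]) >= -1e-12)
        assert np.all(np.diff(row[peak:]) <= 1e-12)

    def test_grid_mismatch_reports_both_shapes(self, rr_curve, shallow):
        sst = _grid(np.full((3, 5), 20.0))
        with pytest.raises(SuitabilityError, match=r"\(3, 5\).*\(4, 5\)"):
            project(sst, shallow, rr_curve)


class TestClassify:
    def test_uniform_half_lands_in_middle_class(self):
        summary = classify(_suit(np.full((3, 3), 0.5)))
        assert summary.percentages[2] == pytest.approx(100.0)

    def test_two_cells_split_between_extremes(self):
        summary = classify(_suit(np.array([[0.1, 0.9]])))
        assert summary.percentages[0] == pytest.approx(50.0)
        assert summary.percentages[4] == pytest.approx(50.0)

    def test_left_closed_bins_and_top_edge(self):
        summary = classify(_suit(np.array([[0.2, 1.0]])))
        assert summary.percentages[1] == pytest.approx(50.0)  # 0.2 -> [0.2, 0.4)
        assert summary.percentages[4] == pytest.approx(50.0)  # 1.0 -> [0.8, 1.0]

    def test_percentages_sum_to_hundred(self, rng):
        summary = classify(_suit(rng.random((13, 17))))
        assert summary.percentages.sum() == pytest.approx(100.0, abs=1e-6)

    def test_counts_conserved_with_mask(self, rng):
        vals = rng.random((10, 10))
        vals[rng.random((10, 10)) < 0.3] = np.nan
        raster = _suit(vals)
        summary = classify(raster)
        counts = summary.percentages / 100.0 * raster.n_unmasked
        assert counts.sum() == pytest.approx(raster.n_unmasked)

    def test_bad_edges_rejected(self):
        raster = _suit(np.full((2, 2), 0.5))
        with pytest.raises(SuitabilityError):
            classify(raster, edges=(0.0, 0.4, 0.2, 1.0))
        with pytest.raises(SuitabilityError):
            classify(raster, edges=(0.1, 0.5, 1.0))


class TestDeltas:
    def test_identical_summaries_give_zero(self):
        a = classify(_suit(np.array([[0.1, 0.5, 0.9]])))
        b = classify(_suit(np.array([[0.1, 0.5, 0.9]]), scenario="rcp45"))
        delta = scenario_delta(b, a)
        assert np.allclose(delta.deltas, 0.0)

    def test_deltas_sum_to_zero(self, rng):
        a = classify(_suit(rng.random((6, 6))))
        b = classify(_suit(rng.random((6, 6)), scenario="rcp85"))
        delta = scenario_delta(b, a)
        assert delta.deltas.sum() == pytest.approx(0.0, abs=1e-6)

    def test_month_mismatch_rejected(self):
        a = classify(_suit(np.full((2, 2), 0.5), month=1))
        b = classify(_suit(np.full((2, 2), 0.5), month=2, scenario="rcp45"))
        with pytest.raises(SuitabilityError, match="month"):
            scenario_delta(b, a)

    def test_warming_below_optimum_never_decreases_ths(self, rr_curve, rng):
        sst_vals = rng.uniform(8.0, 30.0, (5, 6))
        depth = _grid(np.full((5, 6), 10.0), "depth")
        cold = project(_grid(sst_vals), depth, rr_curve)
        warm = project(_grid(sst_vals + 1.5), depth, rr_curve)
        assert np.all(warm.grid.values >= cold.grid.values - 1e-12)
        assert warm.grid.values.mean() > cold.grid.values.mean()


class TestRoundTripAndReport:
    def test_netcdf_round_trip(self, tmp_path, rng):
        vals = rng.random((8, 9))
        vals[0, 0] = np.nan
        raster = _suit(vals, month=7, scenario="rcp45")
        path = tmp_path / "ths.nc"
        write_raster(raster, path)
        back = read_raster(path)
        assert back.month == 7 and back.scenario == "rcp45"
        assert np.array_equal(np.isnan(back.grid.values), np.isnan(vals))
        ok = ~np.isnan(vals)
        assert np.allclose(back.grid.values[ok], vals[ok], atol=1e-6)

    def test_constant_optimum_year_is_all_top_class(self, rr_curve):
        rasters = {
            "current": [
                project(
                    _grid(np.full((3, 4), RR_PARAMS.t_opt)),
                    _grid(np.full((3, 4), 10.0), "depth"),
                    rr_curve,
                    month=m,
                )
                for m in range(1, 13)
            ]
        }
        table = annual_report(rasters)
        assert len(table) == 12
        assert np.allclose(table["pct_0.8-1.0"], 100.0)

    def test_seasonal_cycle_peaks_in_august(self, rr_curve):
        depth = _grid(np.full((3, 4), 10.0), "depth")
        months = np.arange(1, 13)
        sst_by_month = 20.0 + 7.0 * np.cos(2 * np.pi * (months - 8) / 12.0)
        rasters = {
            "current": [
                project(_grid(np.full((3, 4), sst_by_month[m - 1])), depth,
                        rr_curve, month=m)
                for m in months
            ]
        }
        table = annual_report(rasters)
        assert len(table) == 12
        mean_ths = [float(np.nanmean(r.grid.values)) for r in rasters["current"]]
        assert int(np.argmax(mean_ths)) + 1 == 8

    def test_missing_month_listed(self, rr_curve):
        raster = _suit(np.full((2, 2), 0.5), month=3)
        with pytest.raises(SuitabilityError, match=r"\[1, 2, 4"):
            annual_report({"current": [raster]})

    def test_report_rows_scale_with_scenarios(self, rng):
        rasters = {
            scen: [_suit(rng.random((3, 3)), month=m, scenario=scen)
                   for m in range(1, 13)]
            for scen in ("current", "rcp45", "rcp85")
        }
        table = annual_report(rasters)
        assert len(table) == 36
        deltas = table.filter(like="delta_")
        future = table["scenario"] != "current"
        assert np.allclose(deltas[future].sum(axis=1), 0.0, atol=1e-6)
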