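"""Thermal habitat suitability (THS): from fitted TPC to classified maps.

The THS score at a temperature is the TPC-predicted rate divided by the
rate at the curve's optimum, a dimensionless value in [0, 1]: 1 means the
cell's temperature sits at the metabolic optimum, values near 0 mean the
temperature is physiologically marginal. Scores are projected onto monthly
sea-surface-temperature rasters, restricted to shallow coastal cells
(bathymetry 0-50 m by default, the benthic polyp's habitat), binned into
five suitability classes and compared across warming scenarios.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr

SCENARIOS = ("current", "rcp45", "rcp85")
DEFAULT_DEPTH_CUTOFF = 50.0  # metres
DEFAULT_CLASS_EDGES = (0.0, 0.2, 0.4, 0.6, 0.8, 1.0)


class SuitabilityError(ValueError):
    """Raised for invalid rasters, grids or class definitions."""


@dataclass
class SuitabilityRaster:
    """Gridded THS for one month and scenario.

    ``grid`` is a 2-D (lat, lon) DataArray with values in [0, 1]; masked
    cells (land, or seabed deeper than the cutoff) are NaN.
    """

    grid: xr.DataArray
    month: int
    scenario: str

    def __post_init__(self) -> None:
        if not 1 <= self.month <= 12:
            raise SuitabilityError(f"month must be 1-12, got {self.month}")
        if self.scenario not in SCENARIOS:
            raise SuitabilityError(
                f"unknown scenario {self.scenario!r}; expected one of {SCENARIOS}"
            )
        vals = self.grid.values
        finite = vals[np.isfinite(vals)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise SuitabilityError("unmasked THS values must lie in [0, 1]")

    @property
    def n_unmasked(self) -> int:
        return int(np.isfinite(self.grid.values).sum())


@dataclass
class ClassSummary:
    """Percentage of unmasked cells per suitability class for one month."""

    month: int
    scenario: str
    edges: tuple[float, ...]
    percentages: np.ndarray
    deltas: np.ndarray | None = field(default=None)

    @property
    def class_labels(self) -> list[str]:
        return [
            f"{a:.1f}-{b:.1f}" for a, b in zip(self.edges[:-1], self.edges[1:])
        ]


def ths_score(temperature, fit) -> np.ndarray:
    """THS = predicted(T) / predicted(T_peak), clipped to [0, 1].

    NaN temperatures propagate (masked cells stay masked). Scale-free: any
    rescaling of the rate axis cancels in the ratio.
    """
    peak = fit.peak_rate()
    if not np.isfinite(peak) or peak <= 0:
        raise SuitabilityError("fitted curve has non-positive peak rate")
    t = np.asarray(temperature, dtype=float)
    scalar = t.ndim == 0
    t = np.atleast_1d(t)
    score = np.full(t.shape, np.nan)
    ok = np.isfinite(t)
    if np.any(ok):
        score[ok] = np.clip(np.asarray(fit.predict(t[ok])) / peak, 0.0, 1.0)
    if scalar:
        return float(score[0])
    return score


def project(
    sst: xr.DataArray,
    bathymetry: xr.DataArray,
    fit,
    depth_cutoff: float = DEFAULT_DEPTH_CUTOFF,
    month: int = 1,
    scenario: str = "current",
) -> SuitabilityRaster:
    """Project a fitted TPC onto one monthly SST raster.

    ``bathymetry`` holds positive depths in metres with land as NaN; cells
    deeper than ``depth_cutoff`` or on land are masked in the output.
    """
    if sst.shape != bathymetry.shape:
        raise SuitabilityError(
            f"SST grid {sst.shape} does not match bathymetry grid "
            f"{bathymetry.shape}"
        )
    for dim in sst.dims:
        if dim in bathymetry.coords and not np.array_equal(
            sst[dim].values, bathymetry[dim].values
        ):
            raise SuitabilityError(f"coordinate mismatch along {dim!r}")
    score = ths_score(sst.values, fit)
    depth = bathymetry.values
    mask = ~np.isfinite(depth) | (depth > depth_cutoff)
    score = np.where(mask, np.nan, score)
    grid = xr.DataArray(
        score, dims=sst.dims, coords=sst.coords, name="ths", attrs={"units": "1"}
    )
    return SuitabilityRaster(grid=grid, month=month, scenario=scenario)


def classify(
    raster: SuitabilityRaster,
    edges: tuple[float, ...] = DEFAULT_CLASS_EDGES,
) -> ClassSummary:
    """Percentage of unmasked cells in each suitability class.

    Bins are half-open [a, b) except the last, which is closed so a score of
    exactly 1 lands in the top class; counts are unweighted.
    """
    edges = tuple(float(e) for e in edges)
    if len(edges) < 2 or np.any(np.diff(edges) <= 0):
        raise SuitabilityError("class edges must be strictly increasing")
    if edges[0] > 0 or edges[-1] < 1:
        raise SuitabilityError("class edges must cover [0, 1]")
    vals = raster.grid.values
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise SuitabilityError(
            f"no unmasked cells to classify (month {raster.month}, "
            f"scenario {raster.scenario})"
        )
    # right=False gives [a, b); fold top-edge values into the last class
    idx = np.digitize(vals, edges[1:-1], right=False)
    counts = np.bincount(idx, minlength=len(edges) - 1)
    percentages = 100.0 * counts / vals.size
    return ClassSummary(
        month=raster.month,
        scenario=raster.scenario,
        edges=edges,
        percentages=percentages,
    )


def scenario_delta(future: ClassSummary, current: ClassSummary) -> ClassSummary:
    """Per-class percentage-point change, future minus current."""
    if future.month != current.month:
        raise SuitabilityError(
            f"month mismatch: {future.month} vs {current.month}"
        )
    if future.edges != current.edges:
        raise SuitabilityError("class edges differ between summaries")
    return ClassSummary(
        month=future.month,
        scenario=future.scenario,
        edges=future.edges,
        percentages=future.percentages,
        deltas=future.percentages - current.percentages,
    )


def annual_report(
    rasters: dict[str, list[SuitabilityRaster]],
    edges: tuple[float, ...] = DEFAULT_CLASS_EDGES,
) -> pd.DataFrame:
    """Twelve-month class summary per scenario, with deltas vs current.

    ``rasters`` maps scenario name to its 12 monthly rasters. Returns one
    row per month x scenario with five class-percentage columns and, for
    non-current scenarios, five delta columns.
    """
    for scenario, monthly in rasters.items():
        months = sorted(r.month for r in monthly)
        missing = sorted(set(range(1, 13)) - set(months))
        if missing:
            raise SuitabilityError(
                f"scenario {scenario!r} is missing months {missing}"
            )
    current_by_month: dict[int, ClassSummary] = {}
    if "current" in rasters:
        for r in rasters["current"]:
            current_by_month[r.month] = classify(r, edges)
    rows = []
    for scenario, monthly in rasters.items():
        for r in sorted(monthly, key=lambda x: x.month):
            summary = classify(r, edges)
            if scenario != "current" and r.month in current_by_month:
                summary = scenario_delta(summary, current_by_month[r.month])
            row: dict[str, object] = {"month": r.month, "scenario": scenario}
            for label, pct in zip(summary.class_labels, summary.percentages):
                row[f"pct_{label}"] = pct
            if summary.deltas is not None:
                for label, d in zip(summary.class_labels, summary.deltas):
                    row[f"delta_{label}"] = d
            rows.append(row)
    return pd.DataFrame(rows)


def write_raster(raster: SuitabilityRaster, path) -> None:
    """Write a suitability raster to NetCDF (mask stored as NaN)."""
    ds = raster.grid.to_dataset(name="ths")
    ds.attrs.update({"month": raster.month, "scenario": raster.scenario})
    ds.to_netcdf(path, engine="scipy")


def read_raster(path) -> SuitabilityRaster:
    """Read a suitability raster written by :func:`write_raster`."""
    with xr.open_dataset(path, engine="scipy") as ds:
        grid = ds["ths"].load()
        month = int(ds.attrs["month"])
        scenario = str(ds.attrs["scenario"])
    return SuitabilityRaster(grid=grid, month=month, scenario=scenario)
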