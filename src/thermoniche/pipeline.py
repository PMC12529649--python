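"""End-to-end pipeline: simulate -> rates -> fit -> limits -> maps -> report.

Each stage writes its artifacts under the configured output directory and
registers them in a manifest (JSON) carrying the seed and a config hash, so
a rerun with an identical config reproduces the same bytes for the CSV and
report outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd

from . import io as tio
from .config import PipelineConfig
from .models import model_family
from .plotting import render_month_map, render_tpc_figure
from .respirometry import process_experiment, rates_to_frame, summarize_rates
from .suitability import annual_report, project, write_raster
from .synthetic import gen_bathymetry, gen_respirometry, gen_sst
from .tpc import (
    aic_table,
    bootstrap_bands,
    fit_family,
    limits_sensitivity,
    select_best,
    thermal_limits,
)

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and its inputs."""


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis on synthetic inputs; return the artifact bundle.

    The bundle maps artifact names to file paths (all inside
    ``config.outdir``); the manifest lists every output with its SHA-256.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:  # noqa: BLE001 - annotate and re-raise
            raise PipelineError(
                f"stage {name!r} failed (seed={config.seed}, "
                f"config={config.config_hash()}): {exc}"
            ) from exc

    # -- simulate ---------------------------------------------------------
    traces, metadata = stage(
        "simulate",
        gen_respirometry,
        config.design,
        noise_sd=config.fitting.noise_sd,
        seed=config.seed,
    )
    if config.write_traces:
        tio.write_traces_csv(traces, outdir / "traces.csv")
        artifacts["traces"] = outdir / "traces.csv"
        tio.write_metadata_csv(metadata, outdir / "chambers.csv")
        artifacts["chambers"] = outdir / "chambers.csv"

    # -- rates ------------------------------------------------------------
    rates = stage(
        "rates",
        process_experiment,
        traces,
        metadata,
        discard_initial=config.fitting.discard_initial,
    )
    replicate_df = rates_to_frame(rates)
    tio.write_rates_csv(replicate_df, outdir / "rates_replicates.csv")
    artifacts["rates_replicates"] = outdir / "rates_replicates.csv"
    summary = summarize_rates(rates)
    tio.write_rates_csv(summary, outdir / "rates_summary.csv")
    artifacts["rates_summary"] = outdir / "rates_summary.csv"

    # -- fit + limits (RR and GPP) ---------------------------------------
    models = (
        model_family(list(config.fitting.models))
        if config.fitting.models is not None
        else None
    )
    report: dict = {"seed": config.seed, "config_hash": config.config_hash()}
    best_fits = {}
    for rate_col in ("rr", "gpp"):
        fits = stage(
            f"fit:{rate_col}",
            fit_family,
            replicate_df["temp_C"],
            replicate_df[rate_col],
            models=models,
            n_starts=config.fitting.n_starts,
            seed=config.seed,
        )
        best = select_best(fits)
        best_fits[rate_col] = best
        bands = stage(
            f"bootstrap:{rate_col}",
            bootstrap_bands,
            best,
            replicate_df["temp_C"],
            replicate_df[rate_col],
            n_boot=config.fitting.n_boot,
            seed=config.seed,
        )
        best.bootstrap_bands = bands
        bands_path = outdir / f"curve_{rate_col}.csv"
        tio.write_rates_csv(bands, bands_path)
        artifacts[f"curve_{rate_col}"] = bands_path
        limits = stage(
            f"limits:{rate_col}",
            thermal_limits,
            best,
            threshold=config.fitting.ct_threshold,
        )
        sensitivity = limits_sensitivity(best, config.fitting.ct_sensitivity)
        report[rate_col] = {
            "model_id": best.model_id,
            "parameters": best.parameters,
            "rss": best.rss,
            "aic": best.aic,
            "aic_table": aic_table(fits),
            "t_opt_C": best.peak_temperature(),
            "peak_rate": best.peak_rate(),
            "ct_threshold": config.fitting.ct_threshold,
            "ctmin_C": limits.ctmin,
            "ctmax_C": limits.ctmax,
            "ct_sensitivity": sensitivity,
        }
        logger.info(
            "%s: best model %s, t_opt=%.2f degC, CT=[%.2f, %.2f] at theta=%.3f",
            rate_col,
            best.model_id,
            best.peak_temperature(),
            limits.ctmin,
            limits.ctmax,
            config.fitting.ct_threshold,
        )
        if config.render_figures:
            fig_path = outdir / f"tpc_{rate_col}.png"
            render_tpc_figure(
                best,
                replicate_df["temp_C"],
                replicate_df[rate_col],
                fig_path,
                bands=bands,
                limits=limits,
            )
            artifacts[f"tpc_figure_{rate_col}"] = fig_path
    report_path = outdir / "fit_report.json"
    tio.write_fit_report(report, report_path)
    artifacts["fit_report"] = report_path

    # -- maps -------------------------------------------------------------
    clim = config.resolved_climatology()
    bathy = stage("bathymetry", gen_bathymetry, clim)
    tio.write_bathymetry_netcdf(bathy, outdir / "bathymetry.nc")
    artifacts["bathymetry"] = outdir / "bathymetry.nc"
    rr_fit = best_fits["rr"]
    rasters: dict[str, list] = {}
    for scenario in config.scenarios:
        sst = stage("sst", gen_sst, clim, scenario)
        tio.write_sst_netcdf(sst, outdir / f"sst_{scenario}.nc")
        artifacts[f"sst_{scenario}"] = outdir / f"sst_{scenario}.nc"
        monthly = []
        for month in range(1, 13):
            raster = stage(
                f"project:{scenario}:{month}",
                project,
                sst.sel(month=month),
                bathy,
                rr_fit,
                depth_cutoff=config.depth_cutoff,
                month=month,
                scenario=scenario,
            )
            monthly.append(raster)
            nc_path = outdir / f"ths_{scenario}_{month:02d}.nc"
            write_raster(raster, nc_path)
            artifacts[f"ths_{scenario}_{month:02d}"] = nc_path
            if config.render_figures and month in (2, 8):
                png = outdir / f"ths_{scenario}_{month:02d}.png"
                render_month_map(raster, png)
                artifacts[f"ths_map_{scenario}_{month:02d}"] = png
        rasters[scenario] = monthly

    # -- report -----------------------------------------------------------
    table = stage("report", annual_report, rasters, config.class_edges)
    table_path = outdir / "class_summary.csv"
    tio.write_rates_csv(table, table_path)
    artifacts["class_summary"] = table_path

    manifest = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "outputs": {
            name: {"path": str(path), "sha256": _sha256(path)}
            for name, path in sorted(artifacts.items())
        },
    }
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2) + "\n")
    artifacts["manifest"] = manifest_path
    return {name: str(path) for name, path in artifacts.items()}


def _sha256(path: Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def load_class_summary(path) -> pd.DataFrame:
    return pd.read_csv(path)
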