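"""Figure rendering: fitted TPCs and monthly suitability maps."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
from matplotlib.colors import BoundaryNorm, ListedColormap

from .suitability import SuitabilityRaster
from .tpc import TPCFit, ThermalLimits

# Five suitability classes, pessimum red through optimum blue, mirroring
# the convention: optimum green/blue, pejus yellow/orange, pessimum red.
CLASS_COLORS = ("#d73027", "#fc8d59", "#fee08b", "#66bd63", "#3288bd")


def render_tpc_figure(
    fit: TPCFit,
    temperature,
    rate,
    path,
    bands=None,
    limits: ThermalLimits | None = None,
    rate_label: str = "rate (mg O$_2$ h$^{-1}$ g$^{-1}$)",
) -> None:
    """Replicate scatter, fitted curve, optional 95 % band and CT markers."""
    temperature = np.asarray(temperature, dtype=float)
    rate = np.asarray(rate, dtype=float)
    fig, ax = plt.subplots(figsize=(6, 4))
    if bands is not None:
        ax.fill_between(
            bands["temp_C"],
            bands["lower"],
            bands["upper"],
            color="0.8",
            label="95% band",
        )
    grid = np.linspace(temperature.min() - 2, temperature.max() + 2, 300)
    ax.plot(grid, fit.predict(grid), color="k", lw=1.5, label=fit.model_id)
    ax.scatter(temperature, rate, s=14, alpha=0.5, color="C0", label="replicates")
    t_pk = fit.peak_temperature()
    ax.axvline(t_pk, color="green", ls="--", lw=1)
    ax.annotate(f"OPT {t_pk:.1f}", (t_pk, fit.peak_rate()), color="green",
                xytext=(4, 4), textcoords="offset points", fontsize=8)
    if limits is not None:
        ax.axvline(limits.ctmax, color="green", ls=":", lw=1)
        ax.annotate(f"CMT {limits.ctmax:.1f}", (limits.ctmax, 0), color="green",
                    xytext=(4, 4), textcoords="offset points", fontsize=8)
    ax.set_xlabel("temperature (°C)")
    ax.set_ylabel(rate_label)
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def render_month_map(raster: SuitabilityRaster, path) -> None:
    """One monthly THS map with the five-class colour scale."""
    edges = np.array([0.0, 0.2, 0.4, 0.6, 0.8, 1.0])
    cmap = ListedColormap(CLASS_COLORS)
    cmap.set_bad("0.9")
    norm = BoundaryNorm(edges, cmap.N)
    fig, ax = plt.subplots(figsize=(6, 3.5))
    mesh = ax.pcolormesh(
        raster.grid["lon"],
        raster.grid["lat"],
        raster.grid.values,
        cmap=cmap,
        norm=norm,
        shading="auto",
    )
    fig.colorbar(mesh, ax=ax, label="thermal habitat suitability", ticks=edges)
    ax.set_title(f"month {raster.month:02d} — {raster.scenario}")
    ax.set_xlabel("longitude")
    ax.set_ylabel("latitude")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
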