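"""CSV and NetCDF dialects consumed and emitted by the pipeline.

Trace CSV (one row per oxygen reading):
    chamber_id, phase, target_temp_C, time_s, o2_mg_per_L[, is_control]

Metadata CSV (one row per chamber):
    chamber_id, volume_L, n_polyps, wet_mg, dry_mg, is_control

Rates summary CSV (one row per temperature):
    temp_C, rr_mean, rr_se, npp_mean, npp_se, gpp_mean, gpp_se, n

Readers are format-tolerant: unknown columns are ignored.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

from .respirometry import ChamberMeta, OxygenTrace

_FLOAT_FMT = "%.10g"  # fixed formatting so identical runs emit identical bytes


def write_traces_csv(traces: list[OxygenTrace], path) -> None:
    frames = [
        pd.DataFrame(
            {
                "chamber_id": trace.chamber_id,
                "phase": trace.phase,
                "target_temp_C": trace.target_temperature,
                "time_s": trace.time,
                "o2_mg_per_L": trace.oxygen,
                "is_control": trace.is_control,
            }
        )
        for trace in traces
    ]
    pd.concat(frames, ignore_index=True).to_csv(
        path, index=False, float_format=_FLOAT_FMT
    )


def read_traces_csv(path, metadata: dict[str, ChamberMeta] | None = None) -> list[OxygenTrace]:
    """Read traces; the control flag comes from the CSV if present,
    otherwise from ``metadata``."""
    df = pd.read_csv(path)
    required = {"chamber_id", "phase", "target_temp_C", "time_s", "o2_mg_per_L"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"trace CSV {path} is missing columns {sorted(missing)}")
    traces = []
    for (chamber_id, phase), grp in df.groupby(["chamber_id", "phase"], sort=True):
        grp = grp.sort_values("time_s")
        if "is_control" in df.columns:
            is_control = bool(grp["is_control"].iloc[0])
        elif metadata is not None and chamber_id in metadata:
            is_control = metadata[chamber_id].is_control
        else:
            is_control = False
        traces.append(
            OxygenTrace(
                chamber_id=str(chamber_id),
                phase=str(phase),
                target_temperature=float(grp["target_temp_C"].iloc[0]),
                time=grp["time_s"].to_numpy(dtype=float),
                oxygen=grp["o2_mg_per_L"].to_numpy(dtype=float),
                is_control=is_control,
            )
        )
    return traces


def write_metadata_csv(metadata: dict[str, ChamberMeta], path) -> None:
    rows = [
        {
            "chamber_id": m.chamber_id,
            "volume_L": m.volume,
            "n_polyps": m.n_polyps,
            "wet_mg": m.wet_weight,
            "dry_mg": m.dry_weight,
            "is_control": m.is_control,
        }
        for m in sorted(metadata.values(), key=lambda m: m.chamber_id)
    ]
    pd.DataFrame(rows).to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_metadata_csv(path) -> dict[str, ChamberMeta]:
    df = pd.read_csv(path)
    required = {"chamber_id", "volume_L", "is_control"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"metadata CSV {path} is missing columns {sorted(missing)}")
    metadata: dict[str, ChamberMeta] = {}
    for _, row in df.iterrows():
        wet = row.get("wet_mg")
        dry = row.get("dry_mg")
        metadata[str(row["chamber_id"])] = ChamberMeta(
            chamber_id=str(row["chamber_id"]),
            volume=float(row["volume_L"]),
            n_polyps=int(row.get("n_polyps", 0)),
            wet_weight=None if pd.isna(wet) else float(wet),
            dry_weight=None if pd.isna(dry) else float(dry),
            is_control=bool(row["is_control"]),
        )
    return metadata


def write_rates_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_rates_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_fit_report(report: dict, path) -> None:
    """Structured fit report (model choice, parameters, AIC table, limits)."""
    Path(path).write_text(json.dumps(_jsonable(report), indent=2) + "\n")


def read_fit_report(path) -> dict:
    return json.loads(Path(path).read_text())


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, pd.DataFrame):
        return _jsonable(obj.to_dict(orient="records"))
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj


def write_sst_netcdf(sst: xr.DataArray, path) -> None:
    sst.to_dataset(name="sst").to_netcdf(path, engine="scipy")


def read_sst_netcdf(path) -> xr.DataArray:
    with xr.open_dataset(path, engine="scipy") as ds:
        return ds["sst"].load()


def write_bathymetry_netcdf(depth: xr.DataArray, path) -> None:
    depth.to_dataset(name="depth").to_netcdf(path, engine="scipy")


def read_bathymetry_netcdf(path) -> xr.DataArray:
    with xr.open_dataset(path, engine="scipy") as ds:
        return ds["depth"].load()
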