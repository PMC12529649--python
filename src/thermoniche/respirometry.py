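"""Closed-chamber respirometry: oxygen time series to mass-specific metabolic rates.

Each chamber holds two pooled polyps and is measured for one hour in darkness
(oxygen consumption, respiration rate RR) followed by one hour in light
(net oxygen flux, net primary production NPP). A polyp-free control chamber
run at the same temperature corrects for any background oxygen drift.

Rates are standardized to milligrams of O2 per hour per gram dry weight:

    RR  = |(slope_dark  - slope_control)| * 3600 * V / DW
    NPP =  (slope_light - slope_control)  * 3600 * V / DW
    GPP =  NPP + |RR|

with slopes in mg O2 L^-1 s^-1, chamber volume V in litres and dry weight
DW in grams. RR is stored as a magnitude; the consumption sign convention
(declining oxygen gives a negative slope) lives only in the slope estimate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Seconds discarded at the start of every trace (settling after transfer).
DEFAULT_DISCARD_S = 300.0

#: Minimum number of retained points for a slope estimate.
MIN_POINTS = 10


class RespirometryError(ValueError):
    """Raised for invalid traces, metadata or rate inputs."""


@dataclass(frozen=True)
class OxygenTrace:
    """One chamber x phase dissolved-oxygen time series.

    Parameters
    ----------
    chamber_id : str
        Identifier of the respiration chamber.
    phase : {"dark", "light"}
        Illumination phase during the recording.
    target_temperature : float
        Treatment temperature in degrees Celsius.
    time : ndarray
        Sampling times in seconds, strictly increasing.
    oxygen : ndarray
        Dissolved oxygen in mg O2 per litre, non-negative.
    is_control : bool
        True for the polyp-free control chamber.
    """

    chamber_id: str
    phase: str
    target_temperature: float
    time: np.ndarray
    oxygen: np.ndarray
    is_control: bool = False

    def __post_init__(self) -> None:
        time = np.asarray(self.time, dtype=float)
        oxygen = np.asarray(self.oxygen, dtype=float)
        object.__setattr__(self, "time", time)
        object.__setattr__(self, "oxygen", oxygen)
        if self.phase not in ("dark", "light"):
            raise RespirometryError(
                f"chamber {self.chamber_id}: phase must be 'dark' or 'light', "
                f"got {self.phase!r}"
            )
        if time.ndim != 1 or oxygen.ndim != 1 or time.size != oxygen.size:
            raise RespirometryError(
                f"chamber {self.chamber_id}: time and oxygen must be 1-D arrays "
                "of equal length"
            )
        if time.size < 2:
            raise RespirometryError(
                f"chamber {self.chamber_id}: trace needs at least 2 points"
            )
        if np.any(np.diff(time) <= 0):
            raise RespirometryError(
                f"chamber {self.chamber_id}: time must be strictly increasing"
            )
        if np.any(oxygen < 0):
            raise RespirometryError(
                f"chamber {self.chamber_id}: oxygen values must be non-negative"
            )


@dataclass(frozen=True)
class ChamberMeta:
    """Chamber metadata: volume, polyp count and weights.

    Weights are in milligrams as weighed; :attr:`dry_weight_g` converts to
    grams for the rate formula.
    """

    chamber_id: str
    volume: float = 0.0008  # litres
    n_polyps: int = 2
    wet_weight: float | None = None  # mg
    dry_weight: float | None = None  # mg
    is_control: bool = False

    def __post_init__(self) -> None:
        if self.volume <= 0:
            raise RespirometryError(
                f"chamber {self.chamber_id}: volume must be positive"
            )
        if not self.is_control:
            if self.dry_weight is None or self.dry_weight <= 0:
                raise RespirometryError(
                    f"chamber {self.chamber_id}: dry weight must be positive "
                    "for experimental chambers"
                )
        if (
            self.dry_weight is not None
            and self.wet_weight is not None
            and self.dry_weight > self.wet_weight
        ):
            raise RespirometryError(
                f"chamber {self.chamber_id}: dry weight exceeds wet weight"
            )

    @property
    def dry_weight_g(self) -> float:
        if self.dry_weight is None:
            raise RespirometryError(
                f"chamber {self.chamber_id}: dry weight unavailable"
            )
        return self.dry_weight * 1e-3


@dataclass(frozen=True)
class MetabolicRates:
    """Per-replicate mass-specific rates (mg O2 h^-1 g^-1 dry weight)."""

    replicate_id: str
    target_temperature: float
    rr: float
    npp: float
    gpp: float = field(default=np.nan)

    def __post_init__(self) -> None:
        if self.rr < 0:
            raise RespirometryError(
                f"replicate {self.replicate_id}: rr must be non-negative"
            )
        if np.isnan(self.gpp):
            object.__setattr__(self, "gpp", gross_primary_production(self.npp, self.rr))


def estimate_slope(trace: OxygenTrace, discard_initial: float = DEFAULT_DISCARD_S) -> float:
    """Ordinary-least-squares slope of oxygen vs time, mg O2 L^-1 s^-1.

    The first ``discard_initial`` seconds (relative to the trace start) are
    dropped to let the chamber settle. The sign is preserved: consumption
    yields a negative slope.
    """
    if discard_initial < 0:
        raise RespirometryError("discard_initial must be non-negative")
    t0 = trace.time[0] + discard_initial
    keep = trace.time >= t0
    t = trace.time[keep]
    o2 = trace.oxygen[keep]
    if t.size < MIN_POINTS:
        raise RespirometryError(
            f"chamber {trace.chamber_id} ({trace.phase}): only {t.size} points "
            f"remain after discarding the first {discard_initial:g} s "
            f"(need >= {MIN_POINTS})"
        )
    slope, _ = np.polyfit(t, o2, 1)
    return float(slope)


def respiration_rate(
    slope: float,
    volume: float,
    dry_weight: float,
    control_slope: float = 0.0,
) -> float:
    """Mass-specific respiration rate from a dark-phase slope.

    Parameters are the raw slope (mg O2 L^-1 s^-1), chamber volume (L) and
    dry weight (g); the control slope at the same temperature is subtracted
    before standardization. Returned as a magnitude (mg O2 h^-1 g^-1 DW).
    """
    if volume <= 0:
        raise RespirometryError("volume must be positive")
    if dry_weight <= 0:
        raise RespirometryError("dry weight must be positive")
    if abs(control_slope) > abs(slope):
        logger.warning(
            "control slope magnitude (%.3g) exceeds experimental slope (%.3g); "
            "corrected rate may reflect control drift",
            control_slope,
            slope,
        )
    return abs(slope - control_slope) * 3600.0 * volume / dry_weight


def net_primary_production(
    slope: float,
    volume: float,
    dry_weight: float,
    control_slope: float = 0.0,
) -> float:
    """Mass-specific net primary production from a light-phase slope.

    Same standardization as :func:`respiration_rate` but sign-preserving:
    positive values mean net oxygen production.
    """
    if volume <= 0:
        raise RespirometryError("volume must be positive")
    if dry_weight <= 0:
        raise RespirometryError("dry weight must be positive")
    return (slope - control_slope) * 3600.0 * volume / dry_weight


def gross_primary_production(npp: float, rr: float) -> float:
    """GPP = NPP + |RR| (holobiont respiration assumed constant over the day)."""
    if rr < 0:
        raise RespirometryError("rr must be non-negative")
    return npp + abs(rr)


def process_experiment(
    traces: list[OxygenTrace],
    metadata: dict[str, ChamberMeta],
    discard_initial: float = DEFAULT_DISCARD_S,
    control_correction: bool = True,
) -> list[MetabolicRates]:
    """Turn a full experiment's traces into per-replicate rates.

    Chambers are grouped by target temperature; at each temperature the mean
    control slope of that phase (zero if no control chamber was run, or if
    ``control_correction`` is off) is subtracted from every experimental
    slope. A replicate is one experimental chamber with both a dark and a
    light trace.
    """
    by_temp: dict[float, dict[str, dict[str, float]]] = {}
    control_slopes: dict[tuple[float, str], list[float]] = {}
    for trace in traces:
        slope = estimate_slope(trace, discard_initial)
        if trace.is_control:
            control_slopes.setdefault(
                (trace.target_temperature, trace.phase), []
            ).append(slope)
        else:
            by_temp.setdefault(trace.target_temperature, {}).setdefault(
                trace.chamber_id, {}
            )[trace.phase] = slope

    rates: list[MetabolicRates] = []
    for temp in sorted(by_temp):
        for chamber_id in sorted(by_temp[temp]):
            phases = by_temp[temp][chamber_id]
            if "dark" not in phases or "light" not in phases:
                missing = {"dark", "light"} - set(phases)
                raise RespirometryError(
                    f"chamber {chamber_id} at {temp} degC is missing "
                    f"{sorted(missing)} phase trace(s)"
                )
            meta = metadata.get(chamber_id)
            if meta is None:
                raise RespirometryError(f"no metadata for chamber {chamber_id}")
            ctrl = {
                phase: float(np.mean(control_slopes.get((temp, phase), [0.0])))
                if control_correction
                else 0.0
                for phase in ("dark", "light")
            }
            rr = respiration_rate(
                phases["dark"], meta.volume, meta.dry_weight_g, ctrl["dark"]
            )
            npp = net_primary_production(
                phases["light"], meta.volume, meta.dry_weight_g, ctrl["light"]
            )
            rates.append(
                MetabolicRates(
                    replicate_id=chamber_id,
                    target_temperature=temp,
                    rr=rr,
                    npp=npp,
                )
            )
    return rates


def summarize_rates(rates: list[MetabolicRates]) -> pd.DataFrame:
    """Per-temperature mean and standard error of RR, NPP and GPP.

    Returns a frame with columns temp_C, rr_mean, rr_se, npp_mean, npp_se,
    gpp_mean, gpp_se, n. The SE is NaN where only one replicate exists.
    """
    if not rates:
        raise RespirometryError("no replicate rates to summarize")
    df = rates_to_frame(rates)
    rows = []
    for temp, grp in df.groupby("temp_C"):
        row: dict[str, float] = {"temp_C": temp, "n": len(grp)}
        for col in ("rr", "npp", "gpp"):
            vals = grp[col].to_numpy()
            row[f"{col}_mean"] = float(np.mean(vals))
            row[f"{col}_se"] = (
                float(np.std(vals, ddof=1) / np.sqrt(vals.size))
                if vals.size > 1
                else np.nan
            )
        rows.append(row)
    out = pd.DataFrame(rows)
    cols = ["temp_C", "rr_mean", "rr_se", "npp_mean", "npp_se", "gpp_mean", "gpp_se", "n"]
    return out[cols].sort_values("temp_C").reset_index(drop=True)


def rates_to_frame(rates: list[MetabolicRates]) -> pd.DataFrame:
    """Flatten per-replicate rates into a tidy frame."""
    return pd.DataFrame(
        {
            "replicate_id": [r.replicate_id for r in rates],
            "temp_C": [r.target_temperature for r in rates],
            "rr": [r.rr for r in rates],
            "npp": [r.npp for r in rates],
            "gpp": [r.gpp for r in rates],
        }
    )
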