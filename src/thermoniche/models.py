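"""Thermal performance curve (TPC) model family.

A TPC is a unimodal curve of a biological rate against temperature,
typically left-skewed for warm-adapted ectotherms: a Boltzmann-like
exponential rise governed by an activation energy, and a sharp collapse
above the optimum governed by a much larger deactivation energy.

The centrepiece is the enzyme-kinetics form with explicit optimum
temperature (here called the Pawar form):

    rate(T) = r_tref * exp(-(e/k) * (1/T - 1/T_ref))
              / (1 + (e/(eh - e)) * exp((eh/k) * (1/T_opt - 1/T)))

with all temperatures in kelvin (T(K) = T(degC) + 273.15), k the Boltzmann
constant in eV/K, e the activation energy (eV), eh > e the high-temperature
deactivation energy (eV), and r_tref the rate at the reference temperature
T_ref (fixed at 15 degC). The parameterization has the useful property that
the curve's maximizer is exactly the t_opt parameter.

Six further classical forms (full Sharpe-Schoolfield with low- and
high-temperature inactivation, Gaussian, quadratic, Briere-II, Ratkowsky
and Weibull) give the model-selection step genuinely different shapes to
discriminate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

#: Boltzmann constant, eV per kelvin.
BOLTZMANN_EV = 8.62e-5

#: Reference temperature for the enzyme-kinetics forms, degrees Celsius.
T_REF_C = 15.0

#: Offset from Celsius to kelvin.
KELVIN_OFFSET = 273.15


class TPCModelError(ValueError):
    """Raised for invalid TPC parameters or model definitions."""


@dataclass(frozen=True)
class TPCParameters:
    """Parameters of the Pawar-form enzyme-kinetics TPC.

    Attributes
    ----------
    r_tref : float
        Rate at the reference temperature (same units as the fitted rate).
    e : float
        Activation energy, eV; controls the rising limb.
    eh : float
        High-temperature deactivation energy, eV; must exceed ``e``.
    t_opt : float
        Optimum temperature, degrees Celsius; the curve's exact maximizer.
    t_ref : float
        Reference temperature, degrees Celsius (fixed by convention).
    """

    r_tref: float
    e: float
    eh: float
    t_opt: float
    t_ref: float = T_REF_C

    def __post_init__(self) -> None:
        if self.r_tref <= 0:
            raise TPCModelError("r_tref must be positive")
        if self.e <= 0:
            raise TPCModelError("activation energy e must be positive")
        if self.eh <= self.e:
            raise TPCModelError(
                f"deactivation energy eh ({self.eh}) must exceed activation "
                f"energy e ({self.e})"
            )

    def as_array(self) -> np.ndarray:
        return np.array([self.r_tref, self.e, self.eh, self.t_opt])


# Printed parameter sets of the study's fitted curves, used as canonical
# worked examples and as generator defaults for the synthetic experiments.
RR_PARAMS = TPCParameters(r_tref=0.12, e=0.6, eh=14.4, t_opt=35.7)
GPP_PARAMS = TPCParameters(r_tref=0.28, e=0.6, eh=12.3, t_opt=35.4)


def pawar_rate(temperature, params: TPCParameters):
    """Evaluate the Pawar-form TPC at temperature(s) in degrees Celsius.

    Vectorized over ``temperature``; returns strictly positive rates.
    """
    t = np.asarray(temperature, dtype=float)
    if np.any(t <= -KELVIN_OFFSET):
        raise TPCModelError("temperature at or below absolute zero")
    return _pawar(t, params.r_tref, params.e, params.eh, params.t_opt, params.t_ref)


def _pawar(t_c, r_tref, e, eh, t_opt, t_ref=T_REF_C):
    k = BOLTZMANN_EV
    T = np.asarray(t_c, dtype=float) + KELVIN_OFFSET
    Tref = t_ref + KELVIN_OFFSET
    Topt = t_opt + KELVIN_OFFSET
    boltzmann = np.exp(-(e / k) * (1.0 / T - 1.0 / Tref))
    inactivation = 1.0 + (e / (eh - e)) * np.exp((eh / k) * (1.0 / Topt - 1.0 / T))
    return r_tref * boltzmann / inactivation


def _sharpe_schoolfield_full(t_c, r_tref, e, el, t_l, eh, t_h):
    # Full Sharpe-Schoolfield with both low- and high-temperature enzyme
    # inactivation; t_l / t_h are the half-suppression temperatures (degC).
    # Nests the high-deactivation form (t_l -> -inf), which is itself a
    # reparameterization of the Pawar form, so on data generated from the
    # simpler curve this member matches the fit but loses on AIC.
    k = BOLTZMANN_EV
    T = np.asarray(t_c, dtype=float) + KELVIN_OFFSET
    Tref = T_REF_C + KELVIN_OFFSET
    Tl = t_l + KELVIN_OFFSET
    Th = t_h + KELVIN_OFFSET
    boltzmann = np.exp(-(e / k) * (1.0 / T - 1.0 / Tref))
    inactivation = (
        1.0
        + np.exp(-(el / k) * (1.0 / Tl - 1.0 / T))
        + np.exp((eh / k) * (1.0 / Th - 1.0 / T))
    )
    return r_tref * boltzmann / inactivation


def _gaussian(t_c, rmax, t_opt, sigma):
    t = np.asarray(t_c, dtype=float)
    return rmax * np.exp(-0.5 * ((t - t_opt) / sigma) ** 2)


def _quadratic(t_c, a, b, c):
    t = np.asarray(t_c, dtype=float)
    return a + b * t + c * t**2


def _briere2(t_c, a, t_min, t_max, b):
    t = np.asarray(t_c, dtype=float)
    inside = (t > t_min) & (t < t_max)
    out = np.zeros_like(t, dtype=float)
    ti = t[inside]
    out[inside] = a * ti * (ti - t_min) * np.abs(t_max - ti) ** (1.0 / b)
    return out


def _ratkowsky(t_c, a, b, t_min, t_max):
    t = np.asarray(t_c, dtype=float)
    inside = (t > t_min) & (t < t_max)
    out = np.zeros_like(t, dtype=float)
    ti = t[inside]
    out[inside] = (a * (ti - t_min)) ** 2 * (1.0 - np.exp(b * (ti - t_max))) ** 2
    return out


def _weibull(t_c, a, t_opt, b, c):
    # Re-parameterized Weibull whose maximum value a occurs at t_opt.
    t = np.asarray(t_c, dtype=float)
    cc = (c - 1.0) / c
    z = (t - t_opt) / b + cc ** (1.0 / c)
    z = np.maximum(z, 0.0)
    return a * cc ** (-cc) * z ** (c - 1.0) * np.exp(-(z**c) + cc)


@dataclass(frozen=True)
class ModelSpec:
    """One member of the TPC model family.

    ``fn(temperature, theta)`` evaluates the curve; ``start`` and ``bounds``
    derive a feasible multi-start box from the data at hand.
    """

    model_id: str
    param_names: tuple[str, ...]
    fn: Callable[[np.ndarray, np.ndarray], np.ndarray]
    bounds: Callable[[np.ndarray, np.ndarray], tuple[np.ndarray, np.ndarray]]

    @property
    def n_params(self) -> int:
        return len(self.param_names)

    def __call__(self, temperature, theta) -> np.ndarray:
        return self.fn(np.asarray(temperature, dtype=float), np.asarray(theta))


def _data_scales(temp: np.ndarray, rate: np.ndarray):
    rmax = max(float(np.max(rate)), 1e-8)
    tmin, tmax = float(np.min(temp)), float(np.max(temp))
    tpk = float(temp[int(np.argmax(rate))])
    return rmax, tmin, tmax, tpk


def _pawar_bounds(temp, rate):
    rmax, tmin, tmax, _ = _data_scales(temp, rate)
    lo = np.array([1e-6, 0.05, 0.5, tmin - 5.0])
    hi = np.array([10.0 * rmax, 4.0, 40.0, tmax + 10.0])
    return lo, hi


def _ssf_bounds(temp, rate):
    rmax, tmin, tmax, _ = _data_scales(temp, rate)
    lo = np.array([1e-6, 0.05, 0.1, tmin - 30.0, 0.5, tmin])
    hi = np.array([10.0 * rmax, 4.0, 10.0, tmin + 10.0, 40.0, tmax + 15.0])
    return lo, hi


def _gaussian_bounds(temp, rate):
    rmax, tmin, tmax, _ = _data_scales(temp, rate)
    lo = np.array([1e-6, tmin - 10.0, 0.5])
    hi = np.array([5.0 * rmax, tmax + 10.0, 3.0 * (tmax - tmin)])
    return lo, hi


def _quadratic_bounds(temp, rate):
    rmax, _, _, _ = _data_scales(temp, rate)
    big = 10.0 * rmax
    lo = np.array([-big, -big, -big])
    hi = np.array([big, big, big])
    return lo, hi


def _briere2_bounds(temp, rate):
    rmax, tmin, tmax, _ = _data_scales(temp, rate)
    lo = np.array([1e-9, tmin - 30.0, tmax - 2.0, 0.5])
    hi = np.array([rmax, tmin + 2.0, tmax + 20.0, 10.0])
    return lo, hi


def _ratkowsky_bounds(temp, rate):
    rmax, tmin, tmax, _ = _data_scales(temp, rate)
    lo = np.array([1e-6, 0.01, tmin - 30.0, tmax - 2.0])
    hi = np.array([np.sqrt(rmax), 2.0, tmin + 2.0, tmax + 20.0])
    return lo, hi


def _weibull_bounds(temp, rate):
    rmax, tmin, tmax, _ = _data_scales(temp, rate)
    lo = np.array([1e-6, tmin - 5.0, 1.0, 1.2])
    hi = np.array([5.0 * rmax, tmax + 10.0, 5.0 * (tmax - tmin), 12.0])
    return lo, hi


_FAMILY: tuple[ModelSpec, ...] = (
    ModelSpec(
        "pawar",
        ("r_tref", "e", "eh", "t_opt"),
        lambda t, th: _pawar(t, *th),
        _pawar_bounds,
    ),
    ModelSpec(
        "sharpeschoolfield",
        ("r_tref", "e", "el", "t_l", "eh", "t_h"),
        lambda t, th: _sharpe_schoolfield_full(t, *th),
        _ssf_bounds,
    ),
    ModelSpec(
        "gaussian",
        ("rmax", "t_opt", "sigma"),
        lambda t, th: _gaussian(t, *th),
        _gaussian_bounds,
    ),
    ModelSpec(
        "quadratic",
        ("a", "b", "c"),
        lambda t, th: _quadratic(t, *th),
        _quadratic_bounds,
    ),
    ModelSpec(
        "briere2",
        ("a", "t_min", "t_max", "b"),
        lambda t, th: _briere2(t, *th),
        _briere2_bounds,
    ),
    ModelSpec(
        "ratkowsky",
        ("a", "b", "t_min", "t_max"),
        lambda t, th: _ratkowsky(t, *th),
        _ratkowsky_bounds,
    ),
    ModelSpec(
        "weibull",
        ("a", "t_opt", "b", "c"),
        lambda t, th: _weibull(t, *th),
        _weibull_bounds,
    ),
)


def model_family(subset: list[str] | None = None) -> list[ModelSpec]:
    """Return the TPC model family, optionally restricted to named members."""
    if subset is None:
        return list(_FAMILY)
    by_id = {m.model_id: m for m in _FAMILY}
    unknown = [name for name in subset if name not in by_id]
    if unknown:
        raise TPCModelError(
            f"unknown model(s) {unknown}; available: {sorted(by_id)}"
        )
    return [by_id[name] for name in subset]


def pawar_params_from_theta(theta: np.ndarray) -> TPCParameters:
    """Interpret a fitted Pawar parameter vector as :class:`TPCParameters`."""
    r_tref, e, eh, t_opt = (float(v) for v in theta)
    return TPCParameters(r_tref=r_tref, e=e, eh=eh, t_opt=t_opt)
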