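"""Curve models for postprandial kinetics and filament-thinning rheology.

Two parametric curve families describe the study measures:

* the **LinExp** gastric-volume curve

  .. math:: V(t) = V_0 \\, (1 + k t / T) \\, e^{-t/T}

  with initial postprandial volume ``V0`` (mL), shape ``k`` (dimensionless;
  ``k > 1`` produces an initial volume rise, ``k = 0`` a pure exponential
  decay) and emptying time constant ``T`` (min);

* the **power-exponential** delta-over-baseline (DOB) response curve

  .. math:: C(t) = AOB \\, k \\beta \\, (1 - e^{-kt})^{\\beta-1} e^{-kt}

  whose scale parameter ``AOB`` is the exact area over baseline
  (:math:`\\int_0^\\infty C\\,dt = AOB`), with rate ``k`` (1/min) and shape
  ``beta >= 1``.  The curve peaks (or troughs, for negative ``AOB``) at
  ``t_max = ln(beta)/k`` with amplitude ``A_max = C(t_max)``.

The module also carries the capillary-breakup extensional rheometry (CaBER)
post-processing used to fingerprint meal consistency: the Hencky strain of a
thinning filament and the apparent extensional viscosity derived from the
mid-filament force balance.

All curve functions accept scalar or array time arguments with identical
semantics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

__all__ = [
    "LinExpParams",
    "PowerExpParams",
    "FilamentTrace",
    "ExtensionalViscosityResult",
    "linexp_volume",
    "linexp_peak_time",
    "powerexp_curve",
    "powerexp_derived",
    "hencky_strain",
    "apparent_extensional_viscosity",
]


@dataclass(frozen=True)
class LinExpParams:
    """Parameters of the LinExp gastric-volume curve.

    Attributes
    ----------
    v0 : float
        Initial postprandial volume (mL), > 0.  The curve value at t = 0.
    k : float
        Shape parameter (dimensionless), >= 0.  Controls the initial volume
        increase (k > 1) or the delay in volume decrease.
    t_const : float
        Emptying time constant T (min), > 0.
    """

    v0: float
    k: float
    t_const: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.v0) and self.v0 > 0):
            raise ValueError(f"V0 must be finite and > 0, got {self.v0}")
        if not (np.isfinite(self.k) and self.k >= 0):
            raise ValueError(f"k must be finite and >= 0, got {self.k}")
        if not (np.isfinite(self.t_const) and self.t_const > 0):
            raise ValueError(f"T must be finite and > 0, got {self.t_const}")


@dataclass(frozen=True)
class PowerExpParams:
    """Parameters of the power-exponential DOB response curve.

    Attributes
    ----------
    aob : float
        Area over baseline (measure units x min).  May be negative for
        responses that fall below baseline (gallbladder volume, glucose).
    k : float
        Rate constant (1/min), > 0.
    beta : float
        Shape parameter (dimensionless), >= 1.  beta = 1 gives a pure
        exponential decay starting at AOB * k; beta > 1 starts at zero.
    """

    aob: float
    k: float
    beta: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.aob):
            raise ValueError(f"AOB must be finite, got {self.aob}")
        if not (np.isfinite(self.k) and self.k > 0):
            raise ValueError(f"k must be finite and > 0, got {self.k}")
        if not (np.isfinite(self.beta) and self.beta >= 1):
            raise ValueError(f"beta must be finite and >= 1, got {self.beta}")


@dataclass(frozen=True)
class FilamentTrace:
    """A CaBER mid-filament diameter trace.

    Attributes
    ----------
    times : array
        Sample times (s), strictly increasing.
    d_mid : array
        Mid-filament diameter at each time, > 0 and <= d0.
    d0 : float
        Initial diameter of the fluid thread before stretching, > 0.
    surface_tension : float
        Surface tension coefficient, > 0.

    Diameters and surface tension must use consistent units: metres with
    N/m (and seconds) yield apparent viscosities in Pa s.
    """

    times: np.ndarray
    d_mid: np.ndarray
    d0: float
    surface_tension: float = 0.03

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        d = np.asarray(self.d_mid, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "d_mid", d)
        if t.ndim != 1 or d.shape != t.shape:
            raise ValueError("times and d_mid must be 1-d arrays of equal length")
        if t.size and np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(~np.isfinite(d)) or np.any(d <= 0):
            raise ValueError("all mid-filament diameters must be finite and > 0")
        if not (np.isfinite(self.d0) and self.d0 > 0):
            raise ValueError(f"D0 must be finite and > 0, got {self.d0}")
        # small tolerance for measurement jitter right at stretch onset
        if np.any(d > self.d0 * (1 + 1e-9)):
            raise ValueError("d_mid must not exceed the initial diameter D0")
        if not (np.isfinite(self.surface_tension) and self.surface_tension > 0):
            raise ValueError("surface tension must be finite and > 0")


def _check_times(t):
    t = np.asarray(t, dtype=float)
    if np.any(~np.isfinite(t)) or np.any(t < 0):
        raise ValueError("time points must be finite and >= 0")
    return t


def linexp_volume(params: LinExpParams, t):
    """Evaluate the LinExp volume curve V0 (1 + k t/T) exp(-t/T).

    Parameters
    ----------
    params : LinExpParams
    t : scalar or array of times (min), >= 0

    Returns
    -------
    Volume in mL, same shape as ``t``; nonnegative for all t >= 0.
    """
    t = _check_times(t)
    x = t / params.t_const
    return params.v0 * (1.0 + params.k * x) * np.exp(-x)


def linexp_peak_time(params: LinExpParams) -> float:
    """Time of the interior maximum, T (k - 1)/k for k > 1, else 0.

    For k <= 1 the curve is nonincreasing on t >= 0 and the maximum sits at
    the origin.
    """
    if params.k > 1:
        return params.t_const * (params.k - 1.0) / params.k
    return 0.0


def powerexp_curve(params: PowerExpParams, t):
    """Evaluate the power-exponential DOB curve.

    C(t) = AOB k beta (1 - exp(-k t))^(beta-1) exp(-k t).

    For beta = 1 this is AOB k exp(-k t) (so C(0) = AOB k); for beta > 1 the
    curve starts at 0, rises to A_max at t_max = ln(beta)/k and decays back
    to baseline.  Linear in AOB, so negative-amplitude responses are the
    pointwise negation of their positive counterparts.
    """
    t = _check_times(t)
    u = np.exp(-params.k * t)
    # 0**0 == 1.0 in numpy: the beta == 1, t == 0 corner works out naturally
    rise = np.power(1.0 - u, params.beta - 1.0)
    return params.aob * params.k * params.beta * rise * u


def powerexp_derived(params: PowerExpParams) -> tuple[float, float]:
    """Derived response summaries (t_max, A_max).

    t_max = ln(beta)/k is the time of the curve extremum; A_max is the curve
    value there (same sign as AOB).  For beta = 1, t_max = 0 and
    A_max = AOB k.
    """
    t_max = float(np.log(params.beta) / params.k)
    a_max = float(powerexp_curve(params, t_max))
    return t_max, a_max


def hencky_strain(trace: FilamentTrace) -> np.ndarray:
    """System Hencky strain of the thinning filament.

    epsilon(t) = 2 ln(D0 / D_mid(t)); zero where the filament still has its
    initial diameter and monotonically nondecreasing while it thins.
    """
    return 2.0 * np.log(trace.d0 / trace.d_mid)


class ExtensionalViscosityResult(NamedTuple):
    """Apparent extensional viscosity against Hencky strain.

    ``n_dropped`` counts instants with a locally nondecreasing diameter
    (zero or negative thinning rate) that were excluded.
    """

    strain: np.ndarray
    viscosity: np.ndarray
    n_dropped: int


def apparent_extensional_viscosity(
    trace: FilamentTrace, smooth_window: int = 1
) -> ExtensionalViscosityResult:
    """Apparent transient extensional viscosity from a diameter trace.

    Uses the mid-filament force balance eta_app = sigma / (-dD_mid/dt) with
    centered finite differences on the raw trace (no smoothing by default;
    ``smooth_window`` > 1 applies a moving average to D_mid first).  Points
    where the filament is not thinning are dropped and counted.  Output is
    sorted by Hencky strain.
    """
    if trace.times.size < 3:
        raise ValueError(
            "at least 3 time points are required for centered differences"
        )
    d = trace.d_mid
    if smooth_window > 1:
        kernel = np.ones(smooth_window) / smooth_window
        d = np.convolve(d, kernel, mode="same")
    ddt = np.gradient(d, trace.times)
    thinning = ddt < 0
    n_dropped = int(np.sum(~thinning))
    if n_dropped:
        warnings.warn(
            f"dropped {n_dropped} non-thinning point(s) from viscosity estimate",
            stacklevel=2,
        )
    strain = 2.0 * np.log(trace.d0 / d[thinning])
    visc = trace.surface_tension / (-ddt[thinning])
    order = np.argsort(strain)
    return ExtensionalViscosityResult(strain[order], visc[order], n_dropped)
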