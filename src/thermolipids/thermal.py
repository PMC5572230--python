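"""Steady-state downcore temperature modelling.

Hydrothermally influenced sediments carry heat both by conduction and by
upward pore-fluid advection.  At steady state the 1D temperature field
T(z), with depth z positive downward from the sediment surface, satisfies

    kappa * T''(z) + w * T'(z) = 0,        T(0) = T_top,  T(L) = T_bottom,

where ``kappa`` is the thermal diffusivity (m^2/s) and ``w >= 0`` the
upward fluid velocity (supplied in m/h, converted internally).  The closed
form is

    T(z) = T_top + (T_bottom - T_top) * (1 - exp(-Pe z / L)) / (1 - exp(-Pe))

with Peclet number ``Pe = w L / kappa``: the larger Pe, the steeper the
near-surface gradient and the flatter the profile at depth — the shape
observed over diffuse hydrothermal vents.  ``Pe -> 0`` recovers the linear
conductive profile.

The module provides the closed form, an independent finite-difference
solver used as a numerical cross-check, least-squares / single-point
fitting of the flow parameters from sparse probe data, and midpoint
temperature lookup for 2-cm sampling horizons.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.linalg import solve_banded

__all__ = [
    "ThermalModelParams",
    "TemperatureProfile",
    "FitReport",
    "steady_profile_closed_form",
    "steady_profile_numeric",
    "fit_profile",
    "temperature_at",
    "DEFAULT_KAPPA",
    "DEFAULT_W",
]

#: thermal diffusivity of sandy sediments, m^2 s^-1
DEFAULT_KAPPA = 3e-7
#: reference upward pore-fluid velocity, m h^-1
DEFAULT_W = 0.021

_SECONDS_PER_HOUR = 3600.0
_MAX_PECLET = 700.0  # exp underflows/overflows past this


@dataclass(frozen=True)
class ThermalModelParams:
    """Parameters of the steady advection-diffusion temperature model."""

    kappa: float = DEFAULT_KAPPA  # m^2 s^-1
    w: float = DEFAULT_W          # m h^-1, upward positive
    t_top: float = 18.0           # deg C, bottom-water temperature
    t_bottom: float = 101.0       # deg C at depth L
    length: float = 0.2           # m
    dz: float = 1e-4              # m, output grid resolution

    def __post_init__(self):
        if self.kappa <= 0:
            raise ValueError("kappa must be > 0")
        if self.length <= 0 or self.dz <= 0:
            raise ValueError("length and dz must be > 0")
        if self.w < 0:
            raise ValueError(
                "w < 0 (downward flow) is outside the model's domain; "
                "upward hydrothermal discharge only"
            )

    @property
    def w_m_s(self) -> float:
        return self.w / _SECONDS_PER_HOUR

    @property
    def peclet(self) -> float:
        """Pe = w L / kappa, with w in m/s."""
        return self.w_m_s * self.length / self.kappa


@dataclass(frozen=True)
class TemperatureProfile:
    """Depth-temperature grid for one station (depth in m, T in deg C)."""

    station: str
    depth_m: np.ndarray
    temperature_c: np.ndarray
    params: ThermalModelParams | None = None

    def __post_init__(self):
        d = np.asarray(self.depth_m, float)
        if d.ndim != 1 or len(d) < 2 or np.any(np.diff(d) <= 0):
            raise ValueError("depth grid must be 1D and strictly increasing")
        if len(d) != len(self.temperature_c):
            raise ValueError("depth and temperature grids differ in length")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "station": self.station,
                "depth_m": self.depth_m,
                "temperature_C": self.temperature_c,
            }
        )


def _grid(params: ThermalModelParams) -> np.ndarray:
    n = int(round(params.length / params.dz))
    return np.linspace(0.0, params.length, n + 1)


def _shape(pe: float, zeta: np.ndarray) -> np.ndarray:
    """(1 - exp(-Pe zeta)) / (1 - exp(-Pe)) with the Pe -> 0 linear limit."""
    if pe > _MAX_PECLET:
        raise ValueError(
            f"Peclet number {pe:.3g} exceeds {_MAX_PECLET:g}; rescale the problem "
            "(shorter domain or smaller velocity)"
        )
    if pe < 1e-12:
        return zeta
    return np.expm1(-pe * zeta) / np.expm1(-pe)


def steady_profile_closed_form(
    params: ThermalModelParams, station: str = ""
) -> TemperatureProfile:
    """Analytical steady profile on the regular output grid.

    Boundary temperatures are met exactly; for ``w = 0`` the profile is the
    straight line between them.
    """
    z = _grid(params)
    shape = _shape(params.peclet, z / params.length)
    temps = params.t_top + (params.t_bottom - params.t_top) * shape
    return TemperatureProfile(station, z, temps, params)


def steady_profile_numeric(
    params: ThermalModelParams, station: str = "", richardson: bool = True
) -> TemperatureProfile:
    """Finite-difference solution of kappa T'' + w T' = 0, Dirichlet ends.

    Second-order central differences; if the cell Peclet number w dz /
    kappa reaches 2 the advection term is upwinded to keep the scheme
    monotone.  With ``richardson`` (default) the solve is repeated at
    half the step and Richardson-extrapolated, cancelling the leading
    O(dz^2) error term.  Serves as an independent numerical cross-check
    of the closed form.
    """
    if richardson:
        coarse = steady_profile_numeric(params, station, richardson=False)
        fine = steady_profile_numeric(
            replace(params, dz=params.dz / 2), station, richardson=False
        )
        temps = (4.0 * fine.temperature_c[::2] - coarse.temperature_c) / 3.0
        return TemperatureProfile(station, coarse.depth_m, temps, params)
    z = _grid(params)
    n = len(z)
    dz = z[1] - z[0]
    w = params.w_m_s
    cell_pe = w * dz / params.kappa
    a = params.kappa / dz**2
    if cell_pe < 2.0:
        lower = a - w / (2 * dz)   # T_{i-1} coefficient
        diag = -2.0 * a
        upper = a + w / (2 * dz)   # T_{i+1} coefficient
    else:
        # first-order upwind for the advective term (flow is upward, -z)
        lower = a
        diag = -2.0 * a - w / dz
        upper = a + w / dz
    m = n - 2
    ab = np.zeros((3, m))
    ab[0, 1:] = upper
    ab[1, :] = diag
    ab[2, :-1] = lower
    rhs = np.zeros(m)
    rhs[0] -= lower * params.t_top
    rhs[-1] -= upper * params.t_bottom
    interior = solve_banded((1, 1), ab, rhs)
    temps = np.empty(n)
    temps[0], temps[-1] = params.t_top, params.t_bottom
    temps[1:-1] = interior
    return TemperatureProfile(station, z, temps, params)


@dataclass(frozen=True)
class FitReport:
    """Outcome of fitting flow parameters to probe measurements."""

    params: ThermalModelParams
    residuals_c: np.ndarray
    converged: bool
    method: str
    message: str = ""


def _model_temps(z, w, t_bottom, kappa, t_top, length):
    pe = (w / _SECONDS_PER_HOUR) * length / kappa
    return t_top + (t_bottom - t_top) * _shape(pe, np.asarray(z, float) / length)


def fit_profile(
    measurements,
    kappa: float = DEFAULT_KAPPA,
    t_top: float = 18.0,
    length: float = 0.2,
    t_bottom: float | None = None,
    dz: float = 1e-4,
    w_max: float = 1.0,
) -> FitReport:
    """Fit (w, T_bottom) of the steady model to sparse probe readings.

    measurements
        Sequence of ``(depth_m, temperature_C)`` pairs; depths must lie in
        ``[0, length]``.
    t_bottom
        If given, only the velocity ``w`` is fitted.  With exactly one
        interior measurement this is required, and ``w`` is recovered by
        bracketed root finding on the monotone map ``w -> T(z0)``.

    Returns a :class:`FitReport`; degenerate data (no downcore gradient)
    raise with a diagnostic.
    """
    meas = [(float(z), float(t)) for z, t in measurements]
    if not meas:
        raise ValueError("at least one interior measurement is required")
    for z, _ in meas:
        if not 0.0 <= z <= length:
            raise ValueError(f"measurement depth {z} m outside [0, {length}] m")
    z_arr = np.array([z for z, _ in meas])
    t_arr = np.array([t for _, t in meas])

    interior = z_arr > 0
    if np.allclose(t_arr[interior], t_top, atol=1e-9) and (
        t_bottom is None or math.isclose(t_bottom, t_top, abs_tol=1e-9)
    ):
        raise ValueError(
            "zero downcore temperature gradient: flow velocity is unidentifiable"
        )

    n_interior = int(np.sum((z_arr > 0) & (z_arr < length)))
    if t_bottom is not None:
        if n_interior == 1 and len(meas) == 1:
            z0, t0 = meas[0]
            lo = _model_temps(z0, 0.0, t_bottom, kappa, t_top, length)
            hi = _model_temps(z0, w_max, t_bottom, kappa, t_top, length)
            if not min(lo, hi) - 1e-9 <= t0 <= max(lo, hi) + 1e-9:
                raise ValueError(
                    f"target temperature {t0} deg C at {z0} m is outside the "
                    f"attainable range [{min(lo, hi):.3f}, {max(lo, hi):.3f}] "
                    f"for w in [0, {w_max}] m/h"
                )
            w_hat = optimize.brentq(
                lambda w: _model_temps(z0, w, t_bottom, kappa, t_top, length) - t0,
                0.0, w_max, xtol=1e-12,
            )
            params = ThermalModelParams(kappa, w_hat, t_top, t_bottom, length, dz)
            resid = t_arr - _model_temps(z_arr, w_hat, t_bottom, kappa, t_top, length)
            return FitReport(params, resid, True, "bisection",
                             "single-point inversion of the monotone w -> T map")
        res = optimize.least_squares(
            lambda p: _model_temps(z_arr, p[0], t_bottom, kappa, t_top, length) - t_arr,
            x0=[DEFAULT_W], bounds=([0.0], [w_max]),
        )
        w_hat, tb_hat = float(res.x[0]), t_bottom
    else:
        if n_interior < 1 or len(meas) < 2:
            raise ValueError(
                "fitting both w and T_bottom needs >= 2 measurements; "
                "supply t_bottom to fit w alone"
            )
        tb0 = float(t_arr[np.argmax(z_arr)])
        res = optimize.least_squares(
            lambda p: _model_temps(z_arr, p[0], p[1], kappa, t_top, length) - t_arr,
            x0=[DEFAULT_W, tb0], bounds=([0.0, -np.inf], [w_max, np.inf]),
        )
        w_hat, tb_hat = float(res.x[0]), float(res.x[1])
    if not res.success:
        raise RuntimeError(f"profile fit did not converge: {res.message}")
    params = ThermalModelParams(kappa, w_hat, t_top, tb_hat, length, dz)
    resid = t_arr - _model_temps(z_arr, w_hat, tb_hat, kappa, t_top, length)
    return FitReport(params, resid, bool(res.success), "least_squares", res.message)


def temperature_at(
    profile: TemperatureProfile, depth_top_cm: float, depth_bottom_cm: float
) -> float:
    """Temperature at the midpoint of a sampling horizon given in cm."""
    if depth_bottom_cm < depth_top_cm:
        raise ValueError("horizon bottom above its top")
    mid_m = 0.5 * (depth_top_cm + depth_bottom_cm) / 100.0
    zmin, zmax = profile.depth_m[0], profile.depth_m[-1]
    if not zmin <= mid_m <= zmax:
        raise ValueError(
            f"horizon midpoint {mid_m} m outside profile range [{zmin}, {zmax}] m"
        )
    return float(np.interp(mid_m, profile.depth_m, profile.temperature_c))
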