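"""Swollen-fraction kinetics and the delayed subpopulation volume equation.

The swollen-or-swelling fraction obeys the autonomous ODE

    X'(t) = (a * X**r + b) * (X_p - X),   X(0) = 0,

which for ``r = 1`` has the closed-form solution (separation of variables,
partial fractions)

    X(t) = X_p * b * (exp(s*t) - 1) / (a*X_p + b*exp(s*t)),  s = a*X_p + b,

evaluated here in the overflow-safe form
``X_p * b * (1 - exp(-s*t)) / (a*X_p*exp(-s*t) + b)``.

The mean population volume splits into three subpopulations: unswollen
(volume ``V0``), actively swelling (mean volume ``k*V_p``, entered at rate
X' and left ``tau`` minutes later), and fully swollen (``V_p``):

    V(t) = V0*(1 - X(t)) + k*V_p*(X(t) - X(t - tau)) + V_p*X(t - tau),

with the history convention X(s) = 0 for s < 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from numpy.typing import ArrayLike, NDArray
from scipy.integrate import solve_ivp

from .parameters import DEFAULT_CONSTANTS, PopulationConstants, SwellingParameters

__all__ = [
    "FractionSeries",
    "VolumeSeries",
    "ClosedFormUnavailableError",
    "swelling_rate",
    "swelling_fraction",
    "integrate_fraction",
    "fraction_function",
    "subpopulation_split",
    "total_volume",
    "derivative_break",
    "log_volume_transform",
    "default_grid",
]


class ClosedFormUnavailableError(ValueError):
    """The explicit solution exists only for kinetic order r = 1."""


@dataclass(frozen=True)
class FractionSeries:
    """Swollen-or-swelling fraction X(t) on a time grid (minutes)."""

    times: NDArray[np.float64]
    values: NDArray[np.float64]


@dataclass(frozen=True)
class VolumeSeries:
    """Mean population volume V(t) with its subpopulation components.

    ``components`` is a (3, n) array of the unswollen, actively swelling
    and fully swollen volume contributions; they sum to ``values``.
    """

    times: NDArray[np.float64]
    values: NDArray[np.float64]
    components: NDArray[np.float64]


def default_grid(duration: float = 60.0, dt: float = 0.25) -> NDArray[np.float64]:
    """Default evaluation grid: 0..duration min in dt steps."""
    n = int(round(duration / dt))
    return np.linspace(0.0, n * dt, n + 1)


def swelling_rate(
    x: ArrayLike,
    params: SwellingParameters,
    consts: PopulationConstants = DEFAULT_CONSTANTS,
) -> NDArray[np.float64] | float:
    """Right-hand side (a*x**r + b)*(X_p - x) of the fraction ODE, 1/min."""
    x = np.asarray(x, dtype=float)
    if np.any(x < 0) or np.any(x > consts.X_p):
        raise ValueError(f"fraction x must lie in [0, X_p={consts.X_p}]")
    rate = (params.a * x**params.r + params.b) * (consts.X_p - x)
    return float(rate) if rate.ndim == 0 else rate


def swelling_fraction(
    t: ArrayLike,
    params: SwellingParameters,
    consts: PopulationConstants = DEFAULT_CONSTANTS,
) -> NDArray[np.float64] | float:
    """Closed-form X(t) for kinetic order r = 1.

    Times before 0 return 0 (delay history convention).  Monotone
    non-decreasing, X(0) = 0, sup X = X_p approached exponentially.
    """
    if params.r != 1.0:
        raise ClosedFormUnavailableError(
            f"closed form requires r = 1 (got r={params.r}); use integrate_fraction"
        )
    t = np.asarray(t, dtype=float)
    a, b, xp = params.a, params.b, consts.X_p
    if b == 0.0:  # X = 0 is a fixed point: swelling never starts
        z = np.zeros_like(t)
        return float(z) if z.ndim == 0 else z
    s = a * xp + b
    tt = np.maximum(t, 0.0)
    e = np.exp(-s * tt)
    x = xp * b * (1.0 - e) / (a * xp * e + b)
    x = np.where(t < 0, 0.0, x)
    return float(x) if x.ndim == 0 else x


def integrate_fraction(
    params: SwellingParameters,
    consts: PopulationConstants = DEFAULT_CONSTANTS,
    grid: ArrayLike | None = None,
    rtol: float = 1e-10,
    atol: float = 1e-12,
) -> FractionSeries:
    """Numerically integrate X' = (a*X**r + b)*(X_p - X) on a grid from 0.

    Uses an adaptive high-order Runge-Kutta method (DOP853); the default
    tolerances make this a trustworthy oracle for the closed form.
    """
    grid = default_grid() if grid is None else np.asarray(grid, dtype=float)
    if grid.ndim != 1 or grid.size < 2 or np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be strictly increasing with at least 2 points")
    if grid[0] != 0.0:
        raise ValueError("grid must start at t = 0 (initial condition X(0) = 0)")
    a, b, r, xp = params.a, params.b, params.r, consts.X_p

    def rhs(_t: float, x: NDArray) -> NDArray:
        xc = np.clip(x, 0.0, xp)
        return (a * xc**r + b) * (xp - xc)

    sol = solve_ivp(
        rhs, (grid[0], grid[-1]), [0.0], t_eval=grid,
        method="DOP853", rtol=rtol, atol=atol,
    )
    if not sol.success:  # pragma: no cover - non-stiff bounded RHS
        raise RuntimeError(f"integration failed: {sol.message}")
    return FractionSeries(times=grid, values=np.clip(sol.y[0], 0.0, xp))


def fraction_function(
    params: SwellingParameters,
    consts: PopulationConstants = DEFAULT_CONSTANTS,
    t_max: float | None = None,
    rtol: float = 1e-10,
    atol: float = 1e-12,
) -> Callable[[ArrayLike], NDArray[np.float64]]:
    """Return a vectorized callable t -> X(t) honouring the history convention.

    Dispatches to the closed form for r = 1, otherwise to a dense-output
    numeric solution valid on [0, t_max].
    """
    if params.r == 1.0:
        return lambda t: np.asarray(swelling_fraction(t, params, consts), dtype=float)
    if t_max is None:
        raise ValueError("t_max is required for the numeric solution (r != 1)")
    a, b, r, xp = params.a, params.b, params.r, consts.X_p

    def rhs(_t: float, x: NDArray) -> NDArray:
        xc = np.clip(x, 0.0, xp)
        return (a * xc**r + b) * (xp - xc)

    sol = solve_ivp(
        rhs, (0.0, float(t_max)), [0.0],
        method="DOP853", rtol=rtol, atol=atol, dense_output=True,
    )
    if not sol.success:  # pragma: no cover
        raise RuntimeError(f"integration failed: {sol.message}")

    def x_of_t(t: ArrayLike) -> NDArray[np.float64]:
        t = np.asarray(t, dtype=float)
        tt = np.clip(t, 0.0, float(t_max))
        vals = np.clip(sol.sol(np.atleast_1d(tt))[0], 0.0, xp)
        vals = vals.reshape(tt.shape) if tt.ndim else vals[0]
        return np.where(t < 0, 0.0, vals)

    return x_of_t


def subpopulation_split(
    t: ArrayLike,
    params: SwellingParameters,
    consts: PopulationConstants = DEFAULT_CONSTANTS,
    x_of_t: Callable[[ArrayLike], NDArray] | None = None,
) -> tuple[NDArray, NDArray, NDArray]:
    """Fractions (unswollen, actively swelling, fully swollen) at time t.

    Returns ``(1 - X(t), X(t) - X(t - tau), X(t - tau))``; the three always
    sum to 1 and each lies in [0, 1].
    """
    t = np.asarray(t, dtype=float)
    if x_of_t is None:
        x_of_t = fraction_function(params, consts, t_max=float(np.max(t, initial=0.0)))
    x_now = np.asarray(x_of_t(t), dtype=float)
    x_done = np.asarray(x_of_t(t - params.tau), dtype=float)
    return 1.0 - x_now, x_now - x_done, x_done


def total_volume(
    t: ArrayLike,
    params: SwellingParameters,
    consts: PopulationConstants = DEFAULT_CONSTANTS,
    x_of_t: Callable[[ArrayLike], NDArray] | None = None,
) -> VolumeSeries:
    """Mean population volume V(t), ml/mg protein, with its three components.

    V(0) = V0 and V(t) -> V0*(1 - X_p) + V_p*X_p for large t.  When
    ``k * V_p < V0`` the curve dips below V0 (transient shrinking) before
    rising to the limit.
    """
    t = np.atleast_1d(np.asarray(t, dtype=float))
    unswollen, swelling, swollen = subpopulation_split(t, params, consts, x_of_t)
    v1 = consts.V0 * unswollen
    v2 = params.k * consts.V_p * swelling
    v3 = consts.V_p * swollen
    components = np.stack([v1, v2, v3])
    return VolumeSeries(times=t, values=components.sum(axis=0), components=components)


def derivative_break(
    params: SwellingParameters,
    consts: PopulationConstants = DEFAULT_CONSTANTS,
) -> float:
    """Jump of V'(t) at t = tau: b * X_p * V_p * (1 - k).

    The delayed term switches on at t = tau with slope X'(0+) = b * X_p,
    replacing volume k*V_p by V_p for the mitochondria finishing swelling;
    the break vanishes as b -> 0 or k -> 1.
    """
    return params.b * consts.X_p * consts.V_p * (1.0 - params.k)


def log_volume_transform(
    series: VolumeSeries,
    consts: PopulationConstants = DEFAULT_CONSTANTS,
) -> tuple[NDArray[np.float64], NDArray[np.bool_]]:
    """Logarithmic-volume diagnostic L(t) = ln((V_inf - V(t)) / (V_inf - V0)).

    ``V_inf`` is the model's true large-time volume limit, so L(0) = 0 and
    L is non-increasing.  Under first-order kinetics without delay (a = 0,
    tau = 0) L(t) = ln(1 - X(t)/X_p) = -b*t exactly; for the full model L
    is linear only once most of the swelling is done.

    Returns ``(L, valid)``; saturated grid points where the logarithm's
    argument is non-positive are flagged invalid (NaN in L).
    """
    v_inf = consts.V_inf
    denom = v_inf - consts.V0
    if denom <= 0:  # pragma: no cover - excluded by constant invariants
        raise ValueError("degenerate constants: V_inf must exceed V0")
    arg = (v_inf - series.values) / denom
    valid = arg > 0
    out = np.full_like(series.values, np.nan)
    out[valid] = np.log(arg[valid])
    return out, valid
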