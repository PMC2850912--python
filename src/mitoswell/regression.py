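"""Meta-regressions of fitted swelling parameters against Ca2+ concentration.

Across a calcium titration the per-curve kinetic parameters follow simple
laws: the feedback rate a grows linearly with [Ca2+], the single-
mitochondrion swelling time tau decays exponentially, and the swelling-
volume factor k rises along a slow offset exponential.  The goodness
criterion throughout is the relative squared error

    sum_i ((pred_i - obs_i) / obs_i)**2,

a scale-free statistic suited to parameters spanning different magnitudes.
The exponential laws are fitted by minimising this criterion directly
(Nelder-Mead, multi-started from the log-linear least-squares solution);
plain OLS is used for the linear law.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from numpy.typing import ArrayLike, NDArray
from scipy.optimize import minimize
from sklearn.base import BaseEstimator, RegressorMixin

from .parameters import DEFAULT_B

__all__ = [
    "RegressionFit",
    "relative_squared_error",
    "CalciumLinearRegression",
    "CalciumExponentialDecay",
    "CalciumOffsetExponential",
    "fit_linear",
    "fit_exponential_decay",
    "fit_offset_exponential",
    "load_reference_table",
    "run_meta_regressions",
]


@dataclass(frozen=True)
class RegressionFit:
    """A fitted parameter-vs-calcium law."""

    form: str
    coefficients: dict[str, float]
    rel_sq_error: float
    ill_posed: bool = False
    notes: str = ""

    def to_dict(self) -> dict:
        return {
            "form": self.form,
            "coefficients": dict(self.coefficients),
            "rel_sq_error": self.rel_sq_error,
            "ill_posed": self.ill_posed,
            "notes": self.notes,
        }


def relative_squared_error(observed: ArrayLike, predicted: ArrayLike) -> float:
    """Sum of squared relative residuals, sum(((pred - obs)/obs)**2)."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape:
        raise ValueError("observed and predicted must have equal length")
    if np.any(obs == 0):
        raise ValueError("relative error undefined for zero observed values")
    return float(np.sum(((pred - obs) / obs) ** 2))


def _validate_xy(ca: ArrayLike, y: ArrayLike, min_points: int) -> tuple[NDArray, NDArray]:
    ca = np.asarray(ca, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if ca.shape != y.shape:
        raise ValueError("ca and y must have equal length")
    if ca.size < min_points:
        raise ValueError(f"need at least {min_points} points, got {ca.size}")
    return ca, y


class CalciumLinearRegression(RegressorMixin, BaseEstimator):
    """Ordinary least-squares line y = slope*[Ca] + intercept.

    The relative squared error of the fitted line is reported alongside the
    OLS coefficients (the line itself minimises absolute, not relative,
    squared error).
    """

    def fit(self, X: ArrayLike, y: ArrayLike) -> "CalciumLinearRegression":
        ca, y = _validate_xy(X, y, min_points=2)
        if np.ptp(ca) == 0:
            raise ValueError("singular design: all Ca values identical")
        self.slope_, self.intercept_ = (float(c) for c in np.polyfit(ca, y, 1))
        self.rel_sq_error_ = relative_squared_error(y, self.predict(ca))
        return self

    def predict(self, X: ArrayLike) -> NDArray[np.float64]:
        ca = np.asarray(X, dtype=float).ravel()
        return self.slope_ * ca + self.intercept_

    def result_(self) -> RegressionFit:
        return RegressionFit(
            form="linear",
            coefficients={"slope": self.slope_, "intercept": self.intercept_},
            rel_sq_error=self.rel_sq_error_,
        )


class _RelativeNMFit(RegressorMixin, BaseEstimator):
    """Shared machinery: minimise the relative squared error by Nelder-Mead
    from a deterministic primary start plus seeded log-normal perturbations."""

    form = ""

    def __init__(self, n_starts: int = 8, seed: int = 0, maxiter: int = 20000) -> None:
        self.n_starts = n_starts
        self.seed = seed
        self.maxiter = maxiter

    def _model(self, ca: NDArray, theta: NDArray) -> NDArray:  # pragma: no cover
        raise NotImplementedError

    def _primary_start(self, ca: NDArray, y: NDArray) -> NDArray:  # pragma: no cover
        raise NotImplementedError

    def _optimise(self, ca: NDArray, y: NDArray) -> tuple[NDArray, float]:
        def f(theta: NDArray) -> float:
            pred = self._model(ca, theta)
            if not np.all(np.isfinite(pred)):
                return np.inf
            return relative_squared_error(y, pred)

        theta0 = self._primary_start(ca, y)
        rng = np.random.default_rng(self.seed)
        starts = [theta0]
        for _ in range(self.n_starts - 1):
            starts.append(theta0 * np.exp(rng.normal(0.0, 0.3, size=theta0.shape)))
        best_theta, best_f = theta0, f(theta0)
        options = dict(xatol=1e-12, fatol=1e-14, maxiter=self.maxiter, maxfev=self.maxiter)
        for s in starts:
            res = minimize(f, s, method="Nelder-Mead", options=options)
            if res.fun < best_f:
                best_theta, best_f = res.x, float(res.fun)
        # polish from the incumbent
        res = minimize(f, best_theta, method="Nelder-Mead", options=options)
        if res.fun < best_f:
            best_theta, best_f = res.x, float(res.fun)
        return np.asarray(best_theta, dtype=float), float(best_f)


class CalciumExponentialDecay(_RelativeNMFit):
    """tau([Ca]) = prefactor * exp(-rate * [Ca]), fitted in relative error."""

    form = "exponential-decay"

    def _model(self, ca: NDArray, theta: NDArray) -> NDArray:
        pref, rate = theta
        return pref * np.exp(-rate * ca)

    def _primary_start(self, ca: NDArray, y: NDArray) -> NDArray:
        # log-linear OLS: log tau = log A - c * Ca
        slope, intercept = np.polyfit(ca, np.log(y), 1)
        return np.array([np.exp(intercept), -slope])

    def fit(self, X: ArrayLike, y: ArrayLike) -> "CalciumExponentialDecay":
        ca, y = _validate_xy(X, y, min_points=3)
        if np.any(y <= 0):
            raise ValueError("exponential decay requires positive values")
        theta, err = self._optimise(ca, y)
        self.prefactor_, self.rate_ = float(theta[0]), float(theta[1])
        self.rel_sq_error_ = err
        return self

    def predict(self, X: ArrayLike) -> NDArray[np.float64]:
        ca = np.asarray(X, dtype=float).ravel()
        return self.prefactor_ * np.exp(-self.rate_ * ca)

    def result_(self) -> RegressionFit:
        return RegressionFit(
            form=self.form,
            coefficients={"prefactor": self.prefactor_, "rate": self.rate_},
            rel_sq_error=self.rel_sq_error_,
        )


class CalciumOffsetExponential(_RelativeNMFit):
    """k([Ca]) = offset + scale * exp(rate * [Ca]), fitted in relative error.

    At rate ~ 0 the offset and scale are not separately identifiable
    (constant-plus-scale degeneracy); such fits are flagged ``ill_posed_``.
    """

    form = "offset-exponential"

    def _model(self, ca: NDArray, theta: NDArray) -> NDArray:
        offset, scale, rate = theta
        return offset + scale * np.exp(rate * ca)

    def _primary_start(self, ca: NDArray, y: NDArray) -> NDArray:
        offset0 = float(np.min(y)) * 0.95
        resid = np.maximum(y - offset0, 1e-8)
        slope, intercept = np.polyfit(ca, np.log(resid), 1)
        return np.array([offset0, np.exp(intercept), slope])

    def fit(self, X: ArrayLike, y: ArrayLike) -> "CalciumOffsetExponential":
        ca, y = _validate_xy(X, y, min_points=4)
        theta, err = self._optimise(ca, y)
        self.offset_, self.scale_, self.rate_ = (float(v) for v in theta)
        self.rel_sq_error_ = err
        # degenerate curvature: exp(rate*ca) indistinguishable from a constant
        self.ill_posed_ = bool(abs(self.rate_) * float(np.ptp(ca)) < 1e-6)
        return self

    def predict(self, X: ArrayLike) -> NDArray[np.float64]:
        ca = np.asarray(X, dtype=float).ravel()
        return self.offset_ + self.scale_ * np.exp(self.rate_ * ca)

    def result_(self) -> RegressionFit:
        return RegressionFit(
            form=self.form,
            coefficients={"offset": self.offset_, "scale": self.scale_, "rate": self.rate_},
            rel_sq_error=self.rel_sq_error_,
            ill_posed=self.ill_posed_,
            notes="offset/scale not separately identifiable" if self.ill_posed_ else "",
        )


def fit_linear(ca: ArrayLike, y: ArrayLike) -> RegressionFit:
    return CalciumLinearRegression().fit(ca, y).result_()


def fit_exponential_decay(ca: ArrayLike, tau: ArrayLike, **opts) -> RegressionFit:
    return CalciumExponentialDecay(**opts).fit(ca, tau).result_()


def fit_offset_exponential(ca: ArrayLike, k: ArrayLike, **opts) -> RegressionFit:
    return CalciumOffsetExponential(**opts).fit(ca, k).result_()


def load_reference_table() -> pd.DataFrame:
    """Packaged per-calcium parameter table (fixed b = 0.021).

    Columns: ca_uM, tau_min, a, k, err — one row per Ca2+ concentration of
    the 40-140 uM titration of rat-liver mitochondria.
    """
    with resources.files("mitoswell.data").joinpath("calcium_titration_params.csv").open() as fh:
        df = pd.read_csv(fh)
    df.attrs["b"] = DEFAULT_B
    return df


def run_meta_regressions(
    table: pd.DataFrame | None = None,
    exclude_bound_rows: bool = False,
    tau_bound: float = 2.0,
) -> dict[str, RegressionFit]:
    """Fit all three parameter-vs-calcium laws on a parameter table.

    ``exclude_bound_rows`` drops rows whose tau sits at the optimiser's
    lower bound (within 1e-3 of ``tau_bound``), where the delay is not
    reliably identified.
    """
    df = load_reference_table() if table is None else table
    if exclude_bound_rows:
        df = df[np.abs(df["tau_min"] - tau_bound) > 1e-3]
    ca = df["ca_uM"].to_numpy(dtype=float)
    return {
        "a": fit_linear(ca, df["a"].to_numpy(dtype=float)),
        "tau": fit_exponential_decay(ca, df["tau_min"].to_numpy(dtype=float)),
        "k": fit_offset_exponential(ca, df["k"].to_numpy(dtype=float)),
    }
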