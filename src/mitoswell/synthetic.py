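"""Synthetic plate-reader absorbance curves for closed-loop testing.

No raw swelling measurements are publicly deposited, so the generators
here produce curves with the statistical structure the analysis assumes:
model volume kinetics, a decreasing linear volume-to-OD map, and additive
i.i.d. Gaussian measurement noise.  Per-concentration generating
parameters follow the empirical calcium laws of the 40-140 uM titration
(linear a, exponentially decaying tau, offset-exponential k, fixed b),
so a generated panel mimics a full dose-response experiment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from numpy.typing import ArrayLike, NDArray

from . import kinetics
from .fitting import AbsorbanceSeries, RescaleMap
from .parameters import DEFAULT_B, DEFAULT_CONSTANTS, PopulationConstants, SwellingParameters

__all__ = [
    "NoiseModel",
    "PanelSpec",
    "od_map_for",
    "calcium_parameters",
    "generate_curve",
    "generate_panel",
    "generate_shrinking_curve",
]

#: Empirical parameter-vs-calcium laws of the 40-140 uM rat-liver titration.
A_SLOPE, A_INTERCEPT = 0.00297, 0.0333
TAU_PREFACTOR, TAU_RATE = 83.7, 0.0293
K_OFFSET, K_SCALE, K_RATE = 0.692, 0.0137, 0.0218


@dataclass(frozen=True)
class NoiseModel:
    """Additive Gaussian measurement noise on the OD readings."""

    sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError(f"sigma must be >= 0, got {self.sigma}")

    def sample(self, n: int) -> NDArray[np.float64]:
        if self.sigma == 0.0:
            return np.zeros(n)
        return np.random.default_rng(self.seed).normal(0.0, self.sigma, size=n)


@dataclass(frozen=True)
class PanelSpec:
    """A synthetic dose-response panel: one curve per Ca2+ concentration."""

    ca_list: tuple[float, ...] = tuple(range(40, 141, 10))
    duration: float = 60.0
    dt: float = 0.25
    A0: float = 1.0
    Ap: float = 0.4
    noise: NoiseModel = field(default_factory=NoiseModel)
    b: float = DEFAULT_B

    def __post_init__(self) -> None:
        if self.duration <= 0 or self.dt <= 0:
            raise ValueError("duration and dt must be positive")
        if not self.ca_list:
            raise ValueError("ca_list must be nonempty")
        if any(not 10 <= ca <= 300 for ca in self.ca_list):
            raise ValueError("Ca concentrations must lie in 10-300 uM")

    @property
    def grid(self) -> NDArray[np.float64]:
        return kinetics.default_grid(self.duration, self.dt)


def calcium_parameters(ca_uM: float, b: float = DEFAULT_B) -> SwellingParameters:
    """Generating kinetics at one Ca2+ dose from the empirical laws.

    tau decreases and a increases monotonically with the dose; k is capped
    at 1 (the laws slightly exceed it above ~140 uM).
    """
    return SwellingParameters(
        a=A_SLOPE * ca_uM + A_INTERCEPT,
        b=b,
        k=min(K_OFFSET + K_SCALE * np.exp(K_RATE * ca_uM), 1.0),
        tau=TAU_PREFACTOR * np.exp(-TAU_RATE * ca_uM),
    )


def od_map_for(
    consts: PopulationConstants, A0: float = 1.0, Ap: float = 0.4
) -> RescaleMap:
    """Volume-to-OD map anchored at V(0) = V0 -> A0 and V(inf) -> Ap.

    Anchoring at the model's initial and limiting volumes (rather than the
    realised curve extremes) means a shrinking transient, where V dips
    below V0, shows up as OD rising above A0 — as seen in real assays.
    """
    slope = (Ap - A0) / (consts.V_inf - consts.V0)
    return RescaleMap(slope=slope, offset=A0 - slope * consts.V0)


def generate_curve(
    params: SwellingParameters,
    consts: PopulationConstants = DEFAULT_CONSTANTS,
    grid: ArrayLike | None = None,
    od_map: RescaleMap | None = None,
    noise: NoiseModel = NoiseModel(),
    label: str = "",
    ca_uM: float | None = None,
) -> AbsorbanceSeries:
    """One synthetic absorbance curve A(t) = offset + slope*V(t) + eps.

    With sigma = 0 the curve is deterministic, starts exactly at A0
    (V(0) = V0) and decays toward Ap.
    """
    grid = kinetics.default_grid() if grid is None else np.asarray(grid, dtype=float)
    od_map = od_map_for(consts) if od_map is None else od_map
    volume = kinetics.total_volume(grid, params, consts).values
    values = od_map(volume) + noise.sample(grid.size)
    return AbsorbanceSeries(times=grid, values=values, label=label, ca_uM=ca_uM)


def generate_panel(
    spec: PanelSpec,
    consts: PopulationConstants = DEFAULT_CONSTANTS,
) -> list[AbsorbanceSeries]:
    """One labelled curve per concentration of the panel.

    Curves at higher Ca2+ have shorter generating delays and stronger
    feedback, so their OD drop starts earlier.  Each curve gets an
    independent noise stream derived from the panel seed.
    """
    od_map = od_map_for(consts, spec.A0, spec.Ap)
    out = []
    for i, ca in enumerate(spec.ca_list):
        noise = NoiseModel(sigma=spec.noise.sigma, seed=spec.noise.seed + i)
        out.append(
            generate_curve(
                calcium_parameters(ca, b=spec.b), consts, spec.grid, od_map,
                noise, label=f"Ca {ca:g} uM", ca_uM=float(ca),
            )
        )
    return out


def generate_shrinking_curve(
    consts: PopulationConstants = DEFAULT_CONSTANTS,
    k: float = 0.55,
    a: float = 0.7,
    b: float = 0.02,
    tau: float = 5.0,
    grid: ArrayLike | None = None,
    noise: NoiseModel = NoiseModel(),
) -> AbsorbanceSeries:
    """A curve in the transient-shrinking regime (k*V_p < V0).

    The actively swelling subpopulation is then on average smaller than
    unswollen mitochondria, so the mean volume first dips below V0 and the
    noise-free OD transiently rises above A0 before the main decline.
    """
    if k * consts.V_p >= consts.V0:
        raise ValueError(
            f"shrinking regime requires k*V_p < V0 (k*V_p={k * consts.V_p:.3f}, V0={consts.V0})"
        )
    params = SwellingParameters(a=a, b=b, k=k, tau=tau)
    return generate_curve(params, consts, grid, noise=noise, label=f"shrinking k={k:g}")
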