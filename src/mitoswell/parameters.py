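"""Parameter and constant containers for the swelling model.

The kinetic model tracks ``X(t)``, the fraction of mitochondria that are
swollen or have started swelling by time ``t``, via

    X'(t) = (a * X(t)**r + b) * (X_p - X(t)),    X(0) = 0,

and splits the mean population volume into unswollen, actively swelling
(delayed by ``tau``, mean volume ``k * V_p``), and fully swollen
subpopulations.
"""

from __future__ import annotations

from dataclasses import dataclass, replace


@dataclass(frozen=True)
class SwellingParameters:
    """Kinetic parameters of the swelling process.

    Parameters
    ----------
    a : float
        Positive-feedback rate (1/min): Ca2+ released by already-swollen
        mitochondria accelerates swelling of the rest.  ``a = 0`` reduces
        the kinetics to first order.
    b : float
        Background swelling rate (1/min) induced directly by the initial
        stimulus; non-negative.  With ``b = 0`` swelling never starts
        (X = 0 is a fixed point of the kinetics).
    k : float
        Dimensionless fraction of the fully swollen volume ``V_p`` that the
        actively swelling subpopulation occupies on average.  ``k * V_p <
        V0`` encodes transient shrinking.
    tau : float
        Mean time (min) a single mitochondrion spends actively swelling
        (the delay of the volume equation).
    r : float
        Kinetic order of the feedback term; the closed-form solution exists
        only for ``r = 1``.
    """

    a: float
    b: float
    k: float
    tau: float
    r: float = 1.0

    def __post_init__(self) -> None:
        if self.a < 0:
            raise ValueError(f"feedback rate a must be >= 0, got {self.a}")
        if self.b < 0:
            raise ValueError(f"background rate b must be >= 0, got {self.b}")
        if not 0 < self.k <= 1:
            raise ValueError(f"swelling-volume factor k must be in (0, 1], got {self.k}")
        if self.tau < 0:
            raise ValueError(f"delay tau must be >= 0, got {self.tau}")
        if self.r <= 0:
            raise ValueError(f"kinetic order r must be > 0, got {self.r}")

    def with_(self, **changes: float) -> "SwellingParameters":
        return replace(self, **changes)


@dataclass(frozen=True)
class PopulationConstants:
    """Fixed population-level constants.

    ``X_p`` is the final fraction of mitochondria that ever swell (< 1:
    some never do), ``V0`` and ``V_p`` the mean single-mitochondrion
    volumes before and after swelling, in ml per mg protein.
    """

    X_p: float = 0.9
    V0: float = 1.2
    V_p: float = 1.7

    def __post_init__(self) -> None:
        if not 0 < self.X_p < 1:
            raise ValueError(f"X_p must be in (0, 1), got {self.X_p}")
        if not 0 < self.V0 < self.V_p:
            raise ValueError(f"need 0 < V0 < V_p, got V0={self.V0}, V_p={self.V_p}")

    @property
    def V_inf(self) -> float:
        """Large-time limit of the mean population volume."""
        return self.V0 * (1.0 - self.X_p) + self.V_p * self.X_p


#: Background rate shared by all rows of the packaged parameter table.
DEFAULT_B = 0.021

DEFAULT_CONSTANTS = PopulationConstants()
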