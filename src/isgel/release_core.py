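"""Closed-form first-order release model and prediction sweeps.

An in situ forming gel depot releases drug into a well-mixed bath whose
concentration ``C3(t)`` obeys the linear exchange ODE

    dC3/dt + (K32 / V3) C3 = (K32 / V3) C2_edge,     C3(t0) = 0,

where ``C2_edge`` is the drug concentration at the outer edge of the
polymer matrix (the plateau of the release curve, in % of dose), ``K32``
is the matrix-to-bath transfer coefficient and ``V3`` the bath volume.
The solution is the single-exponential release curve

    C3(t) = C2_edge * (1 - exp(-a (t - t0))),    a = K32 / V3.

Units are fixed project-wide: time in days, volume in mL, release in % of
nominal dose.  ``K32`` follows the convention ``K32 = a * V3`` with ``V3``
in mL, so a value of e.g. 56.65 with ``V3 = 80`` mL corresponds to a rate
constant of 0.7081 day^-1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

from .errors import DomainError, InvalidInputError, InvalidModelError

__all__ = [
    "FirstOrderModel",
    "ReleaseSeries",
    "SweepGrid",
    "evaluate_release_curve",
    "fraction_released_at",
    "sweep_profiles",
]


@dataclass(frozen=True)
class FirstOrderModel:
    """Single-exponential release model ``C3(t) = C2_edge (1 - e^{-a(t-t0)})``.

    Parameters
    ----------
    C2_edge:
        Plateau concentration, % of dose. Must be positive.
    rate_a:
        Exterior exchange rate constant ``a = K32 / V3``, day^-1.
    V3:
        Bath (release medium) volume, mL.
    t0:
        Origin (injection / lag) time, days. Release is zero at ``t0``.
    """

    C2_edge: float
    rate_a: float
    V3: float = 80.0
    t0: float = 0.0

    def __post_init__(self) -> None:
        if not (self.C2_edge > 0):
            raise InvalidModelError(f"C2_edge must be > 0, got {self.C2_edge}")
        if not (self.rate_a > 0):
            raise InvalidModelError(f"rate_a must be > 0, got {self.rate_a}")
        if not (self.V3 > 0):
            raise InvalidModelError(f"V3 must be > 0, got {self.V3}")

    @property
    def K32(self) -> float:
        """Transfer coefficient in the ``K32 = rate_a * V3`` convention."""
        return self.rate_a * self.V3

    @classmethod
    def from_K32(
        cls, K32: float, C2_edge: float, V3: float = 80.0, t0: float = 0.0
    ) -> "FirstOrderModel":
        """Build a model from the reported transfer coefficient ``K32``."""
        if not (V3 > 0):
            raise InvalidModelError(f"V3 must be > 0, got {V3}")
        return cls(C2_edge=C2_edge, rate_a=K32 / V3, V3=V3, t0=t0)


@dataclass(frozen=True)
class ReleaseSeries:
    """Sampled cumulative-release trajectory.

    ``times`` are strictly increasing sample times in days (all >= ``t0``);
    ``values`` are cumulative release in % of dose.
    """

    times: np.ndarray
    values: np.ndarray
    t0: float = 0.0

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", values)
        if times.ndim != 1 or values.ndim != 1 or times.size != values.size:
            raise InvalidInputError(
                "times and values must be 1-D arrays of equal length"
            )
        if times.size and not np.all(np.diff(times) > 0):
            raise InvalidInputError("times must be strictly increasing")
        if times.size and times[0] < self.t0 - 1e-12:
            raise InvalidInputError(
                f"times[0]={times[0]} precedes origin t0={self.t0}"
            )
        if not np.all(np.isfinite(values)):
            raise InvalidInputError("values must be finite")

    def __len__(self) -> int:
        return int(self.times.size)


@dataclass(frozen=True)
class SweepGrid:
    """Cartesian parameter grid for release-profile prediction sweeps."""

    K32_values: Sequence[float]
    C2_values: Sequence[float]
    time_grid: Sequence[float]
    V3: float = 80.0

    def __post_init__(self) -> None:
        if any(k <= 0 for k in self.K32_values):
            raise InvalidInputError("all K32 values must be positive")
        if any(c <= 0 for c in self.C2_values):
            raise InvalidInputError("all C2 values must be positive")
        if not (self.V3 > 0):
            raise InvalidInputError("V3 must be positive")
        t = np.asarray(self.time_grid, dtype=float)
        if t.size >= 2 and not np.all(np.diff(t) > 0):
            raise InvalidInputError("time_grid must be strictly increasing")


def evaluate_release_curve(
    model: FirstOrderModel, times: Sequence[float]
) -> ReleaseSeries:
    """Evaluate the closed-form release curve on a time grid.

    Returns the series ``C2_edge * (1 - exp(-rate_a * (t - t0)))`` for each
    ``t`` in ``times``; values are nondecreasing and bounded by ``C2_edge``.

    Raises
    ------
    DomainError
        If any time precedes the model origin ``t0``.
    """
    t = np.asarray(times, dtype=float)
    if t.size and np.min(t) < model.t0 - 1e-12:
        raise DomainError(
            f"evaluation time {np.min(t)} precedes model origin t0={model.t0}"
        )
    values = model.C2_edge * -np.expm1(-model.rate_a * (t - model.t0))
    return ReleaseSeries(times=t, values=values, t0=model.t0)


def fraction_released_at(model: FirstOrderModel, t: float) -> float:
    """Fraction of the plateau released by time ``t`` (in [0, 1))."""
    if t < model.t0:
        raise DomainError(f"t={t} precedes model origin t0={model.t0}")
    return float(-np.expm1(-model.rate_a * (t - model.t0)))


def sweep_profiles(
    grid: SweepGrid, t0: float = 0.0
) -> list[tuple[float, float, ReleaseSeries]]:
    """Release profiles over the cartesian product of a parameter grid.

    One ``(K32, C2_edge, series)`` triple per parameter pair, ordered by
    ``(C2_edge, K32)``. An empty grid yields an empty list.
    """
    out: list[tuple[float, float, ReleaseSeries]] = []
    for c2 in sorted(self_unique(grid.C2_values)):
        for k32 in sorted(self_unique(grid.K32_values)):
            model = FirstOrderModel.from_K32(
                K32=k32, C2_edge=c2, V3=grid.V3, t0=t0
            )
            out.append((k32, c2, evaluate_release_curve(model, grid.time_grid)))
    return out


def self_unique(values: Sequence[float]) -> Iterator[float]:
    """Preserve-order deduplication of a numeric sequence."""
    seen: set[float] = set()
    for v in values:
        if v not in seen:
            seen.add(v)
            yield v
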