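"""Numerical differentiation on uniform grids.

Two stencils are provided, matching the two orders used throughout the
estimation pipeline:

* 2-point forward difference, ``(y[i+1] - y[i]) / h``, order h, anchored
  at the left node — estimates exist at indices ``0 .. n-2``;
* 5-point central difference,
  ``(-y[i+2] + 8 y[i+1] - 8 y[i-1] + y[i-2]) / (12 h)``, order h^4,
  anchored at the centre node — estimates exist at indices ``2 .. n-3``.

Nodes without a full stencil are dropped rather than filled with a
lower-order one-sided formula, so every returned estimate is at the
advertised order.  Experimental schedules are rarely uniform; use
:func:`resample_uniform` (monotone piecewise-cubic) first.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.interpolate import PchipInterpolator

from .errors import GridError, InsufficientDataError
from .release_core import ReleaseSeries

__all__ = [
    "DerivativeEstimate",
    "check_uniform_grid",
    "resample_uniform",
    "forward_diff",
    "central_diff4",
]


@dataclass(frozen=True)
class DerivativeEstimate:
    """Derivative estimates on a subset of the input grid.

    ``node_indices[j]`` is the input-grid index where ``values[j]``
    estimates the derivative; ``order_tag`` records the stencil order.
    """

    node_indices: np.ndarray
    values: np.ndarray
    step_h: float
    order_tag: str


def check_uniform_grid(times: Sequence[float], rel_tol: float = 1e-6) -> float:
    """Return the common spacing of a uniform grid, or raise.

    The grid is accepted when every successive gap deviates from the mean
    gap by at most ``rel_tol`` relatively; the error message names the
    worst interval otherwise.
    """
    t = np.asarray(times, dtype=float)
    if t.size < 2:
        raise GridError("need at least 2 time points to define a spacing")
    gaps = np.diff(t)
    if np.any(gaps <= 0):
        raise GridError("times must be strictly increasing")
    h = float(gaps.mean())
    rel_dev = np.abs(gaps - h) / h
    worst = int(np.argmax(rel_dev))
    if rel_dev[worst] > rel_tol:
        raise GridError(
            f"grid is not uniform: interval [{t[worst]}, {t[worst + 1]}] has "
            f"gap {gaps[worst]:.6g} vs mean {h:.6g} "
            f"(relative deviation {rel_dev[worst]:.3g} > {rel_tol:g})"
        )
    return h


def resample_uniform(series: ReleaseSeries, h: float) -> ReleaseSeries:
    """Resample a release series onto a uniform grid of spacing ``h``.

    Uses monotone shape-preserving piecewise-cubic (PCHIP) interpolation:
    the interpolant passes through every input point and preserves
    monotonicity, so a nondecreasing release curve stays nondecreasing.
    The output grid spans ``[times[0], times[-1]]``.
    """
    if len(series) < 4:
        raise InsufficientDataError(
            f"resampling needs >= 4 points, got {len(series)}"
        )
    if h <= 0:
        raise GridError(f"step h must be positive, got {h}")
    span = series.times[-1] - series.times[0]
    if h > span:
        raise GridError(f"step h={h} exceeds the series span {span}")
    n = int(np.floor(span / h + 1e-9))
    grid = series.times[0] + h * np.arange(n + 1)
    interp = PchipInterpolator(series.times, series.values)
    return ReleaseSeries(times=grid, values=interp(grid), t0=series.t0)


def forward_diff(values: Sequence[float], h: float) -> DerivativeEstimate:
    """2-point forward difference, order h, exact for affine sequences."""
    y = np.asarray(values, dtype=float)
    if y.size < 2:
        raise InsufficientDataError(
            f"forward difference needs >= 2 values, got {y.size}"
        )
    if h <= 0:
        raise GridError(f"step h must be positive, got {h}")
    est = (y[1:] - y[:-1]) / h
    return DerivativeEstimate(
        node_indices=np.arange(y.size - 1),
        values=est,
        step_h=float(h),
        order_tag="O(h)",
    )


def central_diff4(values: Sequence[float], h: float) -> DerivativeEstimate:
    """5-point central difference, order h^4, exact for quartics."""
    y = np.asarray(values, dtype=float)
    if y.size < 5:
        raise InsufficientDataError(
            f"central difference needs >= 5 values, got {y.size}"
        )
    if h <= 0:
        raise GridError(f"step h must be positive, got {h}")
    est = (-y[4:] + 8.0 * y[3:-1] - 8.0 * y[1:-3] + y[:-4]) / (12.0 * h)
    return DerivativeEstimate(
        node_indices=np.arange(2, y.size - 2),
        values=est,
        step_h=float(h),
        order_tag="O(h4)",
    )
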