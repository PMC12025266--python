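"""Small shared numerics: banded trapezoidal integration over an interval."""

from __future__ import annotations

import numpy as np


def trapezoid_band(x: np.ndarray, y: np.ndarray, lo: float, hi: float,
                   min_points: int = 3) -> float:
    """Trapezoidal integral of y(x) over [lo, hi] with interpolated end bins.

    ``x`` may be ascending or descending; the integral is reported with
    positive orientation (lo -> hi). Interval ends falling between grid
    points are handled by linear interpolation, which makes the integral
    exactly additive over a partition of the interval. Sign of ``y`` is
    preserved.
    """
    if not lo < hi:
        raise ValueError("need lo < hi")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x[0] > x[-1]:
        x, y = x[::-1], y[::-1]
    if lo < x[0] - 1e-12 or hi > x[-1] + 1e-12:
        raise ValueError(
            f"interval [{lo}, {hi}] outside data range [{x[0]}, {x[-1]}]"
        )
    inside = (x > lo) & (x < hi)
    if int(inside.sum()) < min_points:
        raise ValueError(
            f"interval [{lo}, {hi}] covers only {int(inside.sum())} grid points "
            f"(< {min_points})"
        )
    xs = np.concatenate(([lo], x[inside], [hi]))
    ys = np.concatenate(([np.interp(lo, x, y)], y[inside], [np.interp(hi, x, y)]))
    return float(np.trapezoid(ys, xs))
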