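"""Wood's lactation curves and the test-interval (interval-centering) method.

The Wood's curve models daily milk yield ``y(t) = a t^b exp(-c t)`` over days
in milk *t*.  Whole-lactation yield from a handful of herd tests is estimated
by interval centering: each test-day yield is weighted by the number of
lactation days nearer to that test than to any other, so the weights are
nonnegative integers summing exactly to the lactation length.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit

from .io_formats import TestDaySeries

__all__ = [
    "WoodsCurve",
    "woods_yield",
    "fit_woods_curve",
    "predict_daily_yield",
    "daily_sum_yield",
    "interval_weights",
    "interval_centering_yield",
]

MIN_TESTS = 4  # the test-interval method requires at least four herd tests


@dataclass
class WoodsCurve:
    """Fitted Wood's-curve parameters for one cow.

    ``a`` scales the curve (L/day), ``b`` is the dimensionless rise exponent,
    ``c`` the per-day exponential decay.  ``peak day`` is b/c when both are
    positive.
    """

    a: float
    b: float
    c: float
    residual_sd: float = 0.0
    n_points: int = 0
    converged: bool = True

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise ValueError(f"Wood's parameter a must be positive, got {self.a}")
        if self.c < 0:
            raise ValueError(f"Wood's parameter c must be >= 0, got {self.c}")


def woods_yield(t, a: float, b: float, c: float):
    """Wood's curve value a * t^b * exp(-c t); vectorised over t."""
    t = np.asarray(t, dtype=float)
    return a * np.power(t, b) * np.exp(-c * t)


def predict_daily_yield(curve: WoodsCurve, day: int | np.ndarray) -> float | np.ndarray:
    """Predicted daily yield at integer day(s) >= 1; clamped at 0."""
    day_arr = np.asarray(day)
    if np.any(day_arr <= 0):
        raise ValueError("day must be >= 1")
    out = woods_yield(day_arr, curve.a, curve.b, curve.c)
    out = np.maximum(out, 0.0)
    return float(out) if np.isscalar(day) or day_arr.ndim == 0 else out


def daily_sum_yield(curve: WoodsCurve, lactation_length: int) -> float:
    """Whole-lactation yield as the day-by-day sum over t = 1..L."""
    if lactation_length < 1:
        raise ValueError("lactation_length must be >= 1")
    days = np.arange(1, lactation_length + 1)
    return float(np.sum(predict_daily_yield(curve, days)))


def fit_woods_curve(
    series: TestDaySeries | None = None,
    *,
    days: Sequence[int] | None = None,
    yields: Sequence[float] | None = None,
    max_nfev: int = 2000,
    xtol: float = 1e-10,
) -> WoodsCurve:
    """Nonlinear least-squares fit of the Wood's curve to one cow's tests.

    Accepts either a :class:`TestDaySeries` or explicit ``days``/``yields``
    vectors.  Starting values come from the log-linearised regression
    ``ln y = ln a + b ln t - c t``; the nonlinear fit then minimises squared
    residuals on the natural scale, residuals assumed independent across
    days and cows.  A fit that exhausts the iteration budget is returned
    with ``converged=False`` rather than silently discarded.
    """
    if series is not None:
        days = series.days_in_milk()
        yields = series.yields()
    t = np.asarray(days, dtype=float)
    y = np.asarray(yields, dtype=float)
    if t.size < MIN_TESTS or np.unique(t).size < MIN_TESTS:
        raise ValueError(
            f"need >= {MIN_TESTS} tests with distinct days in milk, got {t.size}"
        )
    if np.any(y <= 0):
        raise ValueError("non-positive test-day yield; cannot fit Wood's curve")
    # log-linear start: ln y = ln a + b ln t - c t
    X = np.column_stack([np.ones_like(t), np.log(t), -t])
    coef, *_ = np.linalg.lstsq(X, np.log(y), rcond=None)
    a0 = float(np.exp(coef[0]))
    b0 = float(coef[1])
    c0 = float(max(coef[2], 0.0))
    converged = True
    try:
        popt, _ = curve_fit(
            woods_yield,
            t,
            y,
            p0=[a0, b0, c0],
            bounds=([1e-8, -2.0, 0.0], [np.inf, 5.0, 1.0]),
            maxfev=max_nfev,
            xtol=xtol,
        )
    except RuntimeError:
        popt = [max(a0, 1e-8), b0, max(c0, 0.0)]
        converged = False
    a, b, c = (float(v) for v in popt)
    resid = y - woods_yield(t, a, b, c)
    dof = max(t.size - 3, 1)
    return WoodsCurve(
        a=a,
        b=b,
        c=c,
        residual_sd=float(np.sqrt(np.sum(resid**2) / dof)),
        n_points=int(t.size),
        converged=converged,
    )


def interval_weights(test_days: Sequence[int], lactation_length: int) -> np.ndarray:
    """Integer day-counts assigning every lactation day to its nearest test.

    Day boundaries fall at ``floor((t_i + t_{i+1}) / 2)``: the boundary day
    itself belongs to the earlier test (deterministic tie-break when the sum
    is even).  The first test's span extends back to day 1 and the last
    test's forward to the lactation end, so the weights always sum to
    ``lactation_length`` exactly.
    """
    t = np.asarray(test_days, dtype=int)
    if t.size < MIN_TESTS:
        raise ValueError(f"interval centering needs >= {MIN_TESTS} tests, got {t.size}")
    if np.any(np.diff(t) <= 0):
        raise ValueError("test days must be strictly increasing")
    if t[0] < 1 or t[-1] > lactation_length:
        raise ValueError(
            f"tests must lie within (0, {lactation_length}], got range "
            f"[{t[0]}, {t[-1]}]"
        )
    bounds = np.concatenate(
        [[0], (t[:-1] + t[1:]) // 2, [lactation_length]]
    )
    w = np.diff(bounds)
    assert w.sum() == lactation_length and np.all(w >= 0)
    return w


def interval_centering_yield(
    days_in_milk_at_tests: Sequence[int],
    yields: Sequence[float],
    lactation_length: int,
) -> float:
    """Whole-lactation milk yield by the test-interval method.

    ``sum_i y_i * w_i`` with weights from :func:`interval_weights`.  Exact for
    a constant daily yield; approaches the day-by-day sum as tests densify.
    """
    y = np.asarray(yields, dtype=float)
    w = interval_weights(days_in_milk_at_tests, lactation_length)
    if y.size != w.size:
        raise ValueError("days and yields must have equal length")
    return float(np.dot(np.maximum(y, 0.0), w))
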