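"""Discrete and continuous ABC (effort-yield) curves.

An ABC curve plots the cumulative yield ``Y_i`` (fraction of the total sum
contributed by the ``i`` largest values) against the effort ``E_i = i/n``
(fraction of items considered, in decreasing order of value).  For
non-negative data the curve is non-decreasing and concave inside the unit
square, with ABC(0) = 0 and ABC(1) = 1.  Its slope dY/dE, the *profit gain*,
is the marginal yield per unit of effort and is non-increasing.

This module builds the discrete representation (:class:`AbcPoints`), turns it
into a continuous, differentiable curve via a monotone, concavity-preserving
piecewise-quadratic spline (:class:`QuadraticSplineCurve`), and provides the
two reference curves used to judge inequality: the identity diagonal
(all items equal) and the closed-form curve of a uniform distribution over
the observed data range.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .errors import DataValidationError, DegenerateDataError

__all__ = [
    "validate_values",
    "AbcPoints",
    "AbcCurve",
    "QuadraticSplineCurve",
    "ClosedFormCurve",
    "compute_abc_points",
    "fit_curve",
    "profit_gain",
    "reference_curves",
]

#: absolute tolerance for curve invariant checks
TOL = 1e-9


def validate_values(values: Sequence[float] | np.ndarray, min_n: int = 1) -> np.ndarray:
    """Validate a vector of non-negative importance/weight/effect values.

    Negative or non-finite entries are rejected (ABC curves are only defined
    for x >= 0); zeros are permitted but warned about, since items with zero
    value contribute effort without yield.

    Returns a float64 copy of the input.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim == 2 and 1 in x.shape:
        x = x.ravel()
    if x.ndim != 1:
        raise DataValidationError(f"expected a 1-D value vector, got shape {x.shape}")
    if x.size < min_n:
        raise DataValidationError(f"need at least {min_n} values, got {x.size}")
    if not np.all(np.isfinite(x)):
        k = int(np.flatnonzero(~np.isfinite(x))[0])
        raise DataValidationError(f"non-finite value at position {k}")
    if np.any(x < 0):
        k = int(np.flatnonzero(x < 0)[0])
        raise DataValidationError(f"negative value at position {k}")
    n_zero = int(np.count_nonzero(x == 0))
    if n_zero:
        warnings.warn(
            f"{n_zero} zero value(s) in input: they add effort but no yield",
            UserWarning,
            stacklevel=2,
        )
    return x


@dataclass(frozen=True)
class AbcPoints:
    """Discrete effort/yield pairs of a data vector.

    Attributes
    ----------
    efforts : ndarray
        E_i = i/n for i = 1..n; strictly increasing, last value 1.
    yields : ndarray
        Y_i = cumulative sum of the i largest values over the total sum;
        non-decreasing, last value 1.
    order : ndarray
        Permutation mapping decreasing ranks back to input positions
        (ties broken by stable original order).
    """

    efforts: np.ndarray
    yields: np.ndarray
    order: np.ndarray

    def __post_init__(self) -> None:
        e, y = self.efforts, self.yields
        if not (np.all(np.diff(e) > 0) and abs(e[-1] - 1.0) < 1e-12):
            raise DataValidationError("efforts must be strictly increasing up to 1")
        if not (np.all(np.diff(y) >= -1e-12) and abs(y[-1] - 1.0) < 1e-12):
            raise DataValidationError("yields must be non-decreasing up to 1")
        if np.any(y < e - 1e-12):
            raise DataValidationError("yields must dominate efforts (concavity)")

    @property
    def n(self) -> int:
        return len(self.efforts)


def compute_abc_points(values: Sequence[float] | np.ndarray) -> AbcPoints:
    """Sort values decreasingly and compute the (E_i, Y_i) pairs.

    Raises
    ------
    DegenerateDataError
        If all values are zero (the total yield is degenerate).
    DataValidationError
        If any value is negative or non-finite.
    """
    x = validate_values(values)
    total = x.sum()
    if total <= 0:
        raise DegenerateDataError("degenerate total yield: all values are zero")
    order = np.argsort(-x, kind="stable")
    xs = x[order]
    n = x.size
    efforts = np.arange(1, n + 1, dtype=float) / n
    yields = np.cumsum(xs) / total
    yields[-1] = 1.0  # exact by definition; protects the invariant from fp drift
    return AbcPoints(efforts=efforts, yields=yields, order=order)


class AbcCurve:
    """A continuous ABC curve on [0, 1] with a derivative (profit gain).

    Subclasses provide ``_evaluate`` and ``_derivative`` on validated arrays.
    ``knots`` holds the realizable (effort, yield) points for curves fitted to
    empirical data and is ``None`` for analytic curves.
    """

    source: str = "abstract"
    knots: tuple[np.ndarray, np.ndarray] | None = None

    def _check_p(self, p):
        arr = np.asarray(p, dtype=float)
        if np.any(arr < -1e-12) or np.any(arr > 1 + 1e-12):
            raise DataValidationError("curve argument p must lie in [0, 1]")
        return np.clip(arr, 0.0, 1.0)

    def evaluate(self, p):
        arr = self._check_p(p)
        out = self._evaluate(np.atleast_1d(arr))
        return float(out[0]) if arr.ndim == 0 else out

    def derivative(self, p):
        arr = self._check_p(p)
        out = self._derivative(np.atleast_1d(arr))
        return float(out[0]) if arr.ndim == 0 else out

    __call__ = evaluate

    def _evaluate(self, p: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def _derivative(self, p: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class ClosedFormCurve(AbcCurve):
    """ABC curve given by explicit formulas for value and slope."""

    def __init__(
        self,
        fn: Callable[[np.ndarray], np.ndarray],
        dfn: Callable[[np.ndarray], np.ndarray],
        source: str = "closed-form",
        name: str = "",
    ) -> None:
        self._fn = fn
        self._dfn = dfn
        self.source = source
        self.name = name
        self.knots = None

    def _evaluate(self, p: np.ndarray) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            out = np.asarray(self._fn(p), dtype=float)
        # endpoints are pinned by definition
        out = np.where(p <= 0, 0.0, out)
        out = np.where(p >= 1, 1.0, out)
        return out

    def _derivative(self, p: np.ndarray) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.asarray(self._dfn(p), dtype=float)

    def __repr__(self) -> str:  # pragma: no cover
        return f"ClosedFormCurve({self.name or self.source})"


class QuadraticSplineCurve(AbcCurve):
    """Monotone, concavity-preserving piecewise-quadratic interpolant.

    The curve passes exactly through (0,0), every (E_i, Y_i), and (1,1).  Its
    derivative is continuous piecewise-linear and non-increasing, so the
    interpolation cannot introduce spurious wiggles into an effort-yield
    curve.  Knot slopes are set to the mean of the adjacent secants (which for
    concave data always lies between them); where a single quadratic piece
    cannot carry the derivative from one knot slope to the next while
    reproducing the interval mass, the interval is split in two with one
    linear sub-piece.  Where the data forces a kink (an interval of zero
    yield following positive yield) the derivative jumps, which is the
    curve's true behaviour, not an artifact.
    """

    source = "empirical-spline"

    def __init__(self, points: AbcPoints) -> None:
        t = np.concatenate([[0.0], points.efforts])
        z = np.concatenate([[0.0], points.yields])
        bx, bg = self._build(t, z)
        self._bx = bx
        self._bg = bg
        widths = np.diff(bx)
        self._by = np.concatenate([[0.0], np.cumsum(0.5 * (bg[1:] + bg[:-1]) * widths)])
        self._by[-1] = 1.0
        self.points = points
        self.knots = (points.efforts.copy(), points.yields.copy())

    @staticmethod
    def _build(t: np.ndarray, z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        s = np.diff(z) / np.diff(t)  # secant slopes, non-increasing for sorted data
        m = len(s)
        d = np.empty(m + 1)
        if m == 1:
            d[:] = s[0]
        else:
            d[1:m] = 0.5 * (s[:-1] + s[1:])
            # clip interior slopes into the adjacent-secant bracket (fp guard)
            d[1:m] = np.minimum(np.maximum(d[1:m], s[1:]), s[:-1])
            d[0] = 2.0 * s[0] - d[1]
            d[m] = max(2.0 * s[-1] - d[m - 1], 0.0)
        bx = [t[0]]
        bg = [d[0]]
        for i in range(m):
            h = t[i + 1] - t[i]
            dl = max(d[i], s[i])
            dr = min(d[i + 1], s[i])
            mid = 0.5 * (dl + dr)
            if abs(mid - s[i]) <= 1e-13 * max(1.0, abs(s[i])) or dl - dr <= 1e-13:
                pass  # one quadratic piece suffices
            elif mid > s[i]:
                # split: quadratic then linear at slope dr
                alpha = 2.0 * h * (s[i] - dr) / (dl - dr)
                bx.append(t[i] + alpha)
                bg.append(dr)
            else:
                # split: linear at slope dl then quadratic
                alpha = 2.0 * h * (dl - s[i]) / (dl - dr)
                bx.append(t[i + 1] - alpha)
                bg.append(dl)
            bx.append(t[i + 1])
            bg.append(d[i + 1])
        return np.asarray(bx), np.asarray(bg)

    def _segment(self, p: np.ndarray):
        j = np.clip(np.searchsorted(self._bx, p, side="right") - 1, 0, len(self._bx) - 2)
        h = self._bx[j + 1] - self._bx[j]
        xi = p - self._bx[j]
        return j, h, xi

    def _evaluate(self, p: np.ndarray) -> np.ndarray:
        j, h, xi = self._segment(p)
        g0, g1 = self._bg[j], self._bg[j + 1]
        with np.errstate(divide="ignore", invalid="ignore"):
            quad = 0.5 * (g1 - g0) * xi**2 / h
        quad = np.where(h > 0, quad, 0.0)
        return self._by[j] + g0 * xi + quad

    def _derivative(self, p: np.ndarray) -> np.ndarray:
        j, h, xi = self._segment(p)
        g0, g1 = self._bg[j], self._bg[j + 1]
        with np.errstate(divide="ignore", invalid="ignore"):
            lin = (g1 - g0) * xi / h
        return g0 + np.where(h > 0, lin, 0.0)


def fit_curve(points: AbcPoints) -> QuadraticSplineCurve:
    """Interpolate discrete ABC points with the shape-preserving spline.

    Requires at least 3 points; with fewer, interpolation between effort
    fractions is undefined and callers should work with the raw points.
    """
    if points.n < 3:
        raise DataValidationError(
            f"curve fitting needs at least 3 points, got {points.n}: "
            "interpolation is undefined"
        )
    return QuadraticSplineCurve(points)


def profit_gain(curve: AbcCurve, p) -> float | np.ndarray:
    """Slope dY/dE of the ABC curve at effort p (the marginal yield)."""
    return curve.derivative(p)


@dataclass(frozen=True)
class _ReferencePair:
    identity: AbcCurve
    uniform_in_range: AbcCurve
    collapsed: bool = field(default=False)

    def __iter__(self):
        return iter((self.identity, self.uniform_in_range))


def identity_curve() -> ClosedFormCurve:
    """The diagonal ABC(p) = p of the equality distribution (all x_i equal)."""
    return ClosedFormCurve(lambda p: p, lambda p: np.ones_like(p), source="reference", name="identity")


def uniform_abc_curve(a: float, b: float, source: str = "closed-form") -> ClosedFormCurve:
    """Closed-form ABC curve of Uniform[a, a+b]: ((a+b)p - b p^2/2) / (a + b/2)."""
    if b <= 0:
        raise DataValidationError("uniform width b must be positive")
    if a < 0:
        raise DataValidationError("uniform lower bound a must be non-negative")
    mean = a + 0.5 * b

    def fn(p):
        return ((a + b) * p - 0.5 * b * p**2) / mean

    def dfn(p):
        return ((a + b) - b * p) / mean

    return ClosedFormCurve(fn, dfn, source=source, name=f"uniform[{a},{a + b}]")


def reference_curves(values: Sequence[float] | np.ndarray) -> _ReferencePair:
    """Identity and uniform-in-data-range reference curves for a data vector.

    When the data range collapses (max == min) the uniform reference equals
    the identity; the returned pair is flagged via ``collapsed``.
    """
    x = validate_values(values)
    ident = identity_curve()
    lo, hi = float(np.min(x)), float(np.max(x))
    if hi == lo:
        return _ReferencePair(ident, identity_curve(), collapsed=True)
    uni = uniform_abc_curve(lo, hi - lo, source="reference")
    return _ReferencePair(ident, uni, collapsed=False)
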