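"""Set limits on ABC curves and the A/B/C partition.

Three characteristic points define the limits:

* the **Pareto point** A(Ax, Ay): the curve point with the smallest Euclidean
  distance to the ideal of zero effort and full yield, (0, 1);
* the **BreakEven point** B(Bx, By): where the profit gain dABC crosses 1,
  i.e. the marginal yield stops exceeding the marginal effort;
* the **SubMarginal point** C(Cx, Cy): the curve point closest to (Bx, 1),
  the ideal of full yield at the break-even effort.

The A/B limit is t_AB = min(Ax, Bx); when Ax > Bx the two points exchange
roles (the swap rule), which guarantees a profit gain >= 1 throughout set A.
The B/C limit is t_BC = Cx, with the SubMarginal search anchored at
max(Ax, Bx) so that t_AB <= t_BC always holds.

Distance choice: minimizing the Euclidean distance distE = sqrt(E^2 +
(1-ABC)^2) puts the A-limit where the profit gain is ~1.18 on the uniform
curve.  The Manhattan alternative distM = E + (1 - ABC) is *not* exposed: its
minimum sits exactly at profit gain 1, so set A would not contain gains
strictly above 1 and the A/B limit would collapse onto the BreakEven point.

For analytic curves the optimizers run a dense grid scan (step 1e-4) with
golden-section refinement.  For curves fitted to empirical data the
candidates are restricted to the n realizable curve points (E_i, Y_i):
between-knot efforts do not correspond to any selectable subset of items, and
set membership is decided by rank.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Callable, NamedTuple, Sequence

import numpy as np

from .curves import AbcCurve, AbcPoints, compute_abc_points, fit_curve, validate_values

__all__ = [
    "CurvePoint",
    "Limits",
    "AbcPartition",
    "find_pareto_point",
    "find_break_even",
    "find_submarginal",
    "compute_limits",
    "assign_sets",
    "abc_analysis",
    "AbcResult",
]

_GRID_STEP = 1e-4
_REFINE_TOL = 1e-9
_SLOPE_TOL = 1e-6


@dataclass(frozen=True)
class CurvePoint:
    """A point on an ABC curve: effort (x), yield (y) and profit gain there."""

    effort: float
    yield_: float
    gain: float
    degenerate: bool = False


@dataclass(frozen=True)
class Limits:
    """The three characteristic points and the derived set thresholds."""

    pareto: CurvePoint
    break_even: CurvePoint
    submarginal: CurvePoint
    t_ab: float
    t_bc: float
    swapped: bool
    degenerate: bool = False


@dataclass(frozen=True)
class AbcPartition:
    """Assignment of every input item to exactly one of the sets A, B, C."""

    a_indices: np.ndarray
    b_indices: np.ndarray
    c_indices: np.ndarray
    counts: dict[str, int]
    yield_shares: dict[str, float]

    def labels(self, n: int | None = None) -> np.ndarray:
        """Per-item labels 'A'/'B'/'C' in original input order."""
        if n is None:
            n = sum(self.counts.values())
        out = np.empty(n, dtype="<U1")
        out[self.a_indices] = "A"
        out[self.b_indices] = "B"
        out[self.c_indices] = "C"
        return out


class AbcResult(NamedTuple):
    points: AbcPoints
    curve: AbcCurve
    limits: Limits
    partition: AbcPartition


def _golden_min(f: Callable[[float], float], a: float, b: float, tol: float = _REFINE_TOL) -> float:
    """Deterministic golden-section minimizer on [a, b]."""
    gr = (math.sqrt(5.0) - 1.0) / 2.0
    c = b - gr * (b - a)
    d = a + gr * (b - a)
    fc, fd = f(c), f(d)
    while b - a > tol:
        if fc < fd:
            b, d, fd = d, c, fc
            c = b - gr * (b - a)
            fc = f(c)
        else:
            a, c, fc = c, d, fd
            d = a + gr * (b - a)
            fd = f(d)
    return 0.5 * (a + b)


def _point_at(curve: AbcCurve, p: float, degenerate: bool = False) -> CurvePoint:
    return CurvePoint(
        effort=float(p),
        yield_=float(curve.evaluate(p)),
        gain=float(curve.derivative(p)),
        degenerate=degenerate,
    )


def _min_distance_effort(curve: AbcCurve, anchor: float, lower: float) -> float:
    """Effort minimizing the Euclidean distance to the ideal point (anchor, 1).

    Searches p in [lower, 1].  Analytic curves: dense grid + golden-section
    refinement.  Empirical curves: exhaustive scan over the realizable knots.
    """
    if curve.knots is not None:
        e, y = curve.knots
        mask = e >= lower - 1e-12
        e, y = e[mask], y[mask]
        d2 = (e - anchor) ** 2 + (1.0 - y) ** 2
        return float(e[int(np.argmin(d2))])
    grid = np.linspace(lower, 1.0, max(int(round((1.0 - lower) / _GRID_STEP)), 2) + 1)
    vals = curve.evaluate(grid)
    d2 = (grid - anchor) ** 2 + (1.0 - vals) ** 2
    i = int(np.argmin(d2))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, len(grid) - 1)]

    def f(p: float) -> float:
        return (p - anchor) ** 2 + (1.0 - curve.evaluate(p)) ** 2

    return _golden_min(f, float(lo), float(hi))


def find_pareto_point(curve: AbcCurve) -> CurvePoint:
    """Curve point with the smallest Euclidean distance to the ideal (0, 1)."""
    p = _min_distance_effort(curve, anchor=0.0, lower=0.0)
    return _point_at(curve, p)


def find_break_even(curve: AbcCurve) -> CurvePoint:
    """Curve point where the profit gain dABC crosses 1.

    The derivative of a concave ABC curve is non-increasing, so the crossing
    is located by bisection.  Conventions for degenerate slopes: if the gain
    exceeds 1 everywhere the point sits at effort 1; if it is below 1
    everywhere, at effort 0; if the gain is identically 1 on an interval
    (equality-like data) the interval's left endpoint is returned and the
    point is flagged degenerate.
    """
    g0 = float(curve.derivative(0.0))
    g1 = float(curve.derivative(1.0))
    if g0 <= 1.0 + _SLOPE_TOL and g1 >= 1.0 - _SLOPE_TOL:
        # gain ~ 1 everywhere: equality-like plateau, left endpoint by convention
        return _point_at(curve, 0.0, degenerate=True)
    if g1 >= 1.0 - _SLOPE_TOL:
        return _point_at(curve, 1.0, degenerate=True)
    if g0 <= 1.0 + _SLOPE_TOL:
        return _point_at(curve, 0.0, degenerate=True)
    lo, hi = 0.0, 1.0
    while hi - lo > 1e-9:
        mid = 0.5 * (lo + hi)
        if float(curve.derivative(mid)) > 1.0:
            lo = mid
        else:
            hi = mid
    return _point_at(curve, 0.5 * (lo + hi))


def find_submarginal(curve: AbcCurve, break_even: CurvePoint) -> CurvePoint:
    """Curve point closest to (Bx, 1): full yield at the break-even effort."""
    bx = break_even.effort
    p = _min_distance_effort(curve, anchor=bx, lower=bx)
    return _point_at(curve, p, degenerate=break_even.degenerate)


def compute_limits(curve: AbcCurve) -> Limits:
    """Compute the three characteristic points and thresholds, with swap rule.

    When Ax > Bx the Pareto and BreakEven points exchange roles: t_AB becomes
    the smaller effort (keeping the profit gain >= 1 within set A) and the
    SubMarginal search is anchored at the larger one, preserving
    t_AB <= t_BC.
    """
    pareto = find_pareto_point(curve)
    break_even = find_break_even(curve)
    swapped = pareto.effort > break_even.effort
    t_ab = min(pareto.effort, break_even.effort)
    anchor = replace(
        break_even if not swapped else pareto,
        degenerate=break_even.degenerate,
    )
    submarginal = find_submarginal(curve, anchor)
    t_bc = max(submarginal.effort, t_ab)
    return Limits(
        pareto=pareto,
        break_even=break_even,
        submarginal=submarginal,
        t_ab=float(t_ab),
        t_bc=float(t_bc),
        swapped=bool(swapped),
        degenerate=break_even.degenerate,
    )


def assign_sets(values: Sequence[float] | np.ndarray, limits: Limits) -> AbcPartition:
    """Partition items into A, B, C by rank against the effort thresholds.

    After the stable decreasing sort, the item of rank i (1-based) belongs to
    A iff i <= floor(n * t_AB + 1e-9), to C iff i > floor(n * t_BC + 1e-9),
    and to B otherwise.  Membership is decided by rank, not value: tied
    values may straddle a boundary, but every index lands in exactly one set.
    Indices are reported in original input positions.
    """
    x = validate_values(values)
    n = x.size
    order = np.argsort(-x, kind="stable")
    n_a = int(math.floor(n * limits.t_ab + 1e-9))
    n_ab = int(math.floor(n * limits.t_bc + 1e-9))
    n_a = min(n_a, n)
    n_ab = min(max(n_ab, n_a), n)
    a_idx = np.sort(order[:n_a])
    b_idx = np.sort(order[n_a:n_ab])
    c_idx = np.sort(order[n_ab:])
    total = x.sum()
    shares = {
        "A": float(x[a_idx].sum() / total),
        "B": float(x[b_idx].sum() / total),
        "C": float(x[c_idx].sum() / total),
    }
    counts = {"A": len(a_idx), "B": len(b_idx), "C": len(c_idx)}
    return AbcPartition(a_idx, b_idx, c_idx, counts, shares)


def abc_analysis(values: Sequence[float] | np.ndarray) -> AbcResult:
    """One-call pipeline: points -> spline curve -> limits -> partition."""
    points = compute_abc_points(values)
    curve = fit_curve(points)
    limits = compute_limits(curve)
    partition = assign_sets(values, limits)
    return AbcResult(points, curve, limits, partition)
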