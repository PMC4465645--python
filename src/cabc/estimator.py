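"""Scikit-learn style estimator facade for the computed ABC analysis."""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from .errors import DataValidationError
from .io import preprocess
from .limits import abc_analysis

__all__ = ["ABCAnalyzer"]


class ABCAnalyzer(BaseEstimator):
    """Partition non-negative values into the sets A, B and C.

    The analyzer sorts the values decreasingly, interpolates the cumulative
    effort-yield curve with a shape-preserving quadratic spline, locates the
    Pareto, BreakEven and SubMarginal points, and assigns every item to set A
    (the "important few", profit gain >= 1), B (proportional middle) or C
    (the "trivial many").

    Parameters
    ----------
    unit_variance : bool, default=False
        Scale the values to unit variance before the analysis.  This is the
        only admissible standardization: ABC curves are scale invariant (the
        partition is unchanged) but not location invariant, so centering is
        never applied.

    Attributes
    ----------
    points_ : AbcPoints
        Discrete effort/yield pairs of the fitted data.
    curve_ : QuadraticSplineCurve
        The interpolated ABC curve.
    limits_ : Limits
        Characteristic points, thresholds t_AB / t_BC and the swap flag.
    partition_ : AbcPartition
        Index sets A, B, C with counts and yield shares.
    labels_ : ndarray of shape (n_samples,)
        Per-item set label 'A', 'B' or 'C' in input order.

    Examples
    --------
    >>> import numpy as np
    >>> from cabc import ABCAnalyzer
    >>> eig = [3.834, 1.142, 1.061, 0.740, 0.491, 0.432, 0.208, 0.092]
    >>> ABCAnalyzer().fit_predict(eig)
    array(['A', 'A', 'B', 'B', 'C', 'C', 'C', 'C'], dtype='<U1')
    """

    def __init__(self, unit_variance: bool = False) -> None:
        self.unit_variance = unit_variance

    def _validate(self, X) -> np.ndarray:
        x = np.asarray(X, dtype=float)
        if x.ndim == 2 and x.shape[1] == 1:
            x = x.ravel()
        if x.ndim != 1:
            raise DataValidationError(
                "ABCAnalyzer expects a 1-D value vector (or a single column)"
            )
        return x

    def fit(self, X, y=None) -> "ABCAnalyzer":
        """Run the full ABC analysis on a vector of non-negative values."""
        x = self._validate(X)
        if self.unit_variance:
            x = preprocess(x, unit_variance=True)
        points, curve, limits, partition = abc_analysis(x)
        self.values_ = x
        self.points_ = points
        self.curve_ = curve
        self.limits_ = limits
        self.partition_ = partition
        self.labels_ = partition.labels(x.size)
        self.n_samples_ = int(x.size)
        return self

    def fit_predict(self, X, y=None) -> np.ndarray:
        """Fit and return the per-item set labels."""
        return self.fit(X).labels_

    def predict(self, X) -> np.ndarray:
        """Assign new values to the fitted sets by value thresholds.

        A new value joins set A if it is at least the smallest fitted A
        member, set B if at least the smallest fitted B member, and set C
        otherwise.  (On the fitted data itself membership is decided by rank,
        so tied boundary values may differ between ``labels_`` and
        ``predict``.)
        """
        if not hasattr(self, "partition_"):
            raise DataValidationError("this ABCAnalyzer instance is not fitted yet")
        x = self._validate(X)
        part = self.partition_
        vals = self.values_
        a_min = vals[part.a_indices].min() if part.counts["A"] else np.inf
        b_min = vals[part.b_indices].min() if part.counts["B"] else a_min
        out = np.full(x.size, "C", dtype="<U1")
        out[x >= b_min] = "B"
        out[x >= a_min] = "A"
        return out
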