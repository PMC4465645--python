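"""ABC analysis applied to principal-component retention.

The eigenvalues of a covariance or correlation matrix are non-negative and
typically right-skewed: a few components carry most of the variance.  Running
the computed ABC analysis on the eigenvalue spectrum gives an objective
retention rule — keep the components in sets A and B (the "important few"
plus the proportional middle) and drop set C (the "trivial many") — as a
replacement for the subjective scree/elbow inspection and for the
Kaiser-Guttman rule (retain eigenvalues strictly greater than 1), which is
reported alongside for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import DataValidationError
from .limits import AbcPartition, abc_analysis

__all__ = ["ComponentSelection", "select_components", "eigenvalues_from_matrix"]


@dataclass(frozen=True)
class ComponentSelection:
    """Retention decision for a PCA eigenvalue spectrum.

    Indices refer to the eigenvalues sorted in decreasing order; both retained
    sets are prefixes of that order.
    """

    eigenvalues: np.ndarray
    retained_abc: np.ndarray
    retained_kaiser: np.ndarray
    cumulative_variance_abc: float
    cumulative_variance_kaiser: float
    partition: AbcPartition


def eigenvalues_from_matrix(matrix: np.ndarray) -> np.ndarray:
    """Eigenvalues (decreasing) of a symmetric covariance/correlation matrix.

    The matrix is decomposed as given — no centering or scaling is applied.
    Tiny negative eigenvalues from floating-point round-off are clipped to
    zero; genuinely negative spectra are rejected.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise DataValidationError(f"expected a square matrix, got shape {m.shape}")
    if not np.allclose(m, m.T, atol=1e-8):
        raise DataValidationError("matrix must be symmetric")
    eig = np.linalg.eigvalsh(m)[::-1]
    floor = -1e-10 * max(1.0, float(np.abs(eig).max()))
    if np.any(eig < floor):
        raise DataValidationError("matrix is not positive semi-definite")
    return np.clip(eig, 0.0, None)


def select_components(eigenvalues: Sequence[float] | np.ndarray) -> ComponentSelection:
    """Partition an eigenvalue spectrum and derive both retention rules.

    Runs the full ABC analysis on the eigenvalues (sorted decreasingly);
    ``retained_abc`` is the union of sets A and B, ``retained_kaiser`` the
    components with eigenvalue > 1.  Cumulative explained variance is
    computed from the eigenvalues themselves, as a percentage of their sum.
    """
    eig = np.sort(np.asarray(eigenvalues, dtype=float))[::-1]
    if eig.size < 3:
        raise DataValidationError("need at least 3 eigenvalues")
    result = abc_analysis(eig)
    part = result.partition
    n_ab = part.counts["A"] + part.counts["B"]
    retained_abc = np.arange(n_ab)
    retained_kaiser = np.flatnonzero(eig > 1.0)
    total = eig.sum()
    cum_abc = 100.0 * eig[:n_ab].sum() / total
    cum_kaiser = 100.0 * eig[retained_kaiser].sum() / total
    return ComponentSelection(
        eigenvalues=eig,
        retained_abc=retained_abc,
        retained_kaiser=retained_kaiser,
        cumulative_variance_abc=float(cum_abc),
        cumulative_variance_kaiser=float(cum_kaiser),
        partition=part,
    )
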