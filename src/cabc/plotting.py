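"""ABC plot: curve, reference curves, characteristic points and set limits."""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import numpy as np

from .curves import AbcCurve, AbcPoints, reference_curves
from .limits import Limits

__all__ = ["plot_abc"]


def plot_abc(
    points: AbcPoints,
    curve: AbcCurve,
    limits: Limits,
    path: str | Path,
    references: Optional[tuple[AbcCurve, AbcCurve]] = None,
    values: Optional[np.ndarray] = None,
    title: str = "ABC analysis",
) -> Path:
    """Render the unit-square ABC plot to a PNG/SVG file.

    Shows the fitted ABC curve with its data points, the identity and
    uniform-in-data-range references, the anti-diagonal Y = 1 - E (where the
    yield equals the remaining effort), the Pareto / BreakEven / SubMarginal
    points, and vertical red lines at the set limits t_AB and t_BC.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    grid = np.linspace(0.0, 1.0, 513)
    fig, ax = plt.subplots(figsize=(5.5, 5.5))
    ax.plot(grid, curve.evaluate(grid), color="tab:blue", lw=2, label="ABC curve")
    ax.plot(points.efforts, points.yields, "o", color="tab:blue", ms=4)
    if references is None and values is not None:
        references = tuple(reference_curves(values))
    if references is not None:
        ident, uni = references
        ax.plot(grid, ident.evaluate(grid), color="magenta", lw=1, label="identity")
        ax.plot(grid, uni.evaluate(grid), color="green", lw=1, label="uniform in range")
    ax.plot([0, 1], [1, 0], ls="--", color="gray", lw=0.8, label="Y = 1 - E")
    for pt, marker, color, name in (
        (limits.pareto, "*", "red", "Pareto A"),
        (limits.break_even, "*", "green", "BreakEven B"),
        (limits.submarginal, "*", "blue", "SubMarginal C"),
    ):
        ax.plot(pt.effort, pt.yield_, marker, color=color, ms=12, label=name)
    for t in (limits.t_ab, limits.t_bc):
        ax.axvline(t, color="red", lw=1)
    ax.set_xlim(0, 1)
    ax.set_ylim(0, 1.02)
    ax.set_xlabel("effort E (fraction of items)")
    ax.set_ylabel("yield Y (fraction of total)")
    ax.set_title(title)
    ax.legend(loc="lower right", fontsize=8)
    path = Path(path)
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    return path
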