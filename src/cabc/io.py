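"""File input, preprocessing and the serializable analysis report.

Fractions are kept in [0, 1] throughout; percentages appear only at the
presentation layer (CLI text output), so effort/yield units cannot be mixed.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from . import __version__
from .curves import validate_values
from .errors import DataValidationError
from .limits import AbcResult, CurvePoint

__all__ = ["read_values", "preprocess", "AnalysisReport", "build_report"]


def read_values(
    path: str | Path,
    column: Optional[str | int] = None,
    sep: Optional[str] = None,
) -> np.ndarray:
    """Read one numeric column from a CSV/TSV file.

    The dialect is sniffed unless ``sep`` is given; a header row is detected
    by attempting to parse the first line as numbers.  ``column`` selects by
    header name or 0-based position and defaults to the first numeric column.
    Empty or non-numeric cells are rejected with their row numbers; negative
    values are rejected with their (1-based) data row.
    """
    path = Path(path)
    if not path.exists():
        raise DataValidationError(f"no such file: {path}")
    with open(path) as fh:
        first_line = fh.readline().strip()
    if not first_line:
        raise DataValidationError(f"empty file: {path}")
    if sep is None:
        sep = next((c for c in ("\t", ";", ",") if c in first_line), ",")

    def _is_number(token: str) -> bool:
        try:
            float(token)
            return True
        except ValueError:
            return False

    has_header = not all(_is_number(tok) for tok in first_line.split(sep) if tok != "")
    try:
        frame = pd.read_csv(path, header=0 if has_header else None, sep=sep)
    except Exception as exc:
        raise DataValidationError(f"cannot parse {path}: {exc}") from None
    if column is None:
        numeric = [c for c in frame.columns if pd.api.types.is_numeric_dtype(frame[c])]
        if not numeric:
            # a column that is all-NaN or mixed: try coercing each in turn
            raise DataValidationError(f"no numeric column found in {path}")
        col = numeric[0]
    elif isinstance(column, int) and column not in frame.columns:
        if column >= frame.shape[1]:
            raise DataValidationError(f"column index {column} out of range")
        col = frame.columns[column]
    else:
        if column not in frame.columns:
            raise DataValidationError(f"no column named '{column}' in {path}")
        col = column
    series = pd.to_numeric(frame[col], errors="coerce")
    bad = series.index[series.isna()]
    if len(bad):
        rows = ", ".join(str(int(r) + 1) for r in bad[:5])
        raise DataValidationError(
            f"non-numeric or empty cell(s) in column '{col}' at data row(s) {rows}"
        )
    values = series.to_numpy(dtype=float)
    if np.any(values < 0):
        k = int(np.flatnonzero(values < 0)[0])
        raise DataValidationError(f"negative value at row {k + 1}")
    return values


def preprocess(
    values: Sequence[float] | np.ndarray, unit_variance: bool = False
) -> np.ndarray:
    """Optionally scale the data to unit variance (no centering).

    ABC curves are scale invariant, so this mapping never changes the
    partition; it only normalizes reported magnitudes.  Centering is not
    offered: ABC curves are not location invariant and subtracting the mean
    would distort (or invalidate, via negative values) the analysis.
    """
    x = validate_values(values)
    if not unit_variance:
        return x
    sd = float(np.std(x, ddof=1)) if x.size > 1 else 0.0
    if sd == 0.0:
        raise DataValidationError("cannot scale to unit variance: variance is zero")
    return x / sd


class PointReport(BaseModel):
    model_config = ConfigDict(populate_by_name=True)
    effort: float
    yield_: float = Field(alias="yield")
    gain: float
    degenerate: bool = False

    @classmethod
    def from_point(cls, pt: CurvePoint) -> "PointReport":
        return cls(effort=pt.effort, yield_=pt.yield_, gain=pt.gain, degenerate=pt.degenerate)


class SetReport(BaseModel):
    label: str
    indices: list[int]
    count: int
    yield_share: float


class LimitsReport(BaseModel):
    t_ab: float
    t_bc: float
    swapped: bool
    degenerate: bool
    pareto: PointReport
    break_even: PointReport
    submarginal: PointReport


class InputSummary(BaseModel):
    n: int
    n_zeros: int
    preprocessing: str  # "none" or "unit-variance"


class Provenance(BaseModel):
    seed: Optional[int] = None
    config_hash: str
    version: str


class AnalysisReport(BaseModel):
    """Lossless, machine-readable record of one ABC analysis."""

    input: InputSummary
    limits: LimitsReport
    sets: list[SetReport]
    provenance: Provenance

    def to_json(self) -> str:
        return self.model_dump_json(by_alias=True, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "AnalysisReport":
        return cls.model_validate_json(text)


def _config_hash(payload: dict) -> str:
    canonical = json.dumps(payload, sort_keys=True, separators=(",", ":"))
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def build_report(
    values: np.ndarray,
    result: AbcResult,
    seed: Optional[int] = None,
    preprocessing: str = "none",
) -> AnalysisReport:
    """Assemble the serializable report from a finished analysis."""
    x = np.asarray(values, dtype=float)
    limits = result.limits
    part = result.partition
    sets = [
        SetReport(
            label=label,
            indices=[int(i) for i in idx],
            count=part.counts[label],
            yield_share=part.yield_shares[label],
        )
        for label, idx in (
            ("A", part.a_indices),
            ("B", part.b_indices),
            ("C", part.c_indices),
        )
    ]
    prov = Provenance(
        seed=seed,
        config_hash=_config_hash(
            {"n": int(x.size), "preprocessing": preprocessing, "seed": seed}
        ),
        version=__version__,
    )
    return AnalysisReport(
        input=InputSummary(
            n=int(x.size),
            n_zeros=int(np.count_nonzero(x == 0)),
            preprocessing=preprocessing,
        ),
        limits=LimitsReport(
            t_ab=limits.t_ab,
            t_bc=limits.t_bc,
            swapped=limits.swapped,
            degenerate=limits.degenerate,
            pareto=PointReport.from_point(limits.pareto),
            break_even=PointReport.from_point(limits.break_even),
            submarginal=PointReport.from_point(limits.submarginal),
        ),
        sets=sets,
        provenance=prov,
    )
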