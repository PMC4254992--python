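"""Monthly order statistics on captured lengths and their annual summaries.

Two monthly statistics are computed from each month's catch sample: the
median length (mm) and F40, the percentage of individuals with length
strictly below 40 mm.  Each is summarised over a calendar year by its
minimum, maximum and span (max - min), giving six candidate annual
recruitment indices.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "F40_CUTOFF_MM",
    "MonthlyIndices",
    "AnnualIndexRecord",
    "monthly_indices",
    "annual_summary",
]

F40_CUTOFF_MM = 40.0


@dataclass(frozen=True)
class MonthlyIndices:
    """Median length (mm) and F40 (%) of one month's catch sample of size ``n``.

    An empty sample yields ``n = 0`` with NaN statistics ("missing month").
    """

    median_mm: float
    f40_pct: float
    n: int

    @property
    def is_missing(self) -> bool:
        return self.n == 0


@dataclass(frozen=True)
class AnnualIndexRecord:
    """True recruits plus the six candidate annual indices for one year."""

    year: int
    recruits: int
    median_min_mm: float
    median_max_mm: float
    median_span_mm: float
    f40_min_pct: float
    f40_max_pct: float
    f40_span_pct: float


def monthly_indices(lengths) -> MonthlyIndices:
    """Median (midpoint convention for even n) and strict-cutoff F40 of a sample."""
    arr = np.asarray(lengths, dtype=np.float64)
    if arr.size == 0:
        return MonthlyIndices(math.nan, math.nan, 0)
    median = float(np.median(arr))
    f40 = 100.0 * float(np.count_nonzero(arr < F40_CUTOFF_MM)) / arr.size
    return MonthlyIndices(median, f40, int(arr.size))


def annual_summary(
    monthly: Sequence[MonthlyIndices], year: int, recruits: int
) -> AnnualIndexRecord:
    """Min / max / span of the year's non-missing monthly medians and F40 values."""
    medians = [m.median_mm for m in monthly if not m.is_missing]
    f40s = [m.f40_pct for m in monthly if not m.is_missing]
    if not medians:
        raise ValueError(f"year {year}: no non-missing monthly samples")
    med_min, med_max = min(medians), max(medians)
    f40_min, f40_max = min(f40s), max(f40s)
    return AnnualIndexRecord(
        year=year,
        recruits=int(recruits),
        median_min_mm=med_min,
        median_max_mm=med_max,
        median_span_mm=med_max - med_min,
        f40_min_pct=f40_min,
        f40_max_pct=f40_max,
        f40_span_pct=f40_max - f40_min,
    )
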