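"""Quantitative selection among the six candidate annual recruitment indices.

Two criteria guide the choice of an index: (a) it should be monotonically
related to absolute recruitment — otherwise a single-variable regression
cannot recover recruitment from it — and (b) the index-to-recruitment
relationship should stay stable across all levels of recruitment
variability, because real-world variability is unknown.

This module encodes those criteria as three scores computed from a
campaign table (final-year rows, all Rvar levels pooled unless noted):

* ``monotonicity`` — Spearman rank correlation between recruitment-decile
  bin means of the index and the bin order (signed; strength is its
  absolute value, so an index that decreases cleanly with recruitment is
  as monotone as one that increases).
* ``spread`` — mean within-bin standard deviation of the index, normalised
  by the index's overall range (0 = perfectly tight relationship).
* ``stability`` — mean coefficient of variation of the per-Rvar power-law
  coefficients (beta0, beta1) across levels.

Ranking is lexicographic: monotone strength (descending), then spread,
then stability, with an alphabetical tie-break.  The scoring formulas are
a formalisation of what is otherwise a visual assessment; only the
resulting ordering is meaningful, not the score magnitudes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .regression import fit_power_law

__all__ = ["INDEX_COLUMNS", "IndexScore", "score_index", "rank_indices", "score_all"]

#: candidate index name -> campaign-table column
INDEX_COLUMNS = {
    "median_min": "median_min_mm",
    "median_max": "median_max_mm",
    "median_span": "median_span_mm",
    "f40_min": "f40_min_pct",
    "f40_max": "f40_max_pct",
    "f40_span": "f40_span_pct",
}


@dataclass(frozen=True)
class IndexScore:
    index_name: str
    monotonicity: float  # signed Spearman rho, in [-1, 1]
    spread: float
    stability: float


def _cv(values: np.ndarray) -> float:
    mean = np.mean(values)
    sd = np.std(values, ddof=1)
    if sd == 0:
        return 0.0
    if abs(mean) < 1e-12:
        return np.inf
    return float(sd / abs(mean))


def score_index(df: pd.DataFrame, index_name: str, n_bins: int = 10) -> IndexScore:
    """Score one candidate index from a campaign table (needs >= 2 Rvar levels)."""
    if index_name not in INDEX_COLUMNS:
        raise ValueError(f"unknown index {index_name!r}; expected one of {sorted(INDEX_COLUMNS)}")
    col = INDEX_COLUMNS[index_name]
    levels = df["rvar_pct"].unique()
    if levels.size < 2:
        raise ValueError("need campaign rows from at least 2 Rvar levels")
    final_year = int(df["year"].max())
    d = df[df["year"] == final_year]
    if d.shape[0] < 2 * n_bins:
        raise ValueError("insufficient final-year rows for decile binning")

    bins = pd.qcut(d["recruits"], n_bins, labels=False, duplicates="drop")
    grouped = d.groupby(bins)[col]
    bin_means = grouped.mean().to_numpy()
    rho = spearmanr(np.arange(bin_means.size), bin_means).statistic
    index_range = float(d[col].max() - d[col].min())
    spread = 0.0 if index_range == 0 else float(grouped.std(ddof=1).mean() / index_range)

    b0s, b1s = [], []
    for rv in sorted(levels):
        sub = d[d["rvar_pct"] == rv]
        ok = (sub["recruits"] > 0) & (sub[col] > 0)
        try:
            fit = fit_power_law(sub.loc[ok, "recruits"].to_numpy(),
                                sub.loc[ok, col].to_numpy())
        except ValueError:
            continue  # level unusable for a log-log fit (e.g. zero-heavy index)
        b0s.append(fit.beta0)
        b1s.append(fit.beta1)
    if len(b0s) >= 2:
        stability = 0.5 * (_cv(np.array(b0s)) + _cv(np.array(b1s)))
    else:
        stability = np.inf  # relationship not even fittable across levels
    return IndexScore(index_name, float(rho), spread, stability)


def rank_indices(scores: Sequence[IndexScore]) -> list[IndexScore]:
    """Order scores best-first: |monotonicity| desc, spread asc, stability asc, name."""
    if len(scores) < 2:
        raise ValueError("need at least 2 scores to rank")
    return sorted(
        scores,
        key=lambda s: (-abs(s.monotonicity), s.spread, s.stability, s.index_name),
    )


def score_all(df: pd.DataFrame, n_bins: int = 10) -> pd.DataFrame:
    """Score and rank all six candidates; returns a table with a ``rank`` column."""
    scores = [score_index(df, name, n_bins=n_bins) for name in INDEX_COLUMNS]
    ranked = rank_indices(scores)
    return pd.DataFrame(
        {
            "index_name": [s.index_name for s in ranked],
            "monotonicity": [s.monotonicity for s in ranked],
            "spread": [s.spread for s in ranked],
            "stability": [s.stability for s in ranked],
            "rank": np.arange(1, len(ranked) + 1),
        }
    )
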