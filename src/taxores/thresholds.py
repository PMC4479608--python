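"""Category-wise similarity distributions, best thresholds and accuracy.

Given one percent-identity value per sequence pair and the pair's
taxonomic category (S/G/F/O/I), this module computes:

* cumulative frequency curves of each category — the *positive* curve of a
  category at threshold *t* is the fraction of its values >= t, the
  *negative* curve the fraction <= t (ties count on both sides by default);
* the *best threshold* between two adjacent ranks (Lefébure's method): the
  similarity at which the finer category's positive curve crosses the
  coarser category's negative curve, read by linear interpolation on a
  0.1% grid; the common curve value at the crossing is the success rate;
* the probabilistic accuracy of classifying a query at each rank given a
  hit with similarity S >= n::

      OP(S>=n) = (1 - ICP)
      FP(S>=n) = (1 - ICP)(1 - OCP)
      GP(S>=n) = (1 - ICP)(1 - OCP)(1 - FCP)
      SP(S>=n) = (1 - ICP)(1 - OCP)(1 - FCP)(1 - GCP)

  where ICP/OCP/FCP/GCP are the cumulative frequencies of the I/O/F/G
  similarity distributions at S >= n;
* the *lowest similarity threshold*: the smallest n whose rank probability
  meets a pre-designated accuracy floor (default 0.95).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .taxonomy import (
    BOUNDARIES,
    CATEGORIES,
    Lineage,
    categorize_pair,
)

RANK_COLUMN = {
    "species": "SP",
    "genus": "GP",
    "family": "FP",
    "order": "OP",
}


class ThresholdError(ValueError):
    pass


@dataclass
class CategorizedSimilarities:
    """Per-category multisets of percent identities."""

    values: dict[str, np.ndarray] = field(
        default_factory=lambda: {c: np.array([]) for c in CATEGORIES}
    )

    def counts(self) -> dict[str, int]:
        return {c: int(self.values[c].size) for c in CATEGORIES}

    def summary(self) -> pd.DataFrame:
        """Five-number summary per category (boxplot companion)."""
        rows = []
        for cat in CATEGORIES:
            v = self.values[cat]
            if v.size:
                q1, med, q3 = np.percentile(v, [25, 50, 75])
                rows.append(
                    {
                        "category": cat, "n": v.size,
                        "min": v.min(), "q1": q1, "median": med,
                        "q3": q3, "max": v.max(),
                    }
                )
            else:
                rows.append(
                    {
                        "category": cat, "n": 0,
                        "min": np.nan, "q1": np.nan, "median": np.nan,
                        "q3": np.nan, "max": np.nan,
                    }
                )
        return pd.DataFrame(rows)


def categorize_similarities(
    pair_values: Mapping[tuple[str, str], float],
    lineages: Mapping[str, Lineage],
) -> CategorizedSimilarities:
    """Sort each pair's similarity into its S/G/F/O/I category.

    ``lineages`` maps record_id -> Lineage; a pair naming an unknown record
    raises.  Records with an uncertain deciding rank must have been
    filtered beforehand (:func:`taxores.taxonomy.filter_uncertain`).
    """
    buckets: dict[str, list[float]] = {c: [] for c in CATEGORIES}
    for (a, b), value in pair_values.items():
        for rid in (a, b):
            if rid not in lineages:
                raise ThresholdError(f"no lineage for record {rid!r}")
        cat = categorize_pair(lineages[a], lineages[b])
        buckets[cat].append(value)
    return CategorizedSimilarities(
        {c: np.sort(np.asarray(v, dtype=float)) for c, v in buckets.items()}
    )


@dataclass
class CumulativeCurve:
    """Positive/negative cumulative frequency curves on a threshold grid."""

    grid: np.ndarray
    positive: np.ndarray  # fraction of values >= t
    negative: np.ndarray  # fraction of values <= t

    def positive_at(self, t: float) -> float:
        return float(np.interp(t, self.grid, self.positive))


def _make_grid(lo: float, hi: float = 100.0, step: float = 0.1) -> np.ndarray:
    start = math.floor(lo)
    n = int(round((hi - start) / step))
    return np.round(start + step * np.arange(n + 1), 10)


def cumulative_curve(
    values: Iterable[float],
    grid_step: float = 0.1,
    grid: np.ndarray | None = None,
    tie_rule: str = "both",
) -> CumulativeCurve:
    """Cumulative frequency curves of a similarity multiset.

    The grid spans [floor(min), 100] at ``grid_step`` unless given
    explicitly.  ``tie_rule="both"`` counts values equal to a grid
    threshold in both curves (>= and <=); ``"strict"`` uses < in the
    negative curve instead.
    """
    v = np.sort(np.asarray(list(values), dtype=float))
    if v.size == 0:
        raise ThresholdError("empty similarity multiset")
    if grid is None:
        grid = _make_grid(float(v.min()), 100.0, grid_step)
    n = v.size
    # positive: count of values >= t;  negative: count of values <= t
    pos = (n - np.searchsorted(v, grid, side="left")) / n
    if tie_rule == "both":
        neg = np.searchsorted(v, grid, side="right") / n
    elif tie_rule == "strict":
        neg = np.searchsorted(v, grid, side="left") / n
    else:
        raise ThresholdError(f"unknown tie_rule {tie_rule!r}")
    return CumulativeCurve(grid=grid, positive=pos, negative=neg)


@dataclass
class BestThreshold:
    """Crossing of a finer category's positive and a coarser's negative curve."""

    boundary: tuple[str, str]
    threshold: float
    success_rate: float  # percent
    separated: bool = False

    @property
    def label(self) -> str:
        return f"{self.boundary[0]}/{self.boundary[1]}"

    def formatted(self) -> str:
        """Table-style "threshold/success" cell, success as integer percent."""
        return f"{self.threshold:.1f}/{round(self.success_rate)}"


def best_threshold(
    upper_values: Iterable[float],
    lower_values: Iterable[float],
    boundary: tuple[str, str] = ("S", "G"),
    grid_step: float = 0.1,
    tie_rule: str = "both",
) -> BestThreshold:
    """Best similarity threshold between two adjacent categories.

    ``upper_values`` is the finer (higher-similarity) category of the
    boundary, ``lower_values`` the coarser.  The crossing of the finer
    positive curve and the coarser negative curve is located on a shared
    grid and refined by linear interpolation; a plateau of exact equality
    yields its midpoint.  Perfectly separated distributions (the whole
    coarser category lies below the finer) give a success rate of 100 and
    ``separated=True``, with the threshold at the midpoint of the empty
    overlap interval.
    """
    up = np.asarray(list(upper_values), dtype=float)
    lo = np.asarray(list(lower_values), dtype=float)
    if up.size == 0 or lo.size == 0:
        raise ThresholdError("both categories need at least one value")
    grid = _make_grid(float(min(up.min(), lo.min())), 100.0, grid_step)
    pos = cumulative_curve(up, grid=grid, tie_rule=tie_rule).positive
    neg = cumulative_curve(lo, grid=grid, tie_rule=tie_rule).negative

    if lo.max() < up.min():
        return BestThreshold(
            boundary=boundary,
            threshold=float((lo.max() + up.min()) / 2),
            success_rate=100.0,
            separated=True,
        )

    diff = pos - neg  # decreasing from ~+1 to ~-1
    zero = np.isclose(diff, 0.0, atol=1e-12)
    if zero.any():
        idx = np.nonzero(zero)[0]
        # midpoint of the (possibly single-point) equality plateau
        t_star = float((grid[idx[0]] + grid[idx[-1]]) / 2)
        success = float(np.interp(t_star, grid, pos))
        return BestThreshold(boundary, t_star, 100.0 * success)

    sign_change = np.nonzero(np.diff(np.sign(diff)) < 0)[0]
    if sign_change.size == 0:
        raise ThresholdError(
            f"curves for boundary {boundary} never cross on the grid"
        )
    k = int(sign_change[0])
    t0, t1 = grid[k], grid[k + 1]
    d0, d1 = diff[k], diff[k + 1]
    t_star = float(t0 + (t1 - t0) * d0 / (d0 - d1))
    # interpolation can overshoot the observed values by < grid_step;
    # keep the threshold inside the union of the two observed ranges
    t_star = float(
        np.clip(t_star, min(up.min(), lo.min()), max(up.max(), lo.max()))
    )
    # common curve value at the interpolated crossing
    p0, p1 = pos[k], pos[k + 1]
    success = float(p0 + (p1 - p0) * (t_star - t0) / (t1 - t0))
    return BestThreshold(boundary, t_star, 100.0 * success)


def accuracy_table(
    categorized: CategorizedSimilarities,
    grid_step: float = 0.1,
    tie_rule: str = "both",
) -> pd.DataFrame:
    """Rank-assignment accuracy at every similarity threshold.

    Index: threshold n (shared grid over all confusable categories).
    Columns GCP/FCP/OCP/ICP are the cumulative frequencies of the G/F/O/I
    category distributions at S >= n; SP/GP/FP/OP the corresponding
    probabilities of a correct assignment at species/genus/family/order.
    """
    confusable = ["G", "F", "O", "I"]
    mins = [
        categorized.values[c].min() for c in confusable
        if categorized.values[c].size
    ]
    if not mins:
        raise ThresholdError("no confusable pairs (G/F/O/I all empty)")
    grid = _make_grid(float(min(mins)), 100.0, grid_step)
    # a category without observed pairs contributes zero confusion
    cp = {
        c: (
            cumulative_curve(
                categorized.values[c], grid=grid, tie_rule=tie_rule
            ).positive
            if categorized.values[c].size
            else np.zeros_like(grid)
        )
        for c in confusable
    }
    op = 1.0 - cp["I"]
    fp = op * (1.0 - cp["O"])
    gp = fp * (1.0 - cp["F"])
    sp = gp * (1.0 - cp["G"])
    return pd.DataFrame(
        {
            "GCP": cp["G"], "FCP": cp["F"], "OCP": cp["O"], "ICP": cp["I"],
            "SP": sp, "GP": gp, "FP": fp, "OP": op,
        },
        index=pd.Index(grid, name="n"),
    )


def lowest_threshold(
    table: pd.DataFrame,
    rank: str,
    accuracy_floor: float = 0.95,
) -> float | None:
    """Smallest similarity threshold meeting the accuracy floor at a rank.

    ``rank`` is one of species/genus/family/order.  Returns None when no
    grid threshold reaches the floor (conservative: the rank cannot be
    assigned at the demanded accuracy from similarity alone).
    """
    if rank not in RANK_COLUMN:
        raise ThresholdError(f"unknown rank {rank!r}")
    col = table[RANK_COLUMN[rank]]
    ok = col[col >= accuracy_floor]
    if ok.empty:
        return None
    return float(ok.index.min())


def best_threshold_table(
    categorized: CategorizedSimilarities,
    grid_step: float = 0.1,
    tie_rule: str = "both",
) -> pd.DataFrame:
    """Best threshold and success rate for every adjacent-rank boundary.

    Boundaries whose categories are empty (too few sampled taxa) get NaN
    rows rather than errors.
    """
    rows = []
    for upper, lower in BOUNDARIES:
        u = categorized.values[upper]
        l = categorized.values[lower]
        if u.size == 0 or l.size == 0:
            rows.append(
                {
                    "boundary": f"{upper}/{lower}", "threshold": np.nan,
                    "success_rate": np.nan, "separated": False,
                    "n_upper": u.size, "n_lower": l.size,
                }
            )
            continue
        bt = best_threshold(
            u, l, boundary=(upper, lower), grid_step=grid_step, tie_rule=tie_rule
        )
        rows.append(
            {
                "boundary": bt.label, "threshold": bt.threshold,
                "success_rate": bt.success_rate, "separated": bt.separated,
                "n_upper": u.size, "n_lower": l.size,
            }
        )
    return pd.DataFrame(rows)
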