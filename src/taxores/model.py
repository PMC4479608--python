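"""Model/results interface over the threshold analysis.

:class:`ResolutionModel` holds one section's pairwise percent identities
together with the taxonomy; ``fit()`` produces a
:class:`ResolutionResults` carrying the category distributions, the best
threshold and success rate for every adjacent-rank boundary, the
rank-accuracy table, and the lowest thresholds at an accuracy floor —
with ``summary()`` and plotting helpers in the style of statistical
modelling packages.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .similarity import (
    AmbiguousGapError,
    FilterPolicy,
    all_vs_all,
    collapse_pairs,
    filter_records,
)
from .taxonomy import (
    AnnotatedSequence,
    CATEGORIES,
    Lineage,
    filter_uncertain,
)
from .thresholds import (
    CategorizedSimilarities,
    RANK_COLUMN,
    accuracy_table,
    best_threshold_table,
    categorize_similarities,
    lowest_threshold,
)


class ResolutionModel:
    """Taxonomic resolution of one marker section.

    Parameters
    ----------
    pair_values
        Mapping of unordered record-id pairs to percent identity
        (one value per pair, already collapsed and filtered).
    lineages
        Mapping of record id to :class:`~taxores.taxonomy.Lineage`.
        Records with uncertain deciding ranks must be pre-filtered.
    name
        Section label used in summaries.
    """

    def __init__(
        self,
        pair_values: Mapping[tuple[str, str], float],
        lineages: Mapping[str, Lineage],
        name: str = "section",
    ):
        self.pair_values = dict(pair_values)
        self.lineages = dict(lineages)
        self.name = name
        #: fraction of expected pairs surviving length filtering (set by
        #: :meth:`from_sequences`; None when similarities came in pre-made)
        self.retention: float | None = None

    @classmethod
    def from_dataframe(
        cls,
        similarities: pd.DataFrame,
        taxonomy: pd.DataFrame,
        name: str = "section",
    ) -> "ResolutionModel":
        """Build from tidy frames.

        ``similarities`` needs columns query_id/subject_id/percent_identity
        (or id_a/id_b/percent_identity); ``taxonomy`` needs
        record_id/order/family/genus/species.
        """
        cols = similarities.columns
        a_col = "query_id" if "query_id" in cols else "id_a"
        b_col = "subject_id" if "subject_id" in cols else "id_b"
        pairs: dict[tuple[str, str], float] = {}
        for row in similarities.itertuples(index=False):
            key = tuple(sorted((getattr(row, a_col), getattr(row, b_col))))
            val = float(getattr(row, "percent_identity"))
            if key not in pairs or val > pairs[key]:
                pairs[key] = val
        lineages = {
            r.record_id: Lineage(r.order, r.family, r.genus, r.species)
            for r in taxonomy.itertuples(index=False)
        }
        return cls(pairs, lineages, name=name)

    @classmethod
    def from_sequences(
        cls,
        records: Sequence[AnnotatedSequence],
        name: str = "section",
        engine: str = "native",
        policy: FilterPolicy | None = None,
        apply_uncertain_filter: bool = True,
    ) -> "ResolutionModel":
        """Run the full similarity stage on ungapped section sequences.

        Applies the uncertain-identification retention rules, computes
        all-vs-all local alignments with the chosen engine, removes
        short/mismatched hits under ``policy`` (default: the sorted-gap
        strategy) and collapses hits to one value per pair.
        """
        if apply_uncertain_filter:
            records, _ = filter_uncertain(records)
        hits = all_vs_all(records, engine=engine)
        n = len(records)
        expected = n * (n - 1) // 2
        if policy is not None:
            kept, retention = filter_records(hits, policy, expected)
        else:
            # sorted-gap first; when short hits grade continuously into
            # valid ones, fall back to an explicit cutoff at half the
            # shortest section sequence
            try:
                kept, retention = filter_records(
                    hits, FilterPolicy(section_name=name), expected
                )
            except AmbiguousGapError:
                cutoff = min(len(r.residues) for r in records) // 2
                kept, retention = filter_records(
                    hits,
                    FilterPolicy(name, "FIXED_CUTOFF", cutoff),
                    expected,
                )
        pairs = collapse_pairs(kept)
        lineages = {r.record_id: r.lineage for r in records}
        model = cls(pairs, lineages, name=name)
        model.retention = retention
        return model

    def fit(
        self,
        grid_step: float = 0.1,
        accuracy_floor: float = 0.95,
        tie_rule: str = "both",
    ) -> "ResolutionResults":
        """Estimate thresholds and accuracies from the pair similarities."""
        categorized = categorize_similarities(self.pair_values, self.lineages)
        best = best_threshold_table(
            categorized, grid_step=grid_step, tie_rule=tie_rule
        )
        acc = accuracy_table(categorized, grid_step=grid_step, tie_rule=tie_rule)
        lowest = pd.DataFrame(
            [
                {
                    "rank": rank,
                    "threshold": lowest_threshold(acc, rank, accuracy_floor),
                    "accuracy_floor": accuracy_floor,
                }
                for rank in RANK_COLUMN
            ]
        )
        return ResolutionResults(
            model=self,
            categorized=categorized,
            best_thresholds=best,
            accuracy=acc,
            lowest_thresholds=lowest,
            grid_step=grid_step,
            accuracy_floor=accuracy_floor,
        )


@dataclass
class ResolutionResults:
    """Fitted thresholds, success rates and accuracies for one section."""

    model: ResolutionModel
    categorized: CategorizedSimilarities
    best_thresholds: pd.DataFrame
    accuracy: pd.DataFrame
    lowest_thresholds: pd.DataFrame
    grid_step: float
    accuracy_floor: float

    @property
    def category_summary(self) -> pd.DataFrame:
        return self.categorized.summary()

    def accuracy_at(self, n: float, rank: str) -> float:
        """Probability of a correct assignment at ``rank`` given S >= n."""
        col = self.accuracy[RANK_COLUMN[rank]]
        return float(np.interp(n, self.accuracy.index.to_numpy(), col.to_numpy()))

    def summary(self) -> str:
        lines = [
            f"Taxonomic resolution summary — {self.model.name}",
            "=" * 60,
            f"pairs: {len(self.model.pair_values)}   "
            f"records: {len(self.model.lineages)}   "
            f"grid step: {self.grid_step}%",
            "",
            "Category similarity distributions (percent identity):",
            self.category_summary.to_string(
                index=False, float_format=lambda x: f"{x:.2f}"
            ),
            "",
            "Best thresholds (threshold % / success %):",
            self.best_thresholds.to_string(
                index=False, float_format=lambda x: f"{x:.1f}"
            ),
            "",
            f"Lowest thresholds at accuracy floor {self.accuracy_floor:.0%}:",
            self.lowest_thresholds.to_string(
                index=False,
                formatters={
                    "threshold": lambda t: "none" if t is None or (
                        isinstance(t, float) and np.isnan(t)
                    ) else f"{t:.1f}"
                },
            ),
        ]
        return "\n".join(lines)

    # -- plotting -----------------------------------------------------------

    def plot_distributions(self, ax=None):
        """Boxplots of the five category similarity distributions."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        data = [self.categorized.values[c] for c in CATEGORIES]
        ax.boxplot(
            [d if d.size else [np.nan] for d in data], tick_labels=CATEGORIES
        )
        ax.set_xlabel("pair category")
        ax.set_ylabel("percent identity")
        ax.set_title(self.model.name)
        return ax

    def plot_crossing(self, boundary: tuple[str, str] = ("S", "G"), ax=None):
        """Positive/negative cumulative curves and their crossing."""
        import matplotlib.pyplot as plt

        from .thresholds import cumulative_curve, _make_grid

        if ax is None:
            _, ax = plt.subplots()
        upper, lower = boundary
        u = self.categorized.values[upper]
        l = self.categorized.values[lower]
        grid = _make_grid(float(min(u.min(), l.min())), 100.0, self.grid_step)
        pos = cumulative_curve(u, grid=grid).positive
        neg = cumulative_curve(l, grid=grid).negative
        ax.plot(grid, pos, label=f"{upper} positive")
        ax.plot(grid, neg, label=f"{lower} negative")
        row = self.best_thresholds.set_index("boundary").loc[f"{upper}/{lower}"]
        if np.isfinite(row["threshold"]):
            ax.axvline(row["threshold"], ls="--", color="grey")
            ax.annotate(
                f"{row['threshold']:.1f}/{row['success_rate']:.0f}",
                (row["threshold"], row["success_rate"] / 100),
            )
        ax.set_xlabel("similarity threshold (%)")
        ax.set_ylabel("cumulative frequency")
        ax.legend()
        return ax
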