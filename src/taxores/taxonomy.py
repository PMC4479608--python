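"""Four-rank lineages, retention filtering, and pairwise similarity categories.

Every sequence carries an order/family/genus/species lineage.  Pairs of
sequences fall into exactly one of five similarity categories:

* ``S`` — same species (intra-specific)
* ``G`` — same genus, different species
* ``F`` — same family, different genus
* ``O`` — same order, different family
* ``I`` — different orders

A species (or a higher rank) may be marked *uncertain*: the specimen was
identified only to the rank above.  Such records cannot be categorised at the
uncertain rank, so datasets are passed through :func:`filter_uncertain`
before any pairwise statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import pandas as pd

#: Literal token marking an uncertain rank label in taxonomy tables.
UNCERTAIN = "sp_uncertain"

RANKS = ("order", "family", "genus", "species")

CATEGORIES = ("S", "G", "F", "O", "I")

#: Human-readable boundary names, finer category first.
BOUNDARIES = (("S", "G"), ("G", "F"), ("F", "O"), ("O", "I"))


class IndeterminateCategoryError(ValueError):
    """Raised when the rank that decides a pair's category is uncertain."""


class TaxonomyError(ValueError):
    """Raised for malformed or tree-inconsistent taxonomy tables."""


@dataclass(frozen=True)
class Lineage:
    """A four-rank lineage (order, family, genus, species).

    Any rank may carry the :data:`UNCERTAIN` token, meaning the specimen was
    not confidently identified at that rank.  Order/family/genus labels must
    be non-empty.
    """

    order: str
    family: str
    genus: str
    species: str

    def __post_init__(self) -> None:
        for rank in ("order", "family", "genus"):
            if not getattr(self, rank):
                raise TaxonomyError(f"empty {rank} label")
        if not self.species:
            raise TaxonomyError("empty species label (use the uncertain token)")

    def is_uncertain(self, rank: str) -> bool:
        return getattr(self, rank) == UNCERTAIN

    @property
    def highest_uncertain_rank(self) -> str | None:
        """Most inclusive uncertain rank, walking order -> species; None if all certain."""
        for rank in RANKS:
            if self.is_uncertain(rank):
                return rank
        return None


@dataclass
class AnnotatedSequence:
    """One marker sequence with its lineage.

    ``residues`` is the nucleotide string; it may contain ``-`` gap
    characters only when the record is a row of an alignment.
    """

    record_id: str
    accession: str
    lineage: Lineage
    residues: str

    @property
    def ungapped(self) -> str:
        return self.residues.replace("-", "")


def categorize_pair(a: Lineage, b: Lineage) -> str:
    """Classify a pair of lineages into one of the S/G/F/O/I categories.

    Walks the ranks from order downwards; the category is decided by the
    deepest rank at which the two lineages still agree.  Raises
    :class:`IndeterminateCategoryError` if the deciding rank is uncertain on
    either side (such records must be removed by :func:`filter_uncertain`
    first).
    """
    if a.is_uncertain("order") or b.is_uncertain("order"):
        raise IndeterminateCategoryError("order uncertain on one side")
    if a.order != b.order:
        return "I"
    if a.is_uncertain("family") or b.is_uncertain("family"):
        raise IndeterminateCategoryError("family uncertain within one order")
    if a.family != b.family:
        return "O"
    if a.is_uncertain("genus") or b.is_uncertain("genus"):
        raise IndeterminateCategoryError("genus uncertain within one family")
    if a.genus != b.genus:
        return "F"
    if a.is_uncertain("species") or b.is_uncertain("species"):
        raise IndeterminateCategoryError("species uncertain within one genus")
    if a.species != b.species:
        return "G"
    return "S"


@dataclass
class ExclusionLog:
    """Record of every sequence dropped by a filtering step, with reasons."""

    entries: list[tuple[str, str]] = field(default_factory=list)

    def add(self, record_id: str, reason: str) -> None:
        self.entries.append((record_id, reason))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.entries, columns=["record_id", "reason"])

    def __len__(self) -> int:
        return len(self.entries)


def _group_key(lin: Lineage, rank: str) -> tuple[str, ...]:
    """Key identifying the group one rank above ``rank``."""
    idx = RANKS.index(rank)
    return tuple(getattr(lin, r) for r in RANKS[:idx])


def filter_uncertain(
    records: Iterable[AnnotatedSequence],
) -> tuple[list[AnnotatedSequence], ExclusionLog]:
    """Apply the uncertain-identification retention rules.

    Uncertain records are only informative when their group contains no
    confidently named alternative.  Concretely, for each rank from species
    upward: within the parent group (genus for uncertain species, family for
    uncertain genus, ...), if any record is confidently named at that rank,
    every uncertain record is dropped; otherwise exactly one uncertain record
    is retained (the lexicographically smallest accession, ties broken by
    record_id) and the rest dropped.

    Returns the retained records (input order preserved) and an exclusion
    log.  The operation is idempotent.
    """
    records = list(records)
    log = ExclusionLog()
    dropped: set[str] = set()

    # Walk species -> order so a record uncertain at a high rank is judged at
    # that rank (its highest_uncertain_rank), once.
    for rank in reversed(RANKS):
        groups: dict[tuple[str, ...], list[AnnotatedSequence]] = {}
        confident: set[tuple[str, ...]] = set()
        for rec in records:
            if rec.record_id in dropped:
                continue
            key = _group_key(rec.lineage, rank)
            if rec.lineage.highest_uncertain_rank == rank:
                groups.setdefault(key, []).append(rec)
            elif not rec.lineage.is_uncertain(rank):
                confident.add(key)
        for key, members in groups.items():
            if key in confident:
                for rec in members:
                    dropped.add(rec.record_id)
                    log.add(
                        rec.record_id,
                        f"uncertain {rank} in a group with confirmed {rank}",
                    )
            else:
                keep = min(members, key=lambda r: (r.accession, r.record_id))
                for rec in members:
                    if rec.record_id != keep.record_id:
                        dropped.add(rec.record_id)
                        log.add(
                            rec.record_id,
                            f"uncertain {rank}; kept {keep.record_id} "
                            f"as sole representative",
                        )
    kept = [r for r in records if r.record_id not in dropped]
    return kept, log


def validate_tree_consistency(lineages: Iterable[Lineage]) -> None:
    """Reject taxonomies where a label maps to two different parents.

    A genus under two families (or a family under two orders, or a species
    name reused across genera with different parents) indicates a label
    collision and is a hard error.  Uncertain tokens are exempt.
    """
    parent_of: dict[tuple[str, str], tuple[str, ...]] = {}
    for lin in lineages:
        for rank in ("family", "genus"):
            label = getattr(lin, rank)
            if label == UNCERTAIN:
                continue
            parent = _group_key(lin, rank)
            if UNCERTAIN in parent:
                continue
            prev = parent_of.setdefault((rank, label), parent)
            if prev != parent:
                raise TaxonomyError(
                    f"{rank} {label!r} appears under two parents: "
                    f"{prev} and {parent}"
                )


def load_taxonomy(path) -> dict[str, tuple[str, Lineage]]:
    """Load a taxonomy table (TSV) keyed by record_id.

    Expected columns: record_id, accession, order, family, genus, species.
    The literal token ``sp_uncertain`` marks an uncertain rank.  Returns
    ``{record_id: (accession, Lineage)}``; validates uniqueness of
    record_id and tree consistency.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = ["record_id", "accession", *RANKS]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise TaxonomyError(f"taxonomy table missing columns: {missing}")
    if df["record_id"].duplicated().any():
        dups = df.loc[df["record_id"].duplicated(), "record_id"].tolist()
        raise TaxonomyError(f"duplicate record_id(s): {dups}")
    table: dict[str, tuple[str, Lineage]] = {}
    for row in df.itertuples(index=False):
        lin = Lineage(row.order, row.family, row.genus, row.species)
        table[row.record_id] = (row.accession, lin)
    validate_tree_consistency(lin for _, lin in table.values())
    return table


def write_taxonomy(table: dict[str, tuple[str, Lineage]], path) -> None:
    rows = [
        {
            "record_id": rid,
            "accession": acc,
            **{rank: getattr(lin, rank) for rank in RANKS},
        }
        for rid, (acc, lin) in table.items()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
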