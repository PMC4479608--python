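"""Alignment variability profiling and primer-anchored section extraction.

Operates on a multiple sequence alignment of rRNA gene sequences: Shannon
entropy per column and windowed trends, site classification (conserved /
variable / parsimony-informative), GC content, uncorrected p-distance with
pairwise deletion, and extraction of amplicon-like sections anchored by
IUPAC primers on a reference row.

Coordinates are 0-based half-open internally; report tables and logs use
1-based inclusive coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq

from .taxonomy import AnnotatedSequence, ExclusionLog, load_taxonomy

GAP = "-"

#: IUPAC nucleotide codes mapped to bit masks (A=1, C=2, G=4, T=8).
IUPAC_BITS = {
    "A": 1, "C": 2, "G": 4, "T": 8, "U": 8,
    "R": 5, "Y": 10, "S": 6, "W": 9, "K": 12, "M": 3,
    "B": 14, "D": 13, "H": 11, "V": 7, "N": 15,
}

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3}


class RegionError(ValueError):
    pass


class UndefinedDistanceError(ValueError):
    """No comparable (both unambiguous) sites between two rows."""


@dataclass(frozen=True)
class Region:
    name: str
    start: int  # 0-based inclusive
    end: int    # 0-based exclusive

    def __post_init__(self) -> None:
        if self.end <= self.start or self.start < 0:
            raise RegionError(f"bad interval for {self.name}: {self.start}..{self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class RegionMap:
    """Ordered, non-overlapping named intervals on alignment coordinates."""

    regions: list[Region]

    def __post_init__(self) -> None:
        names = [r.name for r in self.regions]
        if len(set(names)) != len(names):
            raise RegionError("duplicate region names")
        for prev, cur in zip(self.regions, self.regions[1:]):
            if cur.start < prev.end:
                raise RegionError(
                    f"regions {prev.name} and {cur.name} overlap or are unordered"
                )

    def __getitem__(self, name: str) -> Region:
        for r in self.regions:
            if r.name == name:
                return r
        raise KeyError(name)

    def names(self) -> list[str]:
        return [r.name for r in self.regions]

    @property
    def variable_names(self) -> list[str]:
        return [r.name for r in self.regions if r.name.upper().startswith("V")]


@dataclass
class RegionStats:
    """Site-composition summary of one alignment interval (Table-style row)."""

    name: str
    length_range: tuple[int, int]
    gc_percent: float
    n_total_sites: int
    n_variable: int
    n_conserved: int
    n_parsimony_informative: int

    def __post_init__(self) -> None:
        assert self.n_variable + self.n_conserved <= self.n_total_sites
        assert self.n_parsimony_informative <= self.n_variable

    @property
    def pi_percent(self) -> float:
        return 100.0 * self.n_parsimony_informative / self.n_total_sites

    @property
    def n_remainder(self) -> int:
        """Columns counted in Nt but neither variable nor conserved

        (all-gap or ambiguity-only columns within the interval)."""
        return self.n_total_sites - self.n_variable - self.n_conserved


@dataclass(frozen=True)
class SectionSpec:
    """An amplicon-like section defined by a primer pair.

    ``reverse_primer`` is given in the orientation the primer is synthesised
    (binding the minus strand); its reverse complement is searched on the
    plus strand.  ``required_regions`` lists the variable regions that must
    be fully covered by a record for it to enter the section database;
    ``end_slack_allowed`` tolerates missing terminal sites outside those
    regions.
    """

    name: str
    forward_primer: str = ""
    reverse_primer: str = ""
    required_regions: tuple[str, ...] = ()
    end_slack_allowed: bool = False
    #: explicit anchor columns (0-based half-open) in place of primers
    columns: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.columns is None and not (self.forward_primer and self.reverse_primer):
            raise RegionError("need a primer pair or explicit anchor columns")


class Alignment:
    """A gapped multiple sequence alignment of annotated sequences."""

    def __init__(self, rows: Sequence[AnnotatedSequence]):
        rows = list(rows)
        if len(rows) < 2:
            raise RegionError("alignment needs at least 2 rows")
        lengths = {len(r.residues) for r in rows}
        if len(lengths) != 1:
            raise RegionError(f"ragged alignment: row lengths {sorted(lengths)}")
        self.rows = rows
        self.n_columns = lengths.pop()
        # byte matrix of uppercase residues for vectorised column ops
        self._mat = np.frombuffer(
            "".join(r.residues.upper() for r in rows).encode("ascii"),
            dtype="S1",
        ).reshape(len(rows), self.n_columns)
        bad = set(np.unique(self._mat).astype(str)) - set(IUPAC_BITS) - {GAP, "."}
        if bad:
            raise RegionError(f"non-IUPAC characters in alignment: {sorted(bad)}")
        # base codes: 0..3 for A/C/G/T, -1 for gap or ambiguity
        codes = np.full(self._mat.shape, -1, dtype=np.int8)
        for base, code in _BASE_CODE.items():
            codes[self._mat == base.encode()] = code
        self._codes = codes
        self.ids = [r.record_id for r in rows]

    def __len__(self) -> int:
        return len(self.rows)

    def subset(self, record_ids: Iterable[str]) -> "Alignment":
        wanted = set(record_ids)
        rows = [r for r in self.rows if r.record_id in wanted]
        missing = wanted - {r.record_id for r in rows}
        if missing:
            raise RegionError(f"records not in alignment: {sorted(missing)}")
        return Alignment(rows)

    def codes(self, start: int = 0, end: int | None = None) -> np.ndarray:
        return self._codes[:, start : end if end is not None else self.n_columns]

    def column_counts(self, column: int) -> np.ndarray:
        """Counts of A,C,G,T (unambiguous only) in one column."""
        col = self._codes[:, column]
        return np.bincount(col[col >= 0], minlength=4)


def load_alignment(fasta_path, taxonomy_path) -> Alignment:
    """Read an aligned FASTA plus its taxonomy TSV into an :class:`Alignment`."""
    table = load_taxonomy(taxonomy_path)
    rows = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id not in table:
            raise RegionError(f"no taxonomy row for aligned record {rec.id!r}")
        acc, lin = table[rec.id]
        rows.append(AnnotatedSequence(rec.id, acc, lin, str(rec.seq)))
    return Alignment(rows)


# ---------------------------------------------------------------------------
# entropy

def column_entropy(alignment: Alignment, column: int) -> float:
    """Shannon entropy (bits) of unambiguous base frequencies in a column.

    Gaps and ambiguity codes carry no weight.  A column with no unambiguous
    bases has entropy 0 (see :func:`entropy_profile` for the explicit flag).
    """
    counts = alignment.column_counts(column)
    total = counts.sum()
    if total == 0:
        return 0.0
    p = counts[counts > 0] / total
    return float(-(p * np.log2(p)).sum())


def entropy_profile(alignment: Alignment, window: int = 20) -> pd.DataFrame:
    """Per-column entropies plus a blockwise mean trend.

    The trend value for block *k* is the arithmetic mean of the entropies of
    the *k*-th successive non-overlapping block of ``window`` columns (a
    trailing partial block is averaged over its actual width).  Returns a
    frame with columns ``column`` (1-based), ``entropy``, ``empty`` (no
    unambiguous base), ``block`` and ``trend``.
    """
    if window < 1:
        raise RegionError("window must be >= 1")
    if window > alignment.n_columns:
        raise RegionError("window exceeds alignment")
    ent = np.array(
        [column_entropy(alignment, j) for j in range(alignment.n_columns)]
    )
    empty = np.array(
        [alignment.column_counts(j).sum() == 0 for j in range(alignment.n_columns)]
    )
    block = np.arange(alignment.n_columns) // window
    trend_per_block = pd.Series(ent).groupby(block).mean()
    return pd.DataFrame(
        {
            "column": np.arange(1, alignment.n_columns + 1),
            "entropy": ent,
            "empty": empty,
            "block": block,
            "trend": trend_per_block.reindex(block).to_numpy(),
        }
    )


# ---------------------------------------------------------------------------
# site classification / GC

def classify_sites(
    alignment: Alignment, interval: tuple[int, int], name: str = "region"
) -> RegionStats:
    """Classify columns of ``interval`` as conserved/variable/PI.

    Nt counts every column in the interval.  A column is *variable* if at
    least two distinct unambiguous states occur, *conserved* if exactly one,
    and *parsimony-informative* if at least two states each occur in at
    least two rows.  Columns with no unambiguous state (all gap/ambiguous)
    fall into neither class; they appear in the remainder Nt - Nv - Nc.
    """
    start, end = interval
    if end <= start:
        raise RegionError("empty interval")
    codes = alignment.codes(start, end)
    nv = nc = pi = 0
    for j in range(codes.shape[1]):
        col = codes[:, j]
        counts = np.bincount(col[col >= 0], minlength=4)
        states = int((counts > 0).sum())
        if states >= 2:
            nv += 1
            if int((counts >= 2).sum()) >= 2:
                pi += 1
        elif states == 1:
            nc += 1
    lengths = (codes >= 0).sum(axis=1) + _ambiguous_counts(alignment, start, end)
    return RegionStats(
        name=name,
        length_range=(int(lengths.min()), int(lengths.max())),
        gc_percent=gc_content(alignment, interval),
        n_total_sites=end - start,
        n_variable=nv,
        n_conserved=nc,
        n_parsimony_informative=pi,
    )


def _ambiguous_counts(alignment: Alignment, start: int, end: int) -> np.ndarray:
    """Per-row counts of ambiguity characters (non-gap, non-ACGT) in a slice."""
    mat = alignment._mat[:, start:end]
    codes = alignment.codes(start, end)
    return ((codes < 0) & (mat != GAP.encode()) & (mat != b".")).sum(axis=1)


def gc_content(alignment: Alignment, interval: tuple[int, int]) -> float:
    """Pooled GC percentage over all rows of an interval.

    Gaps and ambiguity codes are excluded from numerator and denominator.
    """
    start, end = interval
    codes = alignment.codes(start, end)
    total = int((codes >= 0).sum())
    if total == 0:
        raise RegionError("no unambiguous bases in interval")
    gc = int(((codes == 1) | (codes == 2)).sum())
    return 100.0 * gc / total


# ---------------------------------------------------------------------------
# p-distance

def p_distance(a: str, b: str) -> float:
    """Uncorrected proportion of differing sites, pairwise deletion.

    Columns where either sequence has a gap or an ambiguity code are
    skipped.  Raises :class:`UndefinedDistanceError` when no site is
    comparable.
    """
    if len(a) != len(b):
        raise RegionError("sequences must have equal gapped length")
    ca = _encode(a)
    cb = _encode(b)
    usable = (ca >= 0) & (cb >= 0)
    n = int(usable.sum())
    if n == 0:
        raise UndefinedDistanceError("no comparable sites")
    diff = int((ca[usable] != cb[usable]).sum())
    return diff / n


def _encode(s: str) -> np.ndarray:
    arr = np.frombuffer(s.upper().encode("ascii"), dtype="S1")
    codes = np.full(len(arr), -1, dtype=np.int8)
    for base, code in _BASE_CODE.items():
        codes[arr == base.encode()] = code
    return codes


def region_distance_summary(
    alignment: Alignment,
    region_map: RegionMap,
    record_ids: Iterable[str] | None = None,
    include_combined: bool = True,
) -> pd.DataFrame:
    """Mean +/- SD of all-pairs p-distances per region.

    Rows cover every named region plus, when ``include_combined``, the
    combined variable regions (``CVs``), the combined complement (``TCs``)
    and the whole alignment.  Pairs with no comparable sites in a region are
    excluded and counted in ``n_undefined``.  SD uses ddof=1.
    """
    aln = alignment if record_ids is None else alignment.subset(record_ids)
    targets: list[tuple[str, list[tuple[int, int]]]] = [
        (r.name, [(r.start, r.end)]) for r in region_map.regions
    ]
    if include_combined:
        v_ivals = [
            (r.start, r.end) for r in region_map.regions
            if r.name in region_map.variable_names
        ]
        if v_ivals:
            targets.append(("CVs", v_ivals))
            comp = _complement(v_ivals, aln.n_columns)
            if comp:
                targets.append(("TCs", comp))
        targets.append(("whole", [(0, aln.n_columns)]))
    out = []
    for name, intervals in targets:
        codes = np.hstack([aln.codes(s, e) for s, e in intervals])
        n = codes.shape[0]
        dists = []
        undefined = 0
        for i in range(n - 1):
            ci = codes[i]
            block = codes[i + 1 :]
            usable = (ci >= 0) & (block >= 0)
            counts = usable.sum(axis=1)
            diffs = ((ci != block) & usable).sum(axis=1)
            ok = counts > 0
            undefined += int((~ok).sum())
            dists.append(diffs[ok] / counts[ok])
        d = np.concatenate(dists) if dists else np.array([])
        out.append(
            {
                "region": name,
                "mean": float(d.mean()) if d.size else np.nan,
                "sd": float(d.std(ddof=1)) if d.size > 1 else 0.0,
                "n_pairs": int(d.size),
                "n_undefined": undefined,
            }
        )
    return pd.DataFrame(out)


def _complement(intervals: list[tuple[int, int]], n: int) -> list[tuple[int, int]]:
    out = []
    pos = 0
    for s, e in sorted(intervals):
        if s > pos:
            out.append((pos, s))
        pos = max(pos, e)
    if pos < n:
        out.append((pos, n))
    return out


def region_table(alignment: Alignment, region_map: RegionMap) -> pd.DataFrame:
    """Sequence-characteristics table: one row per region plus TCs/CVs/whole."""
    rows = []
    v_ivals = [
        (r.start, r.end) for r in region_map.regions
        if r.name in region_map.variable_names
    ]
    extra = []
    if v_ivals:
        extra = [("CVs", v_ivals)]
        comp = _complement(v_ivals, alignment.n_columns)
        if comp:
            extra.append(("TCs", comp))
    for name, intervals in (
        [("whole", [(0, alignment.n_columns)])]
        + extra
        + [(r.name, [(r.start, r.end)]) for r in region_map.regions]
    ):
        stats = _classify_multi(alignment, intervals, name)
        rows.append(
            {
                "region": name,
                "length_min": stats.length_range[0],
                "length_max": stats.length_range[1],
                "gc_percent": round(stats.gc_percent, 1),
                "Nt": stats.n_total_sites,
                "Nv": stats.n_variable,
                "Nc": stats.n_conserved,
                "PI": stats.n_parsimony_informative,
                "pct_PI": round(stats.pi_percent, 1),
                "remainder": stats.n_remainder,
            }
        )
    return pd.DataFrame(rows)


def _classify_multi(
    alignment: Alignment, intervals: list[tuple[int, int]], name: str
) -> RegionStats:
    parts = [classify_sites(alignment, iv, name) for iv in intervals]
    lengths_min = sum(p.length_range[0] for p in parts)
    lengths_max = sum(p.length_range[1] for p in parts)
    codes = np.hstack([alignment.codes(s, e) for s, e in intervals])
    total = int((codes >= 0).sum())
    gc = int(((codes == 1) | (codes == 2)).sum())
    return RegionStats(
        name=name,
        length_range=(lengths_min, lengths_max),
        gc_percent=100.0 * gc / total if total else 0.0,
        n_total_sites=sum(p.n_total_sites for p in parts),
        n_variable=sum(p.n_variable for p in parts),
        n_conserved=sum(p.n_conserved for p in parts),
        n_parsimony_informative=sum(p.n_parsimony_informative for p in parts),
    )


# ---------------------------------------------------------------------------
# primers and sections

def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def locate_primer(
    sequence: str, primer: str, max_mismatches: int = 3
) -> tuple[int, int] | None:
    """Best ungapped IUPAC-aware match of ``primer`` in ``sequence``.

    Returns the 0-based half-open interval of the best-scoring (fewest
    mismatches) placement, leftmost on ties, or None if every placement
    exceeds ``max_mismatches``.  Ambiguity codes in the primer match any
    compatible base (R matches A/G, N matches anything); ambiguity codes in
    the sequence match compatibly by bit overlap.
    """
    m, n = len(primer), len(sequence)
    if m > n:
        return None
    seq_bits = np.array([IUPAC_BITS.get(c, 0) for c in sequence.upper()], dtype=np.uint8)
    pr_bits = np.array([IUPAC_BITS.get(c, 0) for c in primer.upper()], dtype=np.uint8)
    if (pr_bits == 0).any():
        raise RegionError("primer contains non-IUPAC characters")
    windows = np.lib.stride_tricks.sliding_window_view(seq_bits, m)
    mismatches = ((windows & pr_bits) == 0).sum(axis=1)
    best = int(mismatches.argmin())
    if mismatches[best] > max_mismatches:
        return None
    return best, best + m


def _ungapped_to_columns(row: str) -> np.ndarray:
    """Alignment column index of each ungapped position of a row."""
    arr = np.frombuffer(row.encode("ascii"), dtype="S1")
    return np.nonzero((arr != GAP.encode()) & (arr != b"."))[0]


@dataclass
class SectionExtraction:
    """Result of extracting one section across an alignment."""

    spec: SectionSpec
    columns: tuple[int, int]  # anchor-to-anchor, 0-based half-open
    records: list[AnnotatedSequence] = field(default_factory=list)
    log: ExclusionLog = field(default_factory=ExclusionLog)

    @property
    def length_range(self) -> tuple[int, int]:
        lengths = [len(r.residues) for r in self.records]
        return (min(lengths), max(lengths)) if lengths else (0, 0)


def extract_section(
    alignment: Alignment,
    spec: SectionSpec,
    region_map: RegionMap,
    reference_id: str | None = None,
    max_mismatches: int = 3,
    columns: tuple[int, int] | None = None,
) -> SectionExtraction:
    """Extract one primer-anchored section from every record.

    Anchors are resolved once: explicit columns (argument or
    ``spec.columns``) take precedence; otherwise both primers are located
    on the ungapped reference row (default: first row) and transferred to
    alignment columns.  The section spans the forward primer's first base
    through the reverse primer's last base.

    Each record's ungapped subsequence over those columns is returned.
    Completeness: a record must span the full anchor interval unless
    ``end_slack_allowed``, in which case missing terminal sites are
    tolerated provided every required region is fully covered (the record
    spans it and is gapped at < 50% of its columns).  Incomplete records go
    to the exclusion log.
    """
    if columns is None:
        columns = spec.columns
    if columns is None:
        ref_row = alignment.rows[0] if reference_id is None else next(
            r for r in alignment.rows if r.record_id == reference_id
        )
        ref_seq = ref_row.ungapped
        fwd = locate_primer(ref_seq, spec.forward_primer, max_mismatches)
        rev = locate_primer(
            ref_seq, reverse_complement(spec.reverse_primer), max_mismatches
        )
        if fwd is None or rev is None:
            raise RegionError(
                f"section {spec.name}: primer(s) not resolvable on reference "
                f"{ref_row.record_id!r}"
            )
        col_of = _ungapped_to_columns(ref_row.residues)
        start, end = int(col_of[fwd[0]]), int(col_of[rev[1] - 1]) + 1
        if end <= start:
            raise RegionError(f"section {spec.name}: primers in wrong orientation")
    else:
        start, end = columns

    required = [region_map[name] for name in spec.required_regions]
    out = SectionExtraction(spec=spec, columns=(start, end))
    for rec in alignment.rows:
        cols = _ungapped_to_columns(rec.residues)
        if cols.size == 0:
            out.log.add(rec.record_id, "empty row")
            continue
        first, last = int(cols[0]), int(cols[-1])
        spans_all = first <= start and last >= end - 1
        if not spans_all and not spec.end_slack_allowed:
            out.log.add(rec.record_id, "incomplete at section terminus")
            continue
        ok = True
        for reg in required:
            s, e = max(reg.start, start), min(reg.end, end)
            if not (first <= s and last >= e - 1):
                out.log.add(rec.record_id, f"does not span required region {reg.name}")
                ok = False
                break
            sub = rec.residues[s:e]
            gap_frac = (sub.count(GAP) + sub.count(".")) / (e - s)
            if gap_frac >= 0.5:
                out.log.add(
                    rec.record_id, f"required region {reg.name} mostly gapped"
                )
                ok = False
                break
        if not ok:
            continue
        seq = rec.residues[start:end].replace(GAP, "").replace(".", "")
        if not seq:
            out.log.add(rec.record_id, "no residues within section")
            continue
        out.records.append(
            AnnotatedSequence(rec.record_id, rec.accession, rec.lineage, seq)
        )
    return out


# ---------------------------------------------------------------------------
# configuration

def load_region_config(path) -> tuple[RegionMap, list[SectionSpec]]:
    """Read regions and section specs from a YAML config.

    Schema::

        regions:
          - {name: V1, start: 12, end: 35}      # 1-based inclusive
        sections:
          - name: section5
            forward_primer: GTACACACCGCCCGTC
            reverse_primer: TGATCCTTCTGCAGGTTCACCTAC
            required_regions: [V9]
            end_slack_allowed: true
          - name: by_coords          # explicit anchors instead of primers
            start: 1651              # 1-based inclusive
            end: 1789
            required_regions: [V9]
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    regions = RegionMap(
        [
            Region(r["name"], int(r["start"]) - 1, int(r["end"]))
            for r in cfg.get("regions", [])
        ]
    )
    sections = [
        SectionSpec(
            name=s["name"],
            forward_primer=s.get("forward_primer", ""),
            reverse_primer=s.get("reverse_primer", ""),
            required_regions=tuple(s.get("required_regions", [])),
            end_slack_allowed=bool(s.get("end_slack_allowed", False)),
            columns=(
                (int(s["start"]) - 1, int(s["end"]))
                if "start" in s and "end" in s
                else None
            ),
        )
        for s in cfg.get("sections", [])
    ]
    return regions, sections
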