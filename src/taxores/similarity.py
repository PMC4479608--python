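"""All-vs-all local-alignment percent identities and validity filtering.

The statistics downstream consume one percent-identity value per unordered
sequence pair, obtained from local alignment of section databases.  Two
engines produce the standard 12-column tabular report (query id, subject
id, % identity, alignment length, mismatches, gap opens, q.start, q.end,
s.start, s.end, evalue, bit score):

* ``engine="blast"`` wraps the NCBI ``makeblastdb``/``blastn`` executables
  (tabular output parsed verbatim) — the fast path for large databases;
* ``engine="native"`` is a numpy affine-gap Smith–Waterman with
  megablast-like scores (match +2, mismatch −3, gap open 5, gap extend 2),
  reporting the single best local alignment per ordered pair — no external
  binary required.

Local alignment of divergent sequences also yields spurious short
high-identity hits; :func:`filter_records` removes them by alignment
length, either by locating the gap in the sorted length distribution or by
an explicit cutoff.
"""

from __future__ import annotations

import math
import shutil
import subprocess
import tempfile
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .regions import IUPAC_BITS
from .taxonomy import AnnotatedSequence

OUTFMT6_COLUMNS = [
    "query_id", "subject_id", "percent_identity", "alignment_length",
    "mismatches", "gap_opens", "q_start", "q_end", "s_start", "s_end",
    "evalue", "bit_score",
]

# megablast-like scoring (reward/penalty/gap existence/extension)
MATCH = 2
MISMATCH = -3
GAP_OPEN = 5
GAP_EXTEND = 2
# Karlin-Altschul parameters for the +2/-3 gapped system (approximate,
# used only to put native scores on a bit scale).
_LAMBDA = 0.625
_K = 0.41


class SimilarityError(ValueError):
    pass


class AmbiguousGapError(SimilarityError):
    """SORTED_GAP found no unambiguous short-match gap; use FIXED_CUTOFF."""


@dataclass
class SimilarityRecord:
    """One local-alignment hit in the 12-column tabular convention."""

    query_id: str
    subject_id: str
    percent_identity: float
    alignment_length: int
    mismatches: int
    gap_opens: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    evalue: float
    bit_score: float
    #: exact identity count (native engine only; tabular reports omit it)
    n_identities: int | None = None

    def as_tuple(self) -> tuple:
        return tuple(getattr(self, c) for c in OUTFMT6_COLUMNS)


@dataclass(frozen=True)
class FilterPolicy:
    """How to remove mismatched/short-matched hits for one section."""

    section_name: str
    strategy: str = "SORTED_GAP"  # or "FIXED_CUTOFF"
    min_alignment_length: int | None = None

    def __post_init__(self) -> None:
        if self.strategy not in ("SORTED_GAP", "FIXED_CUTOFF"):
            raise SimilarityError(f"unknown strategy {self.strategy!r}")
        if self.strategy == "FIXED_CUTOFF" and self.min_alignment_length is None:
            raise SimilarityError("FIXED_CUTOFF requires min_alignment_length")


def _validate(seqs: Sequence[AnnotatedSequence]) -> None:
    if len(seqs) < 2:
        raise SimilarityError("need at least 2 sequences")
    for s in seqs:
        bad = set(s.residues.upper()) - set(IUPAC_BITS)
        if bad:
            raise SimilarityError(
                f"sequence {s.record_id!r} has non-IUPAC characters: {sorted(bad)}"
            )


# ---------------------------------------------------------------------------
# native Smith-Waterman

def smith_waterman(a: str, b: str) -> SimilarityRecord | None:
    """Best local alignment of ``a`` (query) vs ``b`` (subject).

    Affine gap cost: a gap of length g costs GAP_OPEN + g*GAP_EXTEND.
    Returns None when no positive-scoring alignment exists.
    """
    qa = a.upper()
    qb = b.upper()
    m, n = len(qa), len(qb)
    open_ = GAP_OPEN + GAP_EXTEND
    ext = GAP_EXTEND
    av = np.frombuffer(qa.encode(), dtype="S1")
    bv = np.frombuffer(qb.encode(), dtype="S1")

    NEG = -(10**9)
    H = np.zeros((m + 1, n + 1), dtype=np.int64)
    E = np.full((m + 1, n + 1), NEG, dtype=np.int64)  # gap in query (horizontal)
    F = np.full((m + 1, n + 1), NEG, dtype=np.int64)  # gap in subject (vertical)
    jix = np.arange(n, dtype=np.int64)
    for i in range(1, m + 1):
        s = np.where(bv == av[i - 1], MATCH, MISMATCH)
        diag = H[i - 1, :-1] + s
        F[i, 1:] = np.maximum(H[i - 1, 1:] - open_, F[i - 1, 1:] - ext)
        G = np.maximum(0, np.maximum(diag, F[i, 1:]))
        # E[i,j] = max over gap starts c<j of G(c) - open_ - ext*(j-c-1),
        # computed with a prefix max of G(c) + ext*c
        pref = np.maximum.accumulate(G + ext * jix)
        E[i, 2:] = pref[:-1] - open_ - ext * jix[:-1]
        E[i, 1] = NEG
        H[i, 1:] = np.maximum(G, E[i, 1:])

    score = int(H.max())
    if score <= 0:
        return None
    i, j = np.unravel_index(int(H.argmax()), H.shape)
    q_end, s_end = int(i), int(j)
    ident = mism = length = gap_opens = 0
    state = "H"
    while True:
        if state == "H":
            h = H[i, j]
            if h == 0:
                break
            if i > 0 and j > 0 and h == H[i - 1, j - 1] + (
                MATCH if qa[i - 1] == qb[j - 1] else MISMATCH
            ):
                ident += qa[i - 1] == qb[j - 1]
                mism += qa[i - 1] != qb[j - 1]
                length += 1
                i -= 1
                j -= 1
            elif h == E[i, j]:
                state = "E"
                gap_opens += 1
            elif h == F[i, j]:
                state = "F"
                gap_opens += 1
            else:  # pragma: no cover - defensive
                raise AssertionError("traceback inconsistency")
        elif state == "E":
            length += 1
            if E[i, j] == E[i, j - 1] - ext:
                j -= 1
            else:
                j -= 1
                state = "H"
        else:  # F
            length += 1
            if F[i, j] == F[i - 1, j] - ext:
                i -= 1
            else:
                i -= 1
                state = "H"
    q_start, s_start = int(i) + 1, int(j) + 1
    bit = (_LAMBDA * score - math.log(_K)) / math.log(2.0)
    evalue = _K * m * n * math.exp(-_LAMBDA * score)
    return SimilarityRecord(
        query_id="query",
        subject_id="subject",
        percent_identity=round(100.0 * ident / length, 2),
        alignment_length=length,
        mismatches=mism,
        gap_opens=gap_opens,
        q_start=q_start,
        q_end=q_end,
        s_start=s_start,
        s_end=s_end,
        evalue=evalue,
        bit_score=round(bit, 1),
        n_identities=ident,
    )


def _all_vs_all_native(seqs: Sequence[AnnotatedSequence]) -> list[SimilarityRecord]:
    out: list[SimilarityRecord] = []
    for q in seqs:
        for s in seqs:
            if q.record_id == s.record_id:
                continue
            rec = smith_waterman(q.residues, s.residues)
            if rec is not None:
                rec.query_id = q.record_id
                rec.subject_id = s.record_id
                out.append(rec)
    return out


# ---------------------------------------------------------------------------
# blast engine

def _write_fasta(seqs: Sequence[AnnotatedSequence], path: Path) -> None:
    with open(path, "w") as fh:
        for s in seqs:
            fh.write(f">{s.record_id}\n{s.residues}\n")


def _all_vs_all_blast(
    seqs: Sequence[AnnotatedSequence], task: str | None = None
) -> list[SimilarityRecord]:
    if shutil.which("blastn") is None or shutil.which("makeblastdb") is None:
        raise SimilarityError(
            "blastn/makeblastdb not on PATH; use engine='native'"
        )
    if task is None:
        # megablast's 28-bp seed misses hits between divergent sequences
        # (inter-order pairs); the classic 11-bp word finds every pair
        task = "blastn"
    with tempfile.TemporaryDirectory() as tmp:
        tmp = Path(tmp)
        fasta = tmp / "db.fasta"
        _write_fasta(seqs, fasta)
        subprocess.run(
            ["makeblastdb", "-in", str(fasta), "-dbtype", "nucl"],
            check=True, capture_output=True,
        )
        res = subprocess.run(
            [
                "blastn", "-task", task, "-query", str(fasta), "-db", str(fasta),
                "-outfmt", "6", "-max_target_seqs", str(len(seqs) + 10),
                "-num_threads", "1",
            ],
            check=True, capture_output=True, text=True,
        )
    out: list[SimilarityRecord] = []
    for line in res.stdout.splitlines():
        f = line.rstrip("\n").split("\t")
        rec = SimilarityRecord(
            query_id=f[0], subject_id=f[1],
            percent_identity=float(f[2]), alignment_length=int(f[3]),
            mismatches=int(f[4]), gap_opens=int(f[5]),
            q_start=int(f[6]), q_end=int(f[7]),
            s_start=int(f[8]), s_end=int(f[9]),
            evalue=float(f[10]), bit_score=float(f[11]),
        )
        if rec.query_id != rec.subject_id:
            out.append(rec)
    return out


def all_vs_all(
    seqs: Sequence[AnnotatedSequence],
    engine: str = "native",
    task: str | None = None,
) -> list[SimilarityRecord]:
    """Local-alignment hits for every ordered pair (self-hits excluded)."""
    _validate(seqs)
    if engine == "native":
        return _all_vs_all_native(seqs)
    if engine == "blast":
        return _all_vs_all_blast(seqs, task=task)
    raise SimilarityError(f"unknown engine {engine!r}")


# ---------------------------------------------------------------------------
# filtering and pair collapse

def _surviving_pairs(records: Iterable[SimilarityRecord]) -> set[frozenset]:
    return {frozenset((r.query_id, r.subject_id)) for r in records}


def filter_records(
    records: Sequence[SimilarityRecord],
    policy: FilterPolicy,
    expected_pairs: int,
) -> tuple[list[SimilarityRecord], float]:
    """Drop mismatched/short-matched hits; return survivors + retention rate.

    ``SORTED_GAP`` sorts hits by alignment length and looks for the largest
    gap between consecutive lengths whose lower side is below 50% of the
    median length; everything below the gap is dropped.  The strategy
    demands 100% retention of the expected unordered pairs — if the gap is
    ambiguous (retention would fall short, or short hits grade continuously
    into valid ones) it raises :class:`AmbiguousGapError` instructing an
    explicit ``FIXED_CUTOFF``.

    ``FIXED_CUTOFF`` drops hits shorter than ``min_alignment_length``.

    The retention rate is the fraction of ``expected_pairs`` unordered
    pairs still represented by at least one surviving hit.
    """
    records = list(records)
    if not records:
        return [], 0.0
    if policy.strategy == "FIXED_CUTOFF":
        kept = [
            r for r in records if r.alignment_length >= policy.min_alignment_length
        ]
    else:
        lengths = np.sort(np.array([r.alignment_length for r in records]))
        median = float(np.median(lengths))
        diffs = np.diff(lengths)
        candidates = [
            (int(diffs[k]), k) for k in range(len(diffs))
            if lengths[k] < 0.5 * median and diffs[k] > 0
        ]
        if not candidates:
            kept = records  # no short-length cluster at all
        else:
            gap, k = max(candidates)
            cutoff = int(lengths[k + 1])
            kept = [r for r in records if r.alignment_length >= cutoff]
            retention = len(_surviving_pairs(kept)) / expected_pairs
            if retention < 1.0:
                raise AmbiguousGapError(
                    f"section {policy.section_name}: sorted-length gap at "
                    f"{cutoff} bp retains only {100 * retention:.1f}% of "
                    f"expected pairs; re-run with FIXED_CUTOFF and an "
                    f"explicit min_alignment_length"
                )
    retention = len(_surviving_pairs(kept)) / expected_pairs if expected_pairs else 0.0
    return kept, retention


def collapse_pairs(records: Iterable[SimilarityRecord]) -> dict[tuple[str, str], float]:
    """One percent identity per unordered pair.

    Among all surviving hits of a pair (both directions, all HSPs), keep
    the percent identity of the highest-bit-score hit; ties broken by
    higher percent identity.
    """
    best: dict[tuple[str, str], SimilarityRecord] = {}
    for rec in records:
        key = tuple(sorted((rec.query_id, rec.subject_id)))
        cur = best.get(key)
        if cur is None or (rec.bit_score, rec.percent_identity) > (
            cur.bit_score, cur.percent_identity
        ):
            best[key] = rec
    return {k: v.percent_identity for k, v in best.items()}


# ---------------------------------------------------------------------------
# tabular I/O

def records_to_frame(records: Iterable[SimilarityRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.as_tuple() for r in records], columns=OUTFMT6_COLUMNS)


def write_records(records: Iterable[SimilarityRecord], path) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(
                f"{r.query_id}\t{r.subject_id}\t{r.percent_identity:.2f}\t"
                f"{r.alignment_length}\t{r.mismatches}\t{r.gap_opens}\t"
                f"{r.q_start}\t{r.q_end}\t{r.s_start}\t{r.s_end}\t"
                f"{r.evalue:.2e}\t{r.bit_score:.1f}\n"
            )


def read_records(path) -> list[SimilarityRecord]:
    df = pd.read_csv(path, sep="\t", header=None, names=OUTFMT6_COLUMNS)
    return [
        SimilarityRecord(
            query_id=str(r.query_id), subject_id=str(r.subject_id),
            percent_identity=float(r.percent_identity),
            alignment_length=int(r.alignment_length),
            mismatches=int(r.mismatches), gap_opens=int(r.gap_opens),
            q_start=int(r.q_start), q_end=int(r.q_end),
            s_start=int(r.s_start), s_end=int(r.s_end),
            evalue=float(r.evalue), bit_score=float(r.bit_score),
        )
        for r in df.itertuples(index=False)
    ]
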