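"""Local-alignment engine, length filtering and pair collapse."""

import random

import numpy as np
import pytest

from conftest import make_lineage, make_records
from taxores.similarity import (
    GAP_EXTEND,
    GAP_OPEN,
    MATCH,
    MISMATCH,
    AmbiguousGapError,
    FilterPolicy,
    SimilarityError,
    SimilarityRecord,
    all_vs_all,
    collapse_pairs,
    filter_records,
    read_records,
    smith_waterman,
    write_records,
)


def gotoh_oracle_score(a: str, b: str) -> int:
    """Plain-python affine-gap local alignment score (independent oracle)."""
    m, n = len(a), len(b)
    NEG = -(10**9)
    H = [[0] * (n + 1) for _ in range(m + 1)]
    E = [[NEG] * (n + 1) for _ in range(m + 1)]
    F = [[NEG] * (n + 1) for _ in range(m + 1)]
    best = 0
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            E[i][j] = max(H[i][j - 1] - GAP_OPEN - GAP_EXTEND, E[i][j - 1] - GAP_EXTEND)
            F[i][j] = max(H[i - 1][j] - GAP_OPEN - GAP_EXTEND, F[i - 1][j] - GAP_EXTEND)
            s = MATCH if a[i - 1] == b[j - 1] else MISMATCH
            H[i][j] = max(0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


def record_score(rec: SimilarityRecord) -> int:
    """Reconstruct the DP score from the reported alignment statistics."""
    gap_cols = rec.alignment_length - rec.n_identities - rec.mismatches
    return (
        MATCH * rec.n_identities
        + MISMATCH * rec.mismatches
        - GAP_OPEN * rec.gap_opens
        - GAP_EXTEND * gap_cols
    )


def test_identical_sequences_full_length_identity():
    seq = "ACGTACGTAC" * 15
    rec = smith_waterman(seq, seq)
    assert rec.percent_identity == 100.00
    assert rec.alignment_length == 150
    assert (rec.q_start, rec.q_end) == (1, 150)
    assert rec.mismatches == 0 and rec.gap_opens == 0


def test_smith_waterman_matches_gotoh_oracle():
    """Native engine reproduces a quadratic brute-force oracle's score
    on random pairs and pairs with planted shared segments (<=200 bp)."""
    random.seed(7)
    for trial in range(20):
        a = "".join(random.choice("ACGT") for _ in range(random.randint(30, 150)))
        b = "".join(random.choice("ACGT") for _ in range(random.randint(30, 150)))
        if trial % 2 == 0:
            seg = "".join(random.choice("ACGT") for _ in range(30))
            a = a[:10] + seg + a[10:]
            mutated = seg[:14] + ("A" if seg[14] != "A" else "C") + seg[15:]
            b = b[:5] + mutated + b[5:]
        rec = smith_waterman(a, b)
        expected = gotoh_oracle_score(a, b)
        if rec is None:
            assert expected <= 0
        else:
            assert record_score(rec) == expected


def test_smith_waterman_planted_duplication_identity():
    random.seed(11)
    core = "".join(random.choice("ACGT") for _ in range(30))
    a = "TTTTTTTTTT" + core + "TTTTTTTTTT"
    b = "GGGGGGGGGG" + core + "GGGGGGGGGG"
    rec = smith_waterman(a, b)
    assert rec.alignment_length >= 30
    assert rec.n_identities >= 30
    assert record_score(rec) == gotoh_oracle_score(a, b)


def test_all_vs_all_excludes_self_hits_and_validates_alphabet():
    recs = make_records([("a", "ACGTACGTACGTACGT"), ("b", "ACGTACGTACGTACGT")])
    hits = all_vs_all(recs, engine="native")
    assert all(h.query_id != h.subject_id for h in hits)
    assert {(h.query_id, h.subject_id) for h in hits} == {("a", "b"), ("b", "a")}
    bad = make_records([("a", "ACGT!!"), ("b", "ACGT")])
    with pytest.raises(SimilarityError, match="non-IUPAC"):
        all_vs_all(bad)


def test_native_and_blast_engines_agree_on_small_fixture(rng):
    """Percent identities from the two engines agree closely for
    moderately diverged full-length pairs."""
    base = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 400)])
    seqs = []
    for i in range(4):
        arr = np.array(list(base))
        mut = rng.random(400) < 0.03 * i
        arr[mut] = [
            "ACGT"[(("ACGT".index(c)) + 1) % 4] for c in arr[mut]
        ]
        seqs.append((f"s{i}", "".join(arr)))
    recs = make_records(seqs)
    native = collapse_pairs(all_vs_all(recs, engine="native"))
    blast = collapse_pairs(all_vs_all(recs, engine="blast"))
    assert set(native) == set(blast)
    for pair in native:
        assert native[pair] == pytest.approx(blast[pair], abs=1.0)


def _hit(q, s, length, pct=99.0, bit=100.0):
    return SimilarityRecord(q, s, pct, length, 1, 0, 1, length, 1, length, 1e-50, bit)


def test_filter_sorted_gap_removes_short_mismatch():
    # a 19 bp spurious hit among full-length (~1700 bp) hits
    records = [
        _hit("a", "b", 1700), _hit("b", "a", 1698),
        _hit("a", "c", 1705), _hit("c", "a", 1703),
        _hit("b", "c", 1690), _hit("c", "b", 1692),
        _hit("a", "b", 19, pct=89.47, bit=30.0),
    ]
    kept, retention = filter_records(records, FilterPolicy("whole"), expected_pairs=3)
    assert all(r.alignment_length > 100 for r in kept)
    assert retention == 1.0


def test_filter_fixed_cutoff_boundary_values():
    # cutoff 100: a 67 bp hit removed, a 104 bp hit kept
    records = [
        _hit("a", "b", 104), _hit("b", "a", 104),
        _hit("a", "c", 130), _hit("c", "a", 130),
        _hit("b", "c", 67), _hit("b", "c", 125), _hit("c", "b", 125),
    ]
    policy = FilterPolicy("section3", "FIXED_CUTOFF", 100)
    kept, retention = filter_records(records, policy, expected_pairs=3)
    assert {r.alignment_length for r in kept} == {104, 125, 130}
    assert retention == 1.0


def test_filter_all_full_length_retained():
    records = [_hit("a", "b", 500), _hit("a", "c", 505), _hit("b", "c", 498)]
    kept, retention = filter_records(records, FilterPolicy("s"), expected_pairs=3)
    assert len(kept) == 3 and retention == 1.0


def test_filter_sorted_gap_ambiguous_raises():
    # short hits grade continuously into valid ones and orphan a pair
    records = [
        _hit("a", "b", 500), _hit("a", "c", 480), _hit("b", "d", 490),
        _hit("c", "d", 200), _hit("a", "d", 30), _hit("b", "c", 20),
    ]
    with pytest.raises(AmbiguousGapError, match="FIXED_CUTOFF"):
        filter_records(records, FilterPolicy("s"), expected_pairs=6)


def test_filter_never_removes_near_full_coverage(rng):
    """Any hit covering >=90% of the shortest section sequence survives."""
    min_len = 120
    long_lengths = list(rng.integers(int(0.9 * min_len), 140, size=30))
    records = [_hit(f"q{i}", f"s{i}", int(L)) for i, L in enumerate(long_lengths)]
    # spurious short hits duplicating existing pairs
    records += [_hit("q0", "s0", 12), _hit("q1", "s1", 15), _hit("q2", "s2", 18)]
    lengths = long_lengths + [12, 15, 18]
    kept, _ = filter_records(records, FilterPolicy("s"), expected_pairs=30)
    surviving = {r.alignment_length for r in kept}
    assert all(L in surviving for L in lengths if L >= 0.9 * min_len)


def test_collapse_pairs_rules():
    # symmetric duplicates -> one value; best bit score wins
    records = [
        _hit("a", "b", 100, pct=97.0, bit=250.0),
        _hit("b", "a", 100, pct=97.0, bit=250.0),
        _hit("a", "b", 40, pct=99.0, bit=80.0),
    ]
    pairs = collapse_pairs(records)
    assert pairs == {("a", "b"): 97.0}


def test_collapse_pairs_matches_per_pair_max_oracle(rng):
    ids = [f"r{i}" for i in range(10)]
    records = []
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            for _ in range(int(rng.integers(1, 4))):
                records.append(
                    _hit(
                        *(rng.permutation([a, b])),
                        int(rng.integers(50, 300)),
                        pct=float(np.round(rng.uniform(70, 100), 2)),
                        bit=float(np.round(rng.uniform(10, 500), 1)),
                    )
                )
    got = collapse_pairs(records)
    assert len(got) == 45
    # brute-force reduction
    for (a, b), value in got.items():
        cand = [
            r for r in records if {r.query_id, r.subject_id} == {a, b}
        ]
        best = max(cand, key=lambda r: (r.bit_score, r.percent_identity))
        assert value == best.percent_identity


def test_records_tabular_round_trip(tmp_path):
    recs = make_records([("a", "ACGTACGTACGTACGTACGT"), ("b", "ACGTACGAACGTACGTACGT")])
    hits = all_vs_all(recs, engine="native")
    path = tmp_path / "hits.tsv"
    write_records(hits, path)
    loaded = read_records(path)
    assert len(loaded) == len(hits)
    for got, want in zip(loaded, hits):
        assert got.as_tuple()[:10] == want.as_tuple()[:10]
        assert got.evalue == pytest.approx(want.evalue, rel=0.01)
        assert got.bit_score == pytest.approx(want.bit_score, abs=0.05)
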