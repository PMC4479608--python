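"""Entropy, site classification, p-distance, primers and sections."""

import math

import numpy as np
import pytest

from conftest import make_alignment
from taxores.regions import (
    Region,
    RegionError,
    RegionMap,
    SectionSpec,
    UndefinedDistanceError,
    classify_sites,
    column_entropy,
    entropy_profile,
    extract_section,
    gc_content,
    locate_primer,
    p_distance,
    region_distance_summary,
    reverse_complement,
)

# ---------------------------------------------------------------------------
# entropy


@pytest.mark.parametrize(
    "column_states, expected",
    [
        ("AAAA", 0.0),
        ("AACC", 1.0),
        ("ACGT", 2.0),
        ("AAC-", -(2 / 3 * math.log2(2 / 3) + 1 / 3 * math.log2(1 / 3))),
        ("A-N.", 0.0),  # single unambiguous state
        ("----", 0.0),  # empty column, flagged via entropy_profile
    ],
)
def test_column_entropy_known_values(column_states, expected):
    aln = make_alignment([c * 3 for c in column_states])
    assert column_entropy(aln, 0) == pytest.approx(expected)
    assert column_entropy(aln, 2) == pytest.approx(expected)


def test_column_entropy_row_permutation_invariant(random_alignment, rng):
    perm = rng.permutation(len(random_alignment.rows))
    shuffled = make_alignment(
        [random_alignment.rows[i].residues for i in perm]
    )
    for col in range(random_alignment.n_columns):
        assert column_entropy(shuffled, col) == pytest.approx(
            column_entropy(random_alignment, col)
        )


def test_entropy_zero_iff_monomorphic(random_alignment):
    for col in range(random_alignment.n_columns):
        counts = random_alignment.column_counts(col)
        mono = (counts > 0).sum() <= 1
        assert (column_entropy(random_alignment, col) == 0.0) == mono


def test_entropy_profile_trend_constant():
    aln = make_alignment(["ACACACAC", "ACACACAC", "GTGTGTGT", "GTGTGTGT"])
    prof = entropy_profile(aln, window=4)
    assert np.allclose(prof["entropy"], 1.0)
    assert np.allclose(prof["trend"], 1.0)


def test_entropy_profile_alternating_columns():
    # columns alternate 0-bit and 2-bit; window 2 averages to 1.0
    rows = ["AA", "AC", "AG", "AT"]
    aln = make_alignment([r * 4 for r in rows])  # 8 columns: A?,A?,...
    prof = entropy_profile(aln, window=2)
    assert np.allclose(prof["trend"], 1.0)


def test_entropy_profile_matches_block_mean_oracle(random_alignment):
    window = 7
    prof = entropy_profile(random_alignment, window=window)
    ent = prof["entropy"].to_numpy()
    for k in range(math.ceil(random_alignment.n_columns / window)):
        block = ent[k * window : (k + 1) * window]
        got = prof.loc[prof["block"] == k, "trend"].unique()
        assert len(got) == 1
        assert got[0] == pytest.approx(block.mean())


def test_entropy_profile_window_exceeds_alignment():
    aln = make_alignment(["ACGT", "ACGT"])
    with pytest.raises(RegionError, match="window exceeds"):
        entropy_profile(aln, window=5)


# ---------------------------------------------------------------------------
# site classification


def test_classify_sites_identical_sequences():
    aln = make_alignment(["ACGTACGT"] * 4)
    st = classify_sites(aln, (0, 8))
    assert st.n_variable == 0
    assert st.n_conserved == st.n_total_sites == 8
    assert st.n_parsimony_informative == 0


def test_classify_sites_pi_definition():
    # column 0: A,A,C,C -> variable and PI; column 1: A,A,A,C -> variable only
    aln = make_alignment(["AA", "AA", "CA", "CC"])
    st = classify_sites(aln, (0, 2))
    assert st.n_total_sites == 2
    assert st.n_variable == 2
    assert st.n_parsimony_informative == 1


def test_classify_sites_all_gap_column_in_remainder():
    aln = make_alignment(["A-G", "A-G", "A-G", "A-C"])
    st = classify_sites(aln, (0, 3))
    assert st.n_total_sites == 3
    assert st.n_conserved == 1
    assert st.n_variable == 1
    assert st.n_remainder == 1


def test_classify_sites_counts_invariants(random_alignment):
    st = classify_sites(random_alignment, (0, random_alignment.n_columns))
    assert st.n_parsimony_informative <= st.n_variable
    assert st.n_variable + st.n_conserved <= st.n_total_sites


def test_classify_sites_empty_interval():
    aln = make_alignment(["ACGT", "ACGT"])
    with pytest.raises(RegionError):
        classify_sites(aln, (2, 2))


@pytest.mark.parametrize(
    "seqs, expected",
    [(["GGCC", "GGCC"], 100.0), (["ATAT", "ATAT"], 0.0), (["ACGT", "ACGT"], 50.0)],
)
def test_gc_content_known_values(seqs, expected):
    aln = make_alignment(seqs)
    assert gc_content(aln, (0, 4)) == pytest.approx(expected)


def test_gc_content_requires_unambiguous_bases():
    aln = make_alignment(["NN--", "--NN"])
    with pytest.raises(RegionError):
        gc_content(aln, (0, 4))


# ---------------------------------------------------------------------------
# p-distance


@pytest.mark.parametrize(
    "a, b, expected",
    [
        ("ACGT", "ACGT", 0.0),
        ("ACGT", "ACGA", 0.25),
        ("A-GT", "ACGA", 1 / 3),
        ("ANGT", "ACGA", 1 / 3),
    ],
)
def test_p_distance_known_values(a, b, expected):
    assert p_distance(a, b) == pytest.approx(expected)
    assert p_distance(b, a) == pytest.approx(expected)


def test_p_distance_undefined():
    with pytest.raises(UndefinedDistanceError):
        p_distance("----", "ACGT")


def test_p_distance_premetric_properties(rng):
    chars = np.array(list("ACGT-N"))
    for _ in range(25):
        a = "".join(chars[rng.integers(0, 6, size=40)])
        b = "".join(chars[rng.integers(0, 6, size=40)])
        assert p_distance(a, a) == 0.0
        try:
            d = p_distance(a, b)
        except UndefinedDistanceError:
            continue
        assert 0.0 <= d <= 1.0
        assert d == pytest.approx(p_distance(b, a))


def test_region_distance_summary_identical_records():
    aln = make_alignment(["ACGTACGT", "ACGTACGT"])
    rm = RegionMap([Region("V1", 0, 4), Region("V2", 4, 8)])
    df = region_distance_summary(aln, rm)
    assert (df["mean"] == 0).all()
    assert (df["sd"] == 0).all()


def test_region_distance_summary_matches_double_loop_oracle(rng):
    chars = np.array(list("ACGT-"))
    seqs = ["".join(chars[rng.integers(0, 5, size=30)]) for _ in range(5)]
    aln = make_alignment(seqs)
    rm = RegionMap([Region("V1", 2, 12), Region("V2", 15, 28)])
    df = region_distance_summary(aln, rm, include_combined=False).set_index("region")
    for name, (s, e) in {"V1": (2, 12), "V2": (15, 28)}.items():
        dists = []
        for i in range(5):
            for j in range(i + 1, 5):
                try:
                    dists.append(p_distance(seqs[i][s:e], seqs[j][s:e]))
                except UndefinedDistanceError:
                    pass
        assert df.loc[name, "mean"] == pytest.approx(np.mean(dists))
        assert df.loc[name, "sd"] == pytest.approx(np.std(dists, ddof=1))
        assert df.loc[name, "n_pairs"] == len(dists)


# ---------------------------------------------------------------------------
# primers and sections


def test_locate_primer_exact_and_iupac():
    seq = "TTTTACGTACGGGG"
    assert locate_primer(seq, "ACGTACG", 0) == (4, 11)
    assert locate_primer(seq, "ACNTACG", 0) == (4, 11)  # N matches anything
    assert locate_primer(seq, "RCGTACG", 0) == (4, 11)  # R matches A/G
    assert locate_primer(seq, "CCCCCCC", 0) is None
    # two mismatches tolerated at max_mismatches=2 only
    assert locate_primer(seq, "AGGTACG", 1) == (4, 11)
    assert locate_primer(seq, "AGGAACG", 1) is None
    assert locate_primer(seq, "AGGAACG", 2) == (4, 11)


def _section_fixture():
    #            FWD......          V.........          RC(REV)...
    ref = "AAAA" + "ACGTACGT" + "CC" + "TTTTGGGG" + "CC" + "GTGTGTGT" + "AAAA"
    full = ref
    # record missing the first 3 bp of the section (columns 4-6)
    slack5 = "-------" + full[7:]
    # record with a gap spanning half of the V region
    gappy = full[:14] + "-----" + full[19:]
    aln = make_alignment([full, full, slack5, gappy])
    rm = RegionMap([Region("V1", 14, 22)])
    spec_strict = SectionSpec(
        "sec", "ACGTACGT", reverse_complement("GTGTGTGT"),
        required_regions=("V1",), end_slack_allowed=False,
    )
    spec_slack = SectionSpec(
        "sec", "ACGTACGT", reverse_complement("GTGTGTGT"),
        required_regions=("V1",), end_slack_allowed=True,
    )
    return aln, rm, spec_strict, spec_slack


def test_extract_section_full_coverage():
    aln, rm, spec, _ = _section_fixture()
    ext = extract_section(aln, spec, rm, reference_id="r0")
    assert ext.columns == (4, 32)
    ids = [r.record_id for r in ext.records]
    assert "r0" in ids and "r1" in ids
    for rec in ext.records:
        assert rec.residues == aln.rows[0].residues[4:32]


def test_extract_section_end_slack():
    aln, rm, strict, slack = _section_fixture()
    strict_ids = {r.record_id for r in extract_section(aln, strict, rm).records}
    slack_ids = {r.record_id for r in extract_section(aln, slack, rm).records}
    # r2 misses 3 terminal bases: rejected without slack, accepted with it
    assert "r2" not in strict_ids
    assert "r2" in slack_ids


def test_extract_section_rejects_gapped_required_region():
    aln, rm, _, slack = _section_fixture()
    ext = extract_section(aln, slack, rm)
    assert "r3" not in {r.record_id for r in ext.records}
    reasons = dict(ext.log.entries)
    assert "V1" in reasons["r3"]


def test_extract_section_by_explicit_columns():
    aln, rm, _, _ = _section_fixture()
    spec = SectionSpec("coords", required_regions=("V1",), columns=(4, 32))
    ext = extract_section(aln, spec, rm)
    assert ext.columns == (4, 32)
    assert {r.record_id for r in ext.records} >= {"r0", "r1"}


def test_section_spec_needs_primers_or_columns():
    with pytest.raises(RegionError, match="primer pair or explicit"):
        SectionSpec("bad")


def test_extract_section_unresolvable_primer():
    aln, rm, _, _ = _section_fixture()
    bad = SectionSpec("sec", "AAAAAAAAGGGGCCCC", "CCCCGGGGTTTTAAAA")
    with pytest.raises(RegionError, match="not resolvable"):
        extract_section(aln, bad, rm)
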