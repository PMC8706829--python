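"""Banded alignment, site tallies, divergence, and coding effects."""

import numpy as np
import pytest
from Bio import Align

import mitocompare as mc
from mitocompare.align import banded_align, merge_on_anchor

from conftest import make_toy_genome


def _rand_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


# --------------------------------------------------------------------------
# aligner
# --------------------------------------------------------------------------

def test_identical_sequences_align_gapless():
    rng = np.random.default_rng(0)
    s = _rand_seq(rng, 3000)
    aln = mc.align_high_identity([("a", s), ("b", s)])
    assert aln[0][1] == aln[1][1] == s


def test_planted_deletion_yields_exact_gap_columns():
    """A 9-nt deletion in the middle produces exactly 9 gap columns."""
    rng = np.random.default_rng(1)
    s = _rand_seq(rng, 5000)
    deleted = s[:2500] + s[2509:]
    aln = mc.align_high_identity([("ref", s), ("del", deleted)])
    cols = list(zip(aln[0][1], aln[1][1]))
    gap_cols = [c for c in cols if "-" in c]
    assert len(gap_cols) == 9
    assert all(b == "-" for _, b in gap_cols)


@pytest.mark.parametrize("seed", range(6))
def test_banded_score_equals_full_dp_oracle(seed):
    """Banded score equals Biopython's full dynamic program on <= 2 kb."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(200, 2000))
    s1 = _rand_seq(rng, n)
    s2 = list(s1)
    for _ in range(int(rng.integers(0, 30))):
        p = int(rng.integers(len(s2)))
        s2[p] = "ACGT"[rng.integers(4)]
    s2 = "".join(s2)
    for _ in range(int(rng.integers(0, 4))):
        p = int(rng.integers(1, len(s2) - 12))
        ln = int(rng.integers(1, 10))
        if rng.random() < 0.5:
            s2 = s2[:p] + s2[p + ln:]
        else:
            s2 = s2[:p] + _rand_seq(rng, ln) + s2[p:]
    al = Align.PairwiseAligner()
    al.mode = "global"
    al.match_score, al.mismatch_score = 1, -1
    al.open_gap_score, al.extend_gap_score = -10.5, -0.5
    score, r1, r2 = banded_align(s1, s2, band=40)
    assert score == pytest.approx(al.score(s1, s2))
    assert r1.replace("-", "") == s1 and r2.replace("-", "") == s2


def test_deletions_larger_than_band_still_align():
    """The band tracks the length difference, so one indel longer than the
    band half-width is recovered exactly."""
    rng = np.random.default_rng(2)
    s = _rand_seq(rng, 1000)
    shifted = s[:100] + s[130:]  # 30-nt deletion with band half-width 8
    score, r1, r2 = banded_align(s, shifted, band=8)
    assert r2.count("-") == 30 and r1.count("-") == 0
    assert r1.replace("-", "") == s and r2.replace("-", "") == shifted


def test_merge_on_anchor_pads_insertions():
    anchor = "ACGT"
    rows = merge_on_anchor(anchor, [("AC-GT", "ACTGT"), ("ACGT", "ACGT")])
    assert rows[0] == "AC-GT"
    assert rows[1] == "ACTGT"
    assert rows[2] == "AC-GT"


# --------------------------------------------------------------------------
# tallies
# --------------------------------------------------------------------------

def _toy_reference():
    #          0123456789...
    seq = "ATGAAATAA" + "C" * 11  # one 9-nt PCG, 11 nt intergenic
    return make_toy_genome(seq, [("nad1", "PCG", [(0, 9)])], "ref")


def test_zero_difference_alignment_is_all_zero():
    g = _toy_reference()
    aln = [("ref", g.sequence), ("x", g.sequence)]
    rep = mc.tally_sites(aln, g)
    assert (rep.indel_sites, rep.variable_sites, rep.divergence_percent) == (0, 0, 0.0)


def test_divergence_arithmetic_on_handcrafted_alignment():
    """100 columns, 2 gap columns + 3 variable columns: divergence 5.0%."""
    rng = np.random.default_rng(3)
    base = _rand_seq(rng, 100)
    g = make_toy_genome(base, [], "ref")
    other = list(base)
    for p in (10, 40, 70):
        other[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[other[p]]
    other = "".join(other)
    # introduce 2 gap columns by deleting 2 bases from the other row
    other = other[:20] + other[21:]
    other = other[:50] + other[51:]
    aln = mc.align_high_identity([("ref", base), ("x", other)], band=50)
    rep = mc.tally_sites(aln, g)
    assert rep.alignment_length == 100
    assert rep.indel_sites == 2 and rep.variable_sites == 3
    assert rep.divergence_percent == pytest.approx(5.0)


def test_sites_partition_genic_vs_intergenic():
    g = _toy_reference()
    other = list(g.sequence)
    other[4] = "G"   # genic (codon AAA -> AGA)
    other[15] = "A"  # intergenic
    aln = [("ref", g.sequence), ("x", "".join(other))]
    rep = mc.tally_sites(aln, g)
    regions = {s.ref_pos: s.region for s in rep.sites}
    assert regions == {4: "genic", 15: "intergenic"}


@pytest.mark.parametrize(
    "codon,alt_base,off,expected",
    [
        ("GGA", "G", 2, "synonymous"),     # Gly -> Gly
        ("TGA", "G", 2, "synonymous"),     # Trp -> Trp under table 4
        ("AAA", "G", 1, "nonsynonymous"),  # Lys -> Arg
    ],
)
def test_coding_effect_under_mold_mito_code(codon, alt_base, off, expected):
    seq = "ATG" + codon + "TAA" + "C" * 11
    g = make_toy_genome(seq, [("nad1", "PCG", [(0, 9)])], "ref")
    other = list(seq)
    other[3 + off] = alt_base
    aln = [("ref", seq), ("x", "".join(other))]
    rep = mc.tally_sites(aln, g)
    assert len(rep.sites) == 1
    assert rep.sites[0].effect == expected


def test_gap_disrupted_codon_is_flagged_indel_adjacent():
    seq = "ATG" + "AAA" + "TAA" + "C" * 11
    g = make_toy_genome(seq, [("nad1", "PCG", [(0, 9)])], "ref")
    # third row deletes one base of the codon; second row varies another base
    aln = [
        ("ref", seq),
        ("x", seq[:4] + "G" + seq[5:]),
        ("y", seq[:3] + "-" + seq[4:]),
    ]
    rep = mc.tally_sites(aln, g)
    effects = {s.ref_pos: s.effect for s in rep.sites if s.site_class == "variable"}
    assert effects == {4: "indel-adjacent"}
    assert rep.effect_census().get("indel-adjacent") == 1


def test_divergence_invariant_to_sequence_order(cohort):
    genome, records, _ = cohort
    aln1 = mc.align_high_identity(records)
    rep1 = mc.tally_sites(aln1, genome)
    reordered = [records[0], records[2], records[1]]
    rep2 = mc.tally_sites(mc.align_high_identity(reordered), genome)
    assert rep1.divergence_percent == pytest.approx(rep2.divergence_percent)
    assert (rep1.indel_sites, rep1.variable_sites) == (
        rep2.indel_sites, rep2.variable_sites)


def test_generator_cohort_tallies_match_plant_log(cohort):
    """Exact bookkeeping round trip on the 30.7 kb three-individual cohort."""
    genome, records, log = cohort
    rep = mc.tally_sites(mc.align_high_identity(records), genome)
    assert rep.variable_sites == log.expected_variable_sites
    assert rep.indel_sites == log.expected_indel_columns
    # per-site truth: every planted substitution appears at its position with
    # the effect computed at plant time
    got = {s.ref_pos: s for s in rep.sites if s.site_class == "variable"}
    for sub in log.substitutions:
        site = got[sub["pos"]]
        assert site.region == sub["region"]
        if sub["effect"] in ("synonymous", "nonsynonymous", "noncoding"):
            assert site.effect == sub["effect"], sub
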