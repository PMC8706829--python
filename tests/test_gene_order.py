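"""Signed circular gene orders: canonicalization and pattern classification."""

import numpy as np
import pytest

import mitocompare as mc
from mitocompare.gene_order import GeneOrderSignature, canonicalize

from conftest import make_toy_genome


def sig(taxon, tokens, missing=frozenset()):
    return GeneOrderSignature.from_strings(taxon, tokens, missing=missing)


def test_canonicalize_rotates_to_rnl():
    s = canonicalize(sig("t", ["nad2", "rnl", "cox1"]))
    assert s.as_strings() == ["rnl", "cox1", "nad2"]


def test_canonicalize_is_identity_on_canonical_input():
    s = sig("t", ["rnl", "cox1", "nad2"])
    assert canonicalize(s).as_strings() == s.as_strings()


def test_canonicalize_quotients_rotation_and_reflection():
    """All rotations and the reflected form of random signed 16-gene orders
    map to a single canonical form (brute force over all rotations)."""
    rng = np.random.default_rng(42)
    genes = list(mc.CORE_GENES)
    for rep in range(50):
        perm = list(rng.permutation(genes))
        signs = rng.choice([1, -1], size=16, p=[0.8, 0.2])
        symbols = list(zip(perm, (int(s) for s in signs)))
        base = canonicalize(GeneOrderSignature("t", symbols))
        forms = set()
        for rot in range(16):
            rotated = symbols[rot:] + symbols[:rot]
            forms.add(tuple(canonicalize(GeneOrderSignature("t", rotated)).symbols))
            reflected = [(g, -s) for g, s in reversed(rotated)]
            forms.add(tuple(canonicalize(GeneOrderSignature("t", reflected)).symbols))
        assert forms == {tuple(base.symbols)}, rep


def test_extract_order_roundtrip_and_trn_track(default_genome):
    genome, log = default_genome
    s = mc.extract_order(genome, with_trn=True)
    expected_core = [g for g in log.gene_order
                     if not g.startswith(("trn", "orf"))]
    assert [g for g, _ in s.symbols] == expected_core
    assert all(sign == 1 for _, sign in s.symbols)
    assert s.missing == frozenset()
    assert len([g for g, _ in s.trn_track if g.startswith("trn")]) == 28


def test_extract_order_records_missing_genes():
    g = make_toy_genome(
        "A" * 100,
        [("rnl", "rRNA", [(0, 20)]), ("nad2", "PCG", [(30, 60)])],
    )
    s = mc.extract_order(g)
    assert {"nad1", "nad4"} <= s.missing
    assert "nad2" not in s.missing


def test_duplicated_core_gene_raises():
    g = make_toy_genome(
        "A" * 100,
        [("cox1", "PCG", [(0, 20)]), ("cox1_b", "PCG", [(30, 60)])],
    )
    g.features[1].name = "cox1"  # force a duplicate past disambiguation
    with pytest.raises(mc.MitoError, match="cox1"):
        mc.extract_order(g)


def test_classify_all_identical_is_one_pattern():
    sigs = [sig(f"t{i}", ["rnl", "cox1", "nad2", "nad3"]) for i in range(5)]
    pats = mc.classify_patterns(sigs)
    assert len(pats) == 1
    assert pats[0].pattern_label == "A" and pats[0].size == 5


def test_classify_translocation_names_the_gene():
    dominant = ["rnl", "nad2", "nad3", "cob", "cox1", "nad1"]
    moved = ["rnl", "cox1", "nad2", "nad3", "cob", "nad1"]
    sigs = [sig(f"t{i}", dominant) for i in range(3)] + [sig("tx", moved)]
    pats = mc.classify_patterns(sigs)
    assert [p.pattern_label for p in pats] == ["A", "B"]
    assert pats[0].size == 3 and pats[1].size == 1
    assert "cox1" in pats[1].description


def test_partial_signature_joins_reduced_pattern():
    dominant = ["rnl", "nad2", "nad3", "cob", "cox1", "nad1"]
    partial = ["rnl", "nad2", "cob", "cox1", "nad1"]  # nad3 missing
    sigs = [sig(f"t{i}", dominant) for i in range(3)] + [
        sig("tp", partial, missing=frozenset({"nad3"}))
    ]
    pats = mc.classify_patterns(sigs)
    assert len(pats) == 1
    assert "tp" in pats[0].member_taxa
    assert "nad3" in pats[0].partial_members["tp"]


def test_pattern_grouping_equals_all_pairs_oracle():
    """Grouping equals the brute-force all-pairs canonical-equality oracle on
    20 synthetic signatures."""
    rng = np.random.default_rng(3)
    genes = list(mc.CORE_GENES)
    base = genes
    pool = []
    for i in range(20):
        symbols = list(base)
        if rng.random() < 0.5:  # translocate one gene
            symbols = symbols.copy()
            g = symbols.pop(int(rng.integers(1, 16)))
            symbols.insert(int(rng.integers(1, 15)), g)
        rot = int(rng.integers(16))
        symbols = symbols[rot:] + symbols[:rot]
        pool.append(sig(f"t{i}", symbols))
    pats = mc.classify_patterns(pool)
    # oracle: canonical equality classes
    canon = {s.taxon: tuple(canonicalize(s).symbols) for s in pool}
    oracle_groups = {}
    for taxon, c in canon.items():
        oracle_groups.setdefault(c, set()).add(taxon)
    got_groups = {frozenset(p.member_taxa) for p in pats}
    assert got_groups == {frozenset(v) for v in oracle_groups.values()}
    # labels by descending size
    sizes = [p.size for p in pats]
    assert sizes == sorted(sizes, reverse=True)


def test_pattern_count_monotone_under_addition():
    rng = np.random.default_rng(11)
    genes = list(mc.CORE_GENES)
    sigs = []
    prev = 0
    for i in range(12):
        symbols = list(rng.permutation(genes)) if i % 3 == 0 else list(genes)
        sigs.append(sig(f"t{i}", symbols))
        n = len(mc.classify_patterns(sigs))
        assert n >= prev
        prev = n


def test_classify_is_rotation_invariant(default_genome):
    genome, _ = default_genome
    s0 = mc.extract_order(genome)
    s1 = mc.extract_order(genome.rotated(17000))
    s1 = GeneOrderSignature("rot", s1.symbols, missing=s1.missing)
    pats = mc.classify_patterns([s0, s1])
    assert len(pats) == 1 and pats[0].size == 2


def test_trn_cluster_report(default_genome):
    genome, _ = default_genome
    s = mc.extract_order(genome, with_trn=True)
    df = mc.trn_cluster_report([s])
    counts = df[genome.id]
    assert counts.loc["rnl->cox1"] == 13
    assert counts.loc["rns->cox3"] == 5
    assert counts.loc["nad6->cob"] == 5
    assert not df["variable"].any()


def test_trn_cluster_flags_variable_interval():
    a = sig("a", ["rnl", "trnA", "trnB", "nad2", "cob"])
    a.trn_track = a.symbols
    b = sig("b", ["rnl", "trnA", "nad2", "trnB", "cob"])
    b.trn_track = b.symbols
    # keep only core genes in .symbols for canonicalization
    for s in (a, b):
        s.trn_track = s.symbols
        s.symbols = [(g, sg) for g, sg in s.symbols if not g.startswith("trn")]
    df = mc.trn_cluster_report([a, b])
    assert bool(df.loc["rnl->nad2", "variable"])
    assert bool(df.loc["nad2->cob", "variable"])
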