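"""Positional intron nomenclature, boundaries, ORF detection, identity."""

import numpy as np
import pytest

import mitocompare as mc
from mitocompare.introns import classify_orf_product, intron_name
from mitocompare.translate import stop_codons, translate


def _rand_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


def test_intron_name_prefixes():
    assert intron_name("rnl", 2450) == "mL2450"
    assert intron_name("rns", 379) == "mS379"
    assert intron_name("cox1", 1125) == "cox1P1125"
    assert intron_name("cox1_1", 212) == "cox1P212"
    with pytest.raises(mc.MitoError):
        intron_name("cox1", 0)


def test_locate_insertion_identity_alignment():
    rng = np.random.default_rng(5)
    ref = _rand_seq(rng, 3000)
    assert mc.locate_insertion(ref, 2450, ref) == 2450


def test_locate_insertion_with_host_deletion():
    """A 3-base deletion upstream of the junction shifts the reference
    coordinate: host base 100 aligns to reference base 103."""
    rng = np.random.default_rng(6)
    ref = _rand_seq(rng, 400)
    host = ref[:50] + ref[53:]  # 3-base deletion upstream
    assert mc.locate_insertion(host, 100, ref) == 103


def test_locate_insertion_below_identity_threshold_is_an_error():
    rng = np.random.default_rng(7)
    a, b = _rand_seq(rng, 300), _rand_seq(rng, 300)
    # unrelated sequences align around 40-45% identity: reject at a stricter
    # threshold, and also when the sequences share no composition at all
    with pytest.raises(mc.MitoError, match="identity"):
        mc.locate_insertion(a, 100, b, min_identity=90.0)
    with pytest.raises(mc.MitoError, match="identity"):
        mc.locate_insertion("A" * 300, 100, "G" * 300)


def test_locate_insertion_recovers_planted_position_under_divergence():
    """With <= 5% exon divergence the planted coordinate is recovered exactly
    in >= 95% of 100 seeded replicates."""
    hits = 0
    for rep in range(100):
        rng = np.random.default_rng(rep)
        ref = _rand_seq(rng, 2000)
        host = list(ref)
        n_mut = int(0.05 * len(host) * rng.random())
        for p in rng.choice(len(host), size=n_mut, replace=False):
            host[p] = "ACGT"[rng.integers(4)]
        junction = int(rng.integers(100, 1900))
        pos = mc.locate_insertion("".join(host), junction, ref)
        hits += pos == junction
    assert hits >= 95


def test_boundary_check_rule():
    assert mc.boundary_check("CCCAG", "AAT") == (True, True)
    assert mc.boundary_check("CCCAG", "AAA") == (False, True)
    assert mc.boundary_check("CCCAA", "AAT") == (True, False)
    with pytest.raises(mc.MitoError):
        mc.boundary_check("", "AAT")


def test_generator_planted_introns_pass_boundary_check(default_genome):
    genome, _ = default_genome
    refs = {
        "rnl": genome.spliced(genome.get("rnl")),
        "cox1": genome.spliced(genome.get("cox1")),
    }
    recs = mc.catalog_introns(genome, refs)
    assert {r.name for r in recs} == {"mL2450", "cox1P1125"}
    assert all(r.boundary_ok == (True, True) for r in recs)
    by_name = {r.name: r for r in recs}
    assert by_name["mL2450"].orf_class == "rps3"
    assert by_name["cox1P1125"].orf_class == "LAGLIDADG"


def _orf_oracle(seq, min_nt, stops):
    """Independent brute force: every maximal ATG->stop ORF per (frame, stop),
    then containment suppression."""
    found = []
    for frame in range(3):
        i = frame
        last_stop = frame - 3
        atg = None
        while i + 3 <= len(seq):
            codon = seq[i:i + 3]
            if codon == "ATG" and atg is None:
                atg = i
            if codon in stops:
                if atg is not None and i + 3 - atg >= min_nt:
                    found.append((atg, i + 3))
                atg = None
            i += 3
    found.sort(key=lambda o: (-(o[1] - o[0]), o[0]))
    kept = []
    for s, e in found:
        if not any(ks <= s and e <= ke for ks, ke in kept):
            kept.append((s, e))
    return sorted(kept)


@pytest.mark.parametrize("seed", range(8))
def test_find_orfs_equals_bruteforce_oracle(seed):
    rng = np.random.default_rng(seed)
    seq = _rand_seq(rng, 4000)
    got = sorted((s, e) for _, s, e in mc.find_orfs(seq, min_nt=300))
    assert got == _orf_oracle(seq, 300, stop_codons(4))


def test_find_orfs_names_by_aa_length_and_handles_empty():
    rng = np.random.default_rng(9)
    # a clean 1353-nt ORF (450 aa) framed by stops
    inner = mc.synthetic._make_orf(rng, 1353, 50.0, None)
    region = "TAATAA" + inner + "TAA"
    orfs = mc.find_orfs(region, min_nt=300)
    assert ("orf450", 6, 6 + 1353) in orfs
    assert mc.find_orfs("TAA" * 200, min_nt=300) == []


def test_orf_motif_classification():
    rng = np.random.default_rng(10)
    lag = mc.synthetic._make_orf(rng, 900, 50.0, "LAGLIDADG")
    giy = mc.synthetic._make_orf(rng, 900, 50.0, "GIY-YIG")
    plain = mc.synthetic._make_orf(rng, 900, 50.0, None)
    assert classify_orf_product(lag) == "LAGLIDADG"
    assert classify_orf_product(giy) == "GIY-YIG"
    assert classify_orf_product(plain) == "unknown"


def test_identity_matrix_values():
    rng = np.random.default_rng(11)
    seq = _rand_seq(rng, 1000)
    mutated = list(seq)
    for p in rng.choice(1000, size=100, replace=False):  # 10% substitutions
        cur = mutated[p]
        mutated[p] = "ACGT"[("ACGT".index(cur) + 1) % 4]
    mutated = "".join(mutated)
    seqs = {
        "t1": {"mL2450": seq},
        "t2": {"mL2450": seq},
        "t3": {"mL2450": mutated, "cox1P212": seq[:500]},
    }
    m = mc.intron_identity_matrix(seqs, "mL2450")
    assert m.loc["t1", "t2"] == 100.0
    assert m.loc["t1", "t3"] == pytest.approx(90.0, abs=1.0)
    m2 = mc.intron_identity_matrix(seqs, "cox1P212")
    assert np.isnan(m2.loc["t1", "t2"])  # intron absent: empty, not 0
    assert m2.loc["t3", "t3"] == 100.0


def test_naming_is_deterministic(default_genome):
    genome, _ = default_genome
    refs = {"rnl": genome.spliced(genome.get("rnl")),
            "cox1": genome.spliced(genome.get("cox1"))}
    a = [(r.name, r.insertion_ref_pos) for r in mc.catalog_introns(genome, refs)]
    b = [(r.name, r.insertion_ref_pos) for r in mc.catalog_introns(genome, refs)]
    assert a == b
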