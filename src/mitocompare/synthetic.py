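"""Synthetic annotated mitogenomes with known ground truth.

The generator emulates compact single-strand-transcribed fungal mitogenomes:
a circular ~30 kb molecule carrying the 14 core PCGs, both rRNAs, a full tRNA
complement (clusters downstream of rnl/rns/nad6 plus scattered singletons),
free-standing ORFs, and group-I introns (upstream exon ending T, intron
ending G) hosting rps3 or homing-endonuclease ORFs.  Every random choice is
driven by one explicitly seeded RNG, and a :class:`PlantLog` records the
ground truth (gene coordinates, junction intervals, intron plants, planted
mutations, simulated node states) so downstream reports can be checked
exactly against predictions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from string import ascii_uppercase

import numpy as np

from .ancestral import CharacterStateMatrix, _load_tree, label_nodes
from .gene_order import base_name
from .model import CORE_PCGS, GeneFeature, MitoError, MitoGenome, revcomp
from .summary import genic_mask
from .translate import stop_codons, translate_codon
from .variation import _CdsIndex

# ---------------------------------------------------------------------------
# default "stachybotrys-like" layout: 14 core PCGs + 2 rRNAs + 28 tRNAs +
# 2 free ORFs; cox1 in the rnl/nad2 region; tRNA clusters downstream of
# rnl (13), rns (5) and nad6 (5); singletons at trnR/nad4L, cob/trnC,
# cox3/trnG and after atp6 and nad1
# ---------------------------------------------------------------------------

STACHYBOTRYS_LIKE_ORDER: tuple[str, ...] = (
    "rnl",
    "trnV", "trnM_1", "trnM_2", "trnL_1", "trnA", "trnF_1", "trnK",
    "trnG_1", "trnQ", "trnH", "trnM_3", "trnI", "trnP",
    "cox1",
    "nad2", "nad3",
    "orf204",
    "atp9", "cox2",
    "orf350",
    "trnR_1",
    "nad4L", "nad5", "nad4", "atp8", "atp6",
    "trnN_1",
    "rns",
    "trnW", "trnS_1", "trnN_2", "trnE", "trnY",
    "cox3",
    "trnG_2",
    "nad6",
    "trnT", "trnL_2", "trnD", "trnS_2", "trnF_2",
    "cob",
    "trnC",
    "nad1",
    "trnR_2",
)


def _build_dominant() -> tuple[str, ...]:
    """The dominant Hypocreales arrangement: cox1 between cob and nad1."""
    order = [g for g in STACHYBOTRYS_LIKE_ORDER if g != "cox1"]
    order.insert(order.index("trnC") + 1, "cox1")
    return tuple(order)


DOMINANT_ORDER: tuple[str, ...] = _build_dominant()

DEFAULT_GENE_LENGTHS: dict[str, int] = {
    "rnl": 3200, "rns": 1550,
    "nad1": 1104, "nad2": 1713, "nad3": 423, "nad4": 1482, "nad4L": 270,
    "nad5": 2001, "nad6": 651, "cob": 1161, "cox1": 1608, "cox2": 753,
    "cox3": 810, "atp6": 774, "atp8": 147, "atp9": 225,
    "orf204": 615, "orf350": 1053,
}
TRNA_LENGTH_RANGE = (71, 85)

#: genes terminated by TAG instead of TAA in the default fixture
TAG_STOPPED = ("atp9", "nad5")


@dataclass
class IntronPlant:
    host: str  # host gene symbol
    after_host_pos: int  # spliced-host position (1-based) of the last 5' exon base
    length: int
    orf_class: str | None = None  # rps3 | LAGLIDADG | GIY-YIG | None
    orf_nt: int = 0  # ORF length in nt incl. stop


DEFAULT_INTRONS: tuple[IntronPlant, ...] = (
    IntronPlant("rnl", 2450, 1800, "rps3", 1353),
    IntronPlant("cox1", 1125, 2084, "LAGLIDADG", 1953),
)


@dataclass
class GenomeSpec:
    """Recipe for one synthetic mitogenome; the defaults give the
    stachybotrys-like fixture (30.7 kb, AT 74%, 46 genes, 2 introns)."""

    genome_id: str = "synthetic_1"
    size_target: int = 30700
    gene_order: tuple[str, ...] = STACHYBOTRYS_LIKE_ORDER
    gene_lengths: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_GENE_LENGTHS)
    )
    spacer_min: int = 20
    junction_overrides: dict[tuple[str, str], int] = field(
        default_factory=lambda: {("nad4L", "nad5"): -1, ("nad2", "nad3"): 0}
    )
    introns: tuple[IntronPlant, ...] = DEFAULT_INTRONS
    at_percent: float = 74.0
    seed: int = 0


@dataclass
class PlantLog:
    """Ground truth sufficient to predict every downstream report."""

    gene_order: tuple[str, ...] = ()
    junctions: list[tuple[str, str, int]] = field(default_factory=list)
    introns: list[dict] = field(default_factory=list)
    substitutions: list[dict] = field(default_factory=list)
    indels: list[dict] = field(default_factory=list)
    node_states: dict[str, str] = field(default_factory=dict)

    @property
    def expected_indel_columns(self) -> int:
        return sum(d["length"] for d in self.indels)

    @property
    def expected_variable_sites(self) -> int:
        return len(self.substitutions)


# ---------------------------------------------------------------------------
# sequence samplers
# ---------------------------------------------------------------------------

_BASES = np.array(list("ACGT"))


def _base_probs(at_percent: float) -> np.ndarray:
    at = at_percent / 100.0
    gc = 1.0 - at
    # mild strand asymmetry: slight T excess over A, G excess over C
    return np.array([0.49 * at, 0.44 * gc, 0.56 * gc, 0.51 * at])  # A C G T


def _random_seq(rng: np.random.Generator, n: int, at_percent: float) -> str:
    if n == 0:
        return ""
    return "".join(_BASES[rng.choice(4, size=n, p=_base_probs(at_percent))])


def _random_codons(rng: np.random.Generator, n_codons: int, at_percent: float,
                   transl_table: int = 4) -> str:
    """Sense codons free of stops, sampled base-wise with the AT bias.

    Rejecting stop codons (AT-rich under table 4) depletes AT by ~1.6 points
    in coding sequence, so the sampler aims that much higher to hit the
    genome-wide target."""
    stops = stop_codons(transl_table)
    probs = _base_probs(min(at_percent + 1.6, 100.0))
    out: list[str] = []
    while len(out) < n_codons:
        codon = "".join(_BASES[rng.choice(4, size=3, p=probs)])
        if codon not in stops:
            out.append(codon)
    return "".join(out)


def _encode_protein(rng: np.random.Generator, protein: str,
                    transl_table: int = 4) -> str:
    from Bio.Data import CodonTable

    tab = CodonTable.unambiguous_dna_by_id[transl_table]
    by_aa: dict[str, list[str]] = {}
    for codon, aa in sorted(tab.forward_table.items()):
        by_aa.setdefault(aa, []).append(codon)
    return "".join(by_aa[aa][int(rng.integers(len(by_aa[aa])))] for aa in protein)


def _anticodon_for(aa: str, transl_table: int = 4) -> str:
    from Bio.Data import CodonTable

    tab = CodonTable.unambiguous_dna_by_id[transl_table]
    codons = sorted(c for c, a in tab.forward_table.items() if a == aa)
    return revcomp(codons[0]) if codons else "NNN"


_MOTIF_PROTEIN = {"LAGLIDADG": "LAGLIDADG", "GIY-YIG": "GIYKGYIG"}


def _make_orf(rng: np.random.Generator, nt_len: int, at_percent: float,
              orf_class: str | None) -> str:
    if nt_len % 3 != 0 or nt_len < 90:
        raise MitoError("ORF length must be a multiple of 3 and >= 90 nt")
    n_codons = nt_len // 3 - 2
    body = _random_codons(rng, n_codons, at_percent)
    motif = _MOTIF_PROTEIN.get(orf_class or "")
    if motif:
        enc = _encode_protein(rng, motif)
        body = enc + body[len(enc):]
    return "ATG" + body + "TAA"


def _make_pcg(rng: np.random.Generator, name: str, nt_len: int,
              at_percent: float) -> str:
    if nt_len % 3 != 0 or nt_len < 9:
        raise MitoError(f"{name}: CDS length must be a positive multiple of 3")
    stop = "TAG" if base_name(name) in TAG_STOPPED else "TAA"
    return "ATG" + _random_codons(rng, nt_len // 3 - 2, at_percent) + stop


def _make_intron(rng: np.random.Generator, plant: IntronPlant,
                 at_percent: float) -> tuple[str, tuple[int, int] | None]:
    """Intron sequence ending in G, optionally embedding an ORF preceded by an
    in-frame stop (so the planted ATG is the ORF start).  Returns the sequence
    and the ORF interval within the intron."""
    length = plant.length
    if plant.orf_class is None:
        return _random_seq(rng, length - 1, at_percent) + "G", None
    orf_nt = plant.orf_nt or max(300, (length // 2) // 3 * 3)
    lead = (length - orf_nt) // 2
    if lead < 5 or length - lead - orf_nt < 5:
        raise MitoError(f"intron of {length} nt cannot hold a {orf_nt} nt ORF")
    head = _random_seq(rng, lead - 3, at_percent) + "TAA"
    orf = _make_orf(rng, orf_nt, at_percent, plant.orf_class)
    tail = _random_seq(rng, length - lead - orf_nt - 1, at_percent) + "G"
    return head + orf + tail, (lead, lead + orf_nt)


def _force_boundary_t(seq: str, pos: int, symbol: str) -> str:
    """Set the exon base at 1-based ``pos`` to T (group I upstream boundary);
    for coding hosts, repair the codon if the change created a stop."""
    i = pos - 1
    out = seq[:i] + "T" + seq[i + 1:]
    coding = symbol in CORE_PCGS or symbol.startswith("orf")
    if coding:
        if pos <= 3 or pos > len(seq) - 3:
            raise MitoError(f"intron boundary {pos} hits the start/stop of {symbol}")
        c0 = (i // 3) * 3
        codon = out[c0:c0 + 3]
        if translate_codon(codon) == "*":
            out = out[:c0 + 2] + "C" + out[c0 + 3:]
    return out


# ---------------------------------------------------------------------------
# genome assembly
# ---------------------------------------------------------------------------

def generate_mitogenome(spec: GenomeSpec) -> tuple[MitoGenome, PlantLog]:
    """Build a circular annotated genome honoring the spec exactly (gene
    order, junction overrides, intron plants, size target), deterministically
    per seed.  An unrealizable spec raises before any sequence is emitted."""
    rng = np.random.default_rng(spec.seed)
    order = list(spec.gene_order)
    if len(set(order)) != len(order):
        raise MitoError("gene order contains duplicate symbols")

    introns_by_host: dict[str, list[IntronPlant]] = {}
    for p in spec.introns:
        introns_by_host.setdefault(p.host, []).append(p)
    for plants in introns_by_host.values():
        plants.sort(key=lambda p: p.after_host_pos)

    # 1. exonic gene sequences, in layout order (one RNG stream)
    gene_seqs: dict[str, str] = {}
    for name in order:
        b = base_name(name)
        if b.startswith("trn"):
            length = int(rng.integers(TRNA_LENGTH_RANGE[0], TRNA_LENGTH_RANGE[1] + 1))
            gene_seqs[name] = _random_seq(rng, length, spec.at_percent)
        elif b in ("rnl", "rns"):
            gene_seqs[name] = _random_seq(rng, spec.gene_lengths[b], spec.at_percent)
        elif b in CORE_PCGS or b.startswith("orf"):
            if b not in spec.gene_lengths:
                raise MitoError(f"no length configured for {b}")
            gene_seqs[name] = _make_pcg(rng, name, spec.gene_lengths[b],
                                        spec.at_percent)
        else:
            raise MitoError(f"unknown symbol {name!r} in gene order")

    # 2. intron plants: force the exon boundary T, build intron sequences
    intron_parts: dict[str, list[tuple[int, str, str | None, tuple[int, int] | None]]] = {}
    for host, plants in introns_by_host.items():
        if host not in gene_seqs:
            raise MitoError(f"intron host {host!r} not in gene order")
        seq = gene_seqs[host]
        parts = []
        for p in plants:
            if not (0 < p.after_host_pos < len(seq)):
                raise MitoError(f"intron position {p.after_host_pos} outside {host}")
            seq = _force_boundary_t(seq, p.after_host_pos, base_name(host))
            iseq, orf_iv = _make_intron(rng, p, spec.at_percent)
            parts.append((p.after_host_pos, iseq, p.orf_class, orf_iv))
        gene_seqs[host] = seq
        intron_parts[host] = parts

    # 3. junction intervals: overrides exact; the rest fills the size target
    n_genes = len(order)
    pairs = [(order[i], order[(i + 1) % n_genes]) for i in range(n_genes)]
    overrides: dict[tuple[str, str], int] = {}
    for (u, v), iv in spec.junction_overrides.items():
        if iv < -1:
            raise MitoError("junction overlaps beyond -1 nt are not supported")
        overrides[(u, v)] = iv
    intervals: dict[tuple[str, str], int] = {}
    for u, v in pairs:
        key = (base_name(u), base_name(v))
        if key in overrides:
            intervals[(u, v)] = overrides[key]
    if pairs and pairs[-1] in intervals and intervals[pairs[-1]] < 0:
        raise MitoError("the junction closing the circle cannot overlap")

    footprint = sum(len(gene_seqs[g]) for g in order)
    footprint += sum(len(iseq) for parts in intron_parts.values()
                     for _, iseq, _, _ in parts)
    footprint += sum(intervals.values())
    free = [pr for pr in pairs if pr not in intervals]
    remaining = spec.size_target - footprint
    if remaining < spec.spacer_min * len(free):
        raise MitoError(
            f"spec unrealizable: {remaining} nt left for {len(free)} spacers "
            f"(min {spec.spacer_min} each)"
        )
    if free:
        extra = remaining - spec.spacer_min * len(free)
        alloc = rng.multinomial(extra, np.full(len(free), 1.0 / len(free)))
        for pr, a in zip(free, alloc):
            intervals[pr] = spec.spacer_min + int(a)
    elif remaining != 0:
        raise MitoError("no free spacers left to absorb the size target")

    # 4. -1 overlaps must share the boundary base (TAA stop / ATG start)
    for (u, v), iv in intervals.items():
        if iv == -1 and (not gene_seqs[u].endswith("A")
                         or not gene_seqs[v].startswith("A")):
            raise MitoError(f"cannot overlap {u}/{v} by 1 nt: boundary bases differ")

    # 5. assemble
    chunks: list[str] = []
    pos = 0
    carry = 0  # 1 when the previous junction overlapped by one base
    features: list[GeneFeature] = []
    log = PlantLog(gene_order=tuple(order))
    for gi, name in enumerate(order):
        b = base_name(name)
        seq = gene_seqs[name]
        kind = ("tRNA" if b.startswith("trn")
                else "rRNA" if b in ("rnl", "rns")
                else "PCG" if b in CORE_PCGS
                else "free_ORF")
        gene_start = pos - carry
        segs: list[tuple[int, int]] = []
        if name in intron_parts:
            if carry:
                raise MitoError(f"{name}: overlap into an intron-bearing gene")
            exon_cursor = 0
            for after, iseq, orf_class, orf_iv in intron_parts[name]:
                exon = seq[exon_cursor:after]
                chunks.append(exon)
                segs.append((pos, pos + len(exon)))
                pos += len(exon)
                istart = pos
                chunks.append(iseq)
                pos += len(iseq)
                features.append(
                    GeneFeature(f"{b}-intron", "intron",
                                [(istart, istart + len(iseq))])
                )
                if orf_iv is not None:
                    os_, oe_ = orf_iv
                    orf_name = ("rps3" if orf_class == "rps3"
                                else f"orf{(oe_ - os_) // 3 - 1}")
                    notes = ("ribosomal protein S3" if orf_class == "rps3"
                             else f"{orf_class} homing endonuclease")
                    features.append(
                        GeneFeature(orf_name, "intronic_ORF",
                                    [(istart + os_, istart + oe_)], notes=notes)
                    )
                log.introns.append(dict(
                    host=b, after_host_pos=after, length=len(iseq),
                    orf_class=orf_class, intron_start=istart,
                ))
                exon_cursor = after
            tail = seq[exon_cursor:]
            chunks.append(tail)
            segs.append((pos, pos + len(tail)))
            pos += len(tail)
        else:
            chunks.append(seq[carry:])
            segs.append((gene_start, gene_start + len(seq)))
            pos = gene_start + len(seq)
        anticodon = _anticodon_for(b[3]) if kind == "tRNA" else None
        features.append(GeneFeature(name, kind, segs, anticodon=anticodon))
        # spacer / overlap towards the next gene
        u, v = pairs[gi]
        iv = intervals[(u, v)]
        log.junctions.append((u, v, iv))
        if iv >= 0:
            chunks.append(_random_seq(rng, iv, spec.at_percent))
            pos += iv
            carry = 0
        else:
            carry = 1

    sequence = "".join(chunks)
    genome = MitoGenome(spec.genome_id, sequence, True, features,
                        {"organism": "synthetic fungal mitogenome"})
    if genome.length != spec.size_target:
        raise MitoError(
            f"internal: assembled {genome.length} bp != target {spec.size_target}"
        )
    return genome, log


# ---------------------------------------------------------------------------
# intraspecific cohort
# ---------------------------------------------------------------------------

def mutate_individuals(
    genome: MitoGenome,
    n_individuals: int,
    n_substitutions: int,
    n_indels: int,
    seed: int = 0,
    genic_substitution_fraction: float = 0.64,
    intergenic_indel_fraction: float = 0.73,
    indel_len_range: tuple[int, int] = (1, 9),
    min_separation: int = 30,
) -> tuple[list[tuple[str, str]], PlantLog]:
    """Near-identical individuals: the first is the reference genome itself;
    each planted substitution/deletion goes to one random other individual.

    Mutation footprints are kept ``min_separation`` nt apart (and off the
    sequence ends) so alignment columns map one-to-one to plants and the
    syn/nonsyn truth computed at plant time is exact.  Raises after 1000
    placement attempts if the counts do not fit.
    """
    if n_individuals < 2:
        raise MitoError("need at least 2 individuals")
    rng = np.random.default_rng(seed)
    n = genome.length
    mask = genic_mask(genome)
    genic_pos = np.flatnonzero(mask)
    inter_pos = np.flatnonzero(~mask)
    cds_index = _CdsIndex(genome)
    log = PlantLog()
    taken: list[tuple[int, int]] = []  # footprints (start, end)

    def _clash(s: int, e: int) -> bool:
        if s < min_separation or e > n - min_separation:
            return True
        return any(s < te + min_separation and ts < e + min_separation
                   for ts, te in taken)

    def _draw_pos(genic: bool) -> int:
        pool = genic_pos if genic else inter_pos
        return int(pool[rng.integers(len(pool))])

    # substitutions
    for _ in range(n_substitutions):
        for attempt in range(1000):
            genic = bool(rng.random() < genic_substitution_fraction)
            p = _draw_pos(genic)
            if not _clash(p, p + 1):
                break
        else:
            raise MitoError("could not place substitution after 1000 attempts")
        taken.append((p, p + 1))
        old = genome.sequence[p]
        new = str(rng.choice([b for b in "ACGT" if b != old]))
        indiv = int(rng.integers(1, n_individuals))
        effect = _substitution_effect(genome, cds_index, p, new)
        log.substitutions.append(dict(
            individual=indiv, pos=p, ref=old, alt=new,
            region="genic" if mask[p] else "intergenic", effect=effect,
        ))

    # deletions
    for _ in range(n_indels):
        for attempt in range(1000):
            length = int(rng.integers(indel_len_range[0], indel_len_range[1] + 1))
            inter = bool(rng.random() < intergenic_indel_fraction)
            p = _draw_pos(not inter)
            homogeneous = bool(
                (~mask[p:p + length]).all() if inter else mask[p:p + length].all()
            )
            if homogeneous and not _clash(p, p + length):
                break
        else:
            raise MitoError("could not place indel after 1000 attempts")
        taken.append((p, p + length))
        indiv = int(rng.integers(1, n_individuals))
        log.indels.append(dict(
            individual=indiv, pos=p, length=length,
            region="intergenic" if inter else "genic",
        ))

    # build individual sequences (apply edits right-to-left)
    records: list[tuple[str, str]] = [(genome.id, genome.sequence)]
    for i in range(1, n_individuals):
        edits: list[tuple[int, int, str]] = []
        for s in log.substitutions:
            if s["individual"] == i:
                edits.append((s["pos"], 1, s["alt"]))
        for d in log.indels:
            if d["individual"] == i:
                edits.append((d["pos"], d["length"], ""))
        seq = genome.sequence
        for p, ln, repl in sorted(edits, reverse=True):
            seq = seq[:p] + repl + seq[p + ln:]
        records.append((f"{genome.id}_ind{i}", seq))
    return records, log


def _substitution_effect(genome: MitoGenome, cds_index: _CdsIndex,
                         pos: int, new: str) -> str:
    hit = cds_index.by_pos.get(pos)
    if hit is None:
        return "noncoding"
    feat, idx = hit
    cds = genome.spliced(feat)
    ci, off = divmod(idx, 3)
    codon = cds[ci * 3: ci * 3 + 3]
    if len(codon) < 3:
        return "noncoding"
    alt = new if feat.strand == 1 else revcomp(new)
    alt_codon = codon[:off] + alt + codon[off + 1:]
    return ("synonymous"
            if translate_codon(alt_codon) == translate_codon(codon)
            else "nonsynonymous")


# ---------------------------------------------------------------------------
# discrete characters on trees
# ---------------------------------------------------------------------------

def random_tree(n_leaves: int, seed: int = 0, depth: float = 1.0):
    """Seeded pure-birth (Yule) tree with the maximum root-to-tip distance
    scaled to ``depth``, so rates are expressed per tree depth."""
    import random as _random

    import dendropy
    from dendropy.simulate import treesim

    t = treesim.birth_death_tree(
        birth_rate=1.0, death_rate=0.0, num_extant_tips=n_leaves,
        rng=_random.Random(seed),
    )
    maxd = max(lf.distance_from_root() for lf in t.leaf_node_iter())
    if maxd > 0:
        for e in t.preorder_edge_iter():
            if e.length:
                e.length *= depth / maxd
    return t

def simulate_characters(
    tree, k: int, rate: float, seed: int = 0
) -> tuple[CharacterStateMatrix, PlantLog]:
    """Evolve one k-state character along a rooted tree under the equal-rates
    Markov model (uniform root prior); returns the leaf matrix and a log with
    the true state of every node (labelled as in :class:`MkModel`)."""
    if k < 2:
        raise MitoError("k must be >= 2")
    if rate < 0:
        raise MitoError("rate must be >= 0")
    t = _load_tree(tree)
    labels = label_nodes(t)
    rng = np.random.default_rng(seed)
    alphabet = tuple(ascii_uppercase[:k])
    states: dict[int, int] = {}
    log = PlantLog()
    for nd in t.preorder_node_iter():
        if nd.parent_node is None:
            states[id(nd)] = int(rng.integers(k))
        else:
            parent = states[id(nd.parent_node)]
            bl = nd.edge.length or 0.0
            if rate == 0 or bl == 0:
                states[id(nd)] = parent
            else:
                p_stay = 1.0 / k + (1.0 - 1.0 / k) * np.exp(-k * rate * bl / (k - 1))
                if rng.random() < p_stay:
                    states[id(nd)] = parent
                else:
                    others = [s for s in range(k) if s != parent]
                    states[id(nd)] = int(rng.choice(others))
        log.node_states[labels[id(nd)]] = alphabet[states[id(nd)]]
    matrix = CharacterStateMatrix(
        {lf.taxon.label: alphabet[states[id(lf)]] for lf in t.leaf_node_iter()},
        alphabet,
    )
    return matrix, log
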