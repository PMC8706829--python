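"""Genome-level composition and region accounting.

Genic nucleotides are the union of the genomic extents of all gene-level
features (core PCGs, rRNAs, tRNAs, free-standing ORFs); introns count as
genic because they sit inside host genes, and overlapping genes are counted
once, so genic + intergenic always equals genome size exactly.  Skews follow
the standard conventions (A-T)/(A+T) and (G-C)/(G+C); N bases are excluded
from all composition denominators but retained in genome size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import CORE_PCGS, MitoError, MitoGenome
from .translate import translate_codon

STANDARD_START = "ATG"
STANDARD_STOPS = ("TAA", "TAG")


@dataclass
class CodonAudit:
    gene: str
    start_codon: str
    stop_codon: str
    flags: list[str] = field(default_factory=list)


@dataclass
class GenomeSummary:
    genome_id: str
    size_bp: int
    at_percent: float
    at_skew: float
    gc_skew: float
    n_core_pcg: int
    n_free_orf: int
    n_rrna: int
    n_trna: int
    n_intron: int
    n_intronic_orf: int
    intronic_nt: int
    genic_nt: int
    genic_percent: float
    intergenic_nt: int
    intergenic_percent: float
    start_stop_audit: dict[str, CodonAudit] = field(default_factory=dict)

    def to_tsv(self) -> str:
        """Two-column TSV whose row names mirror the standard per-genome
        summary table of mitogenome papers."""
        rows = [
            ("Mitogenome size (bp)", f"{self.size_bp:,}"),
            ("AT%", f"{self.at_percent:.1f}"),
            ("AT skew", f"{self.at_skew:.2f}"),
            ("GC skew", f"{self.gc_skew:.2f}"),
            ("No. standard PCGs", str(self.n_core_pcg)),
            ("No. free-standing ORFs", str(self.n_free_orf)),
            ("No. rRNAs", str(self.n_rrna)),
            ("No. tRNAs", str(self.n_trna)),
            ("No. introns", str(self.n_intron)),
            ("No. intronic ORFs", str(self.n_intronic_orf)),
            ("Intronic region (nt)", f"{self.intronic_nt:,}"),
            ("Genic region (nt)", f"{self.genic_nt:,}"),
            ("Genic region (%)", f"{self.genic_percent:.1f}"),
            ("Intergenic regions (nt)", f"{self.intergenic_nt:,}"),
            ("Intergenic regions (%)", f"{self.intergenic_percent:.1f}"),
        ]
        head = f"Item\t{self.genome_id}\n"
        return head + "\n".join(f"{k}\t{v}" for k, v in rows) + "\n"


def composition(genome: MitoGenome | str) -> tuple[float, float, float]:
    """Return ``(at_percent, at_skew, gc_skew)`` of a genome or raw sequence."""
    seq = genome.sequence if isinstance(genome, MitoGenome) else genome.upper()
    a, c, g, t = (seq.count(b) for b in "ACGT")
    acgt = a + c + g + t
    if acgt == 0:
        raise MitoError("composition undefined: sequence has no unambiguous bases")
    at_percent = 100.0 * (a + t) / acgt
    at_skew = (a - t) / (a + t) if a + t else 0.0
    gc_skew = (g - c) / (g + c) if g + c else 0.0
    return at_percent, at_skew, gc_skew


def genic_mask(genome: MitoGenome) -> np.ndarray:
    """Boolean mask over the genome: True where inside the genomic extent of
    any gene-level feature (introns included via their host spans)."""
    mask = np.zeros(genome.length, dtype=bool)
    for f in genome.genes():
        for s, e in f.genomic_extent(genome.length):
            mask[s:e] = True
    return mask


def percent(part: int | float, whole: int | float, ndigits: int = 1) -> float:
    """Percentage rounded to ``ndigits`` (the table-formatting convention)."""
    return round(100.0 * part / whole, ndigits)


def region_accounting(genome: MitoGenome, transl_table: int = 4) -> GenomeSummary:
    """Compute the full per-genome summary (composition, feature census,
    genic/intergenic/intronic accounting, start/stop codon audit)."""
    at_percent, at_skew, gc_skew = composition(genome)
    mask = genic_mask(genome)
    genic_nt = int(mask.sum())
    intergenic_nt = genome.length - genic_nt

    base = lambda n: n.rsplit("_", 1)[0] if n.rsplit("_", 1)[-1].isdigit() else n
    core = [f for f in genome.features if f.kind == "PCG" and base(f.name) in CORE_PCGS]
    introns = genome.features_of_kind("intron")
    intronic_nt = sum(f.length for f in introns)

    audit = start_stop_audit(genome, transl_table)
    return GenomeSummary(
        genome_id=genome.id,
        size_bp=genome.length,
        at_percent=at_percent,
        at_skew=at_skew,
        gc_skew=gc_skew,
        n_core_pcg=len(core),
        n_free_orf=len(genome.features_of_kind("free_ORF")),
        n_rrna=len(genome.features_of_kind("rRNA")),
        n_trna=len(genome.features_of_kind("tRNA")),
        n_intron=len(introns),
        n_intronic_orf=len(genome.features_of_kind("intronic_ORF")),
        intronic_nt=intronic_nt,
        genic_nt=genic_nt,
        genic_percent=percent(genic_nt, genome.length),
        intergenic_nt=intergenic_nt,
        intergenic_percent=percent(intergenic_nt, genome.length),
        start_stop_audit=audit,
    )


def start_stop_audit(genome: MitoGenome, transl_table: int = 4) -> dict[str, CodonAudit]:
    """First/last codon of every protein-coding feature's spliced CDS, with
    flags for nonstandard starts (non-ATG), nonstandard stops (non-TAA/TAG)
    and CDS lengths not divisible by three."""
    out: dict[str, CodonAudit] = {}
    for f in genome.features_of_kind("PCG", "free_ORF", "intronic_ORF"):
        cds = genome.spliced(f)
        flags: list[str] = []
        if len(cds) % 3 != 0:
            flags.append("length not divisible by 3")
        start, stop = cds[:3], cds[-3:]
        if start != STANDARD_START:
            flags.append(f"nonstandard start {start}")
        if stop not in STANDARD_STOPS:
            if translate_codon(stop, transl_table) == "*":
                flags.append(f"rare stop {stop}")
            else:
                flags.append(f"no stop codon ({stop})")
        out[f.name] = CodonAudit(f.name, start, stop, flags)
    return out
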