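"""Group I intron cataloguing: positional nomenclature, boundary checks,
intronic/intergenic ORF detection, and cross-taxon intron identity.

Introns are named by the insertion position on a homologous reference gene:
an rnl intron inserted after reference position 2450 is mL2450; an intron in
a protein-coding gene is <gene>P<position> (e.g., cox1P1125).  Reference
sequences are user-supplied per host gene; the insertion coordinate is read
off a global pairwise alignment of the spliced (exon-only) host sequence to
the reference.  Group I subgroup labels (IA/IB) are metadata passthrough —
structural RNA classification is out of scope.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .align import pairwise_global, percent_identity
from .gene_order import base_name
from .model import GeneFeature, MitoError, MitoGenome
from .translate import stop_codons, translate

_LAGLIDADG_RE = re.compile(r"L[A-Z]GL[IV]DADG", re.IGNORECASE)
_GIY_YIG_RE = re.compile(r"GIY[A-Z]{0,12}YIG", re.IGNORECASE)


@dataclass
class IntronRecord:
    host_gene: str
    name: str
    insertion_ref_pos: int
    group: str = "unknown"  # IA/IB/unknown: user-supplied metadata
    boundary_ok: tuple[bool, bool] = (False, False)
    orf: str | None = None
    orf_class: str | None = None  # rps3 | LAGLIDADG | GIY-YIG | unknown


def intron_name(host_gene: str, insertion_ref_pos: int) -> str:
    """Positional intron name: mL<pos> for rnl, mS<pos> for rns,
    <gene>P<pos> for protein-coding hosts."""
    if insertion_ref_pos <= 0:
        raise MitoError("insertion position must be positive (1-based)")
    host = base_name(host_gene)
    if host == "rnl":
        return f"mL{insertion_ref_pos}"
    if host == "rns":
        return f"mS{insertion_ref_pos}"
    return f"{host}P{insertion_ref_pos}"


def locate_insertion(
    spliced_host: str,
    junction: int,
    reference: str,
    min_identity: float = 40.0,
) -> int:
    """Reference coordinate (1-based) of the intron insertion site.

    ``junction`` is the number of spliced host bases 5' of the intron (the
    1-based index of the last upstream-exon base).  The spliced host is
    globally aligned to the reference; the returned position is the reference
    base aligned to host base ``junction``, or the nearest upstream
    reference-aligned base when that host base sits in a reference gap.
    """
    if not (0 < junction <= len(spliced_host)):
        raise MitoError(f"junction {junction} outside spliced host")
    row_h, row_r = pairwise_global(spliced_host, reference)
    matches = sum(1 for x, y in zip(row_h, row_r) if x == y and x != "-")
    identity = 100.0 * matches / len(row_h)
    if identity < min_identity:
        raise MitoError(
            f"alignment identity {identity:.1f}% below {min_identity}%: "
            "insertion position unreliable"
        )
    hp = rp = 0
    last_ref = 0
    for ch, cr in zip(row_h, row_r):
        if cr != "-":
            rp += 1
        if ch != "-":
            hp += 1
            if cr != "-":
                last_ref = rp
            if hp == junction:
                return rp if cr != "-" else last_ref
    raise MitoError("junction beyond aligned host sequence")  # pragma: no cover


def boundary_check(intron_seq: str, upstream_exon_seq: str) -> tuple[bool, bool]:
    """Group I diagnostic: (upstream exon ends 'T', intron ends 'G')."""
    if not intron_seq or not upstream_exon_seq:
        raise MitoError("boundary_check requires non-empty sequences")
    return upstream_exon_seq[-1].upper() == "T", intron_seq[-1].upper() == "G"


# --------------------------------------------------------------------------
# ORF detection
# --------------------------------------------------------------------------

def find_orfs(
    region_seq: str, min_nt: int = 300, transl_table: int = 4
) -> list[tuple[str, int, int]]:
    """Sense-strand ORFs (ATG to in-frame stop, stop included) of nucleotide
    length >= ``min_nt``, named orf<aa length>.  For each stop codon only the
    longest ORF is kept, and ORFs nested inside a longer kept ORF are
    suppressed.  Coordinates are 0-based half-open within ``region_seq``."""
    seq = region_seq.upper()
    stops = stop_codons(transl_table)
    candidates: dict[tuple[int, int], int] = {}  # (frame, stop_end) -> earliest start
    for frame in range(3):
        first_atg: int | None = None
        for i in range(frame, len(seq) - 2, 3):
            codon = seq[i : i + 3]
            if codon == "ATG" and first_atg is None:
                first_atg = i
            elif codon in stops:
                if first_atg is not None:
                    candidates[(frame, i + 3)] = first_atg
                first_atg = None
    orfs = []
    for (frame, end), start in candidates.items():
        if end - start >= min_nt:
            aa_len = (end - start) // 3 - 1
            orfs.append((f"orf{aa_len}", start, end))
    orfs.sort(key=lambda o: (-(o[2] - o[1]), o[1]))
    kept: list[tuple[str, int, int]] = []
    for name, s, e in orfs:
        if any(ks <= s and e <= ke for _, ks, ke in kept):
            continue
        kept.append((name, s, e))
    kept.sort(key=lambda o: o[1])
    return kept


def classify_orf_product(orf_nt: str, transl_table: int = 4) -> str:
    """Heuristic homing-endonuclease class from simple protein motifs."""
    prot = translate(orf_nt, transl_table)
    if _LAGLIDADG_RE.search(prot):
        return "LAGLIDADG"
    if _GIY_YIG_RE.search(prot):
        return "GIY-YIG"
    return "unknown"


# --------------------------------------------------------------------------
# Genome-level catalog
# --------------------------------------------------------------------------

def _host_of(intron: GeneFeature, genome: MitoGenome) -> GeneFeature:
    lo = intron.min_start()
    hi = max(e for _, e in intron.segments)
    for f in genome.features_of_kind("PCG", "rRNA"):
        for a, b in f.genomic_extent(genome.length):
            if a <= lo and hi <= b:
                return f
    raise MitoError(f"{genome.id}: no host gene contains intron at [{lo},{hi})")


def catalog_introns(
    genome: MitoGenome,
    references: dict[str, str],
    groups: dict[str, str] | None = None,
    min_identity: float = 40.0,
) -> list[IntronRecord]:
    """Name and validate every annotated intron of a genome.

    ``references`` maps host gene symbols to reference gene sequences (the
    coordinate system of the positional nomenclature); hosts without a
    reference are catalogued with position 0 and name '<host>-intron'.
    ``groups`` optionally maps positional names to IA/IB labels.
    """
    records: list[IntronRecord] = []
    for intron in genome.features_of_kind("intron"):
        host = _host_of(intron, genome)
        spliced = genome.spliced(host)
        # number of spliced host bases 5' of the intron
        junction = 0
        istart = intron.segments[0][0] if host.strand == 1 else intron.segments[0][1]
        for s, e in host.segments:
            if host.strand == 1:
                if e <= istart:
                    junction += e - s
                elif s < istart:
                    junction += istart - s
            else:
                if s >= istart:
                    junction += e - s
                elif e > istart:
                    junction += e - istart
        ref = references.get(base_name(host.name))
        if ref is None:
            pos, name = 0, f"{base_name(host.name)}-intron"
        else:
            pos = locate_insertion(spliced, junction, ref, min_identity)
            name = intron_name(host.name, pos)
        upstream_exon = spliced[:junction]
        b_ok = boundary_check(genome.spliced(intron), upstream_exon)
        orf_name = orf_class = None
        lo, hi = intron.min_start(), max(e for _, e in intron.segments)
        for f in genome.features_of_kind("intronic_ORF"):
            if lo <= f.min_start() and max(e for _, e in f.segments) <= hi:
                orf_name = f.name
                if base_name(f.name) == "rps3" or "ribosomal protein s3" in f.notes.lower():
                    orf_class = "rps3"
                else:
                    orf_class = classify_orf_product(genome.spliced(f))
                break
        records.append(
            IntronRecord(
                host_gene=host.name,
                name=name,
                insertion_ref_pos=pos,
                group=(groups or {}).get(name, "unknown"),
                boundary_ok=b_ok,
                orf=orf_name,
                orf_class=orf_class,
            )
        )
    return records


def intron_identity_matrix(
    seqs: dict[str, dict[str, str]], name: str | None = None
) -> pd.DataFrame | dict[str, pd.DataFrame]:
    """Pairwise global-alignment identity (%) among taxa sharing an intron
    name.  ``seqs`` maps taxon -> {intron name -> sequence}.  Cells for taxa
    lacking the intron are NaN (empty), never 0.  With ``name=None`` a matrix
    is returned for every intron name present in >= 2 taxa."""
    if name is None:
        names = sorted({n for d in seqs.values() for n in d})
        return {
            n: intron_identity_matrix(seqs, n)
            for n in names
            if sum(n in d for d in seqs.values()) >= 2
        }
    taxa = list(seqs)
    mat = pd.DataFrame(np.nan, index=taxa, columns=taxa, dtype=float)
    for i, t1 in enumerate(taxa):
        for t2 in taxa[i:]:
            if name in seqs[t1] and name in seqs[t2]:
                pid = (
                    100.0
                    if t1 == t2
                    else percent_identity(seqs[t1][name], seqs[t2][name])
                )
                mat.loc[t1, t2] = mat.loc[t2, t1] = pid
    return mat
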