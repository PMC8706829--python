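"""Intraspecific whole-mitogenome comparison.

Near-identical genomes are aligned (banded progressive alignment anchored on
the first sequence), and alignment columns are tallied into two disjoint
classes: indel sites (columns containing at least one gap) and variable
sites (gap-free columns with >= 2 distinct bases).  Divergence is
100*(indel_sites + variable_sites)/alignment_length.  Sites are partitioned
into genic/intergenic through a designated reference annotation, and each
variable coding site is classified synonymous/nonsynonymous under the mold
mitochondrial code (table 4) by translating the reference codon against every
alternate codon.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .align import banded_align, merge_on_anchor
from .model import GeneFeature, MitoError, MitoGenome, revcomp
from .summary import genic_mask
from .translate import translate_codon

CODING_KINDS = ("PCG", "free_ORF", "intronic_ORF")


@dataclass
class SiteRecord:
    column: int  # 0-based alignment column
    ref_pos: int | None  # 0-based reference coordinate (None: ref gap)
    site_class: str  # "indel" | "variable"
    region: str  # "genic" | "intergenic"
    bases: tuple[str, ...]
    effect: str | None = None  # synonymous | nonsynonymous | indel-adjacent | noncoding


@dataclass
class VariationReport:
    n_sequences: int
    alignment_length: int
    indel_sites: int
    variable_sites: int
    divergence_percent: float
    sites: list[SiteRecord] = field(default_factory=list)
    metadata: dict[str, str] = field(default_factory=dict)

    def partition(self) -> dict[str, dict[str, int]]:
        out = {"indel": {"genic": 0, "intergenic": 0},
               "variable": {"genic": 0, "intergenic": 0}}
        for s in self.sites:
            out[s.site_class][s.region] += 1
        return out

    def effect_census(self) -> dict[str, int]:
        census: dict[str, int] = {}
        for s in self.sites:
            if s.effect:
                census[s.effect] = census.get(s.effect, 0) + 1
        return census

    def to_tsv(self) -> str:
        lines = ["column\tref_pos_1based\tclass\tregion\tbases\teffect"]
        for s in self.sites:
            lines.append(
                f"{s.column + 1}\t{'' if s.ref_pos is None else s.ref_pos + 1}\t"
                f"{s.site_class}\t{s.region}\t{'/'.join(s.bases)}\t{s.effect or ''}"
            )
        return "\n".join(lines) + "\n"


def align_high_identity(
    seqs: list[tuple[str, str]], band: int = 200,
) -> list[tuple[str, str]]:
    """Progressive banded global alignment of >= 2 near-identical sequences,
    anchored on the first; deterministic for fixed inputs and parameters."""
    if len(seqs) < 2:
        raise MitoError("alignment needs at least two sequences")
    anchor_name, anchor = seqs[0]
    pairs = []
    for _, seq in seqs[1:]:
        _, rowa, rowo = banded_align(anchor, seq, band=band)
        pairs.append((rowa, rowo))
    rows = merge_on_anchor(anchor, pairs)
    return [(name, row) for (name, _), row in zip(seqs, rows)]


def tally_sites(
    alignment: list[tuple[str, str]],
    reference_annotation: MitoGenome,
    transl_table: int = 4,
) -> VariationReport:
    """Column tallies, genic/intergenic partition and coding effects.

    The reference annotation's sequence must be one of the aligned rows
    (matched by id prefix of the header or by ungapped sequence identity).
    """
    ref_row = _reference_row(alignment, reference_annotation)
    rows = [seq.upper() for _, seq in alignment]
    ncol = len(rows[0])
    if any(len(r) != ncol for r in rows):
        raise MitoError("alignment rows have unequal lengths")

    mask = genic_mask(reference_annotation)
    # column -> reference position map (and inverse for codon lookups)
    ref_seq_row = rows[ref_row]
    col_to_ref: list[int | None] = []
    ref_to_col: dict[int, int] = {}
    p = 0
    for c, ch in enumerate(ref_seq_row):
        if ch == "-":
            col_to_ref.append(None)
        else:
            col_to_ref.append(p)
            ref_to_col[p] = c
            p += 1
    if p != reference_annotation.length:
        raise MitoError("reference row does not match the reference annotation length")

    gap_cols = {c for c in range(ncol) if any(r[c] == "-" for r in rows)}
    cds_index = _CdsIndex(reference_annotation)

    sites: list[SiteRecord] = []
    indel = variable = 0
    for c in range(ncol):
        col = tuple(r[c] for r in rows)
        if "-" in col:
            indel += 1
            rp = col_to_ref[c]
            if rp is None:  # insertion relative to reference: nearest 5' base
                prev = next((col_to_ref[k] for k in range(c - 1, -1, -1)
                             if col_to_ref[k] is not None), 0)
                rp_cls = prev
                rp = None
            else:
                rp_cls = rp
            sites.append(SiteRecord(
                c, rp, "indel",
                "genic" if mask[rp_cls] else "intergenic", col))
        elif len(set(col)) > 1:
            variable += 1
            rp = col_to_ref[c]
            effect = _coding_effect(
                reference_annotation, cds_index, rp, col, ref_row,
                ref_to_col, gap_cols, transl_table,
            )
            sites.append(SiteRecord(
                c, rp, "variable",
                "genic" if mask[rp] else "intergenic", col, effect))

    divergence = 100.0 * (indel + variable) / ncol
    return VariationReport(
        n_sequences=len(rows),
        alignment_length=ncol,
        indel_sites=indel,
        variable_sites=variable,
        divergence_percent=divergence,
        sites=sites,
        metadata={
            "divergence_definition":
                "100*(indel_sites+variable_sites)/alignment_length",
            "divergence_variable_only":
                f"{100.0 * variable / ncol:.4f}",
            "transl_table": str(transl_table),
        },
    )


class _CdsIndex:
    """Reference position -> (coding feature, index within spliced CDS)."""

    def __init__(self, genome: MitoGenome):
        self.genome = genome
        self.by_pos: dict[int, tuple[GeneFeature, int]] = {}
        for f in genome.features_of_kind(*CODING_KINDS):
            for idx, pos in enumerate(_spliced_to_genomic(f)):
                self.by_pos.setdefault(pos, (f, idx))


def _coding_effect(
    genome: MitoGenome,
    cds_index: _CdsIndex,
    ref_pos: int,
    col: tuple[str, ...],
    ref_row: int,
    ref_to_col: dict[int, int],
    gap_cols: set[int],
    transl_table: int,
) -> str:
    hit = cds_index.by_pos.get(ref_pos)
    if hit is None:
        return "noncoding"
    feat, idx = hit
    cds = genome.spliced(feat)
    codon_i = idx // 3
    offset = idx % 3
    codon = cds[codon_i * 3 : codon_i * 3 + 3]
    if len(codon) < 3:
        return "indel-adjacent"
    # genomic positions of the codon's three bases, checked for gap columns
    spliced_positions = _spliced_to_genomic(feat)
    for k in range(3):
        gpos = spliced_positions[codon_i * 3 + k]
        ccol = ref_to_col.get(gpos)
        if ccol is None or ccol in gap_cols:
            return "indel-adjacent"
    ref_base = col[ref_row]
    effects_same = True
    for base in set(col) - {ref_base}:
        alt = base if feat.strand == 1 else revcomp(base)
        alt_codon = codon[:offset] + alt + codon[offset + 1 :]
        if translate_codon(alt_codon, transl_table) != translate_codon(
            codon, transl_table
        ):
            effects_same = False
    return "synonymous" if effects_same else "nonsynonymous"


def _spliced_to_genomic(feat: GeneFeature) -> list[int]:
    positions: list[int] = []
    for s, e in feat.segments:
        rng = range(s, e) if feat.strand == 1 else range(e - 1, s - 1, -1)
        positions.extend(rng)
    return positions


def coding_effect(
    alignment: list[tuple[str, str]],
    reference_annotation: MitoGenome,
    column: int,
    transl_table: int = 4,
) -> str:
    """Effect (synonymous/nonsynonymous/...) of the variable site at an
    alignment column; convenience wrapper over :func:`tally_sites`."""
    report = tally_sites(alignment, reference_annotation, transl_table)
    for s in report.sites:
        if s.column == column:
            return s.effect or s.site_class
    return "invariant"


def _reference_row(alignment: list[tuple[str, str]], genome: MitoGenome) -> int:
    for i, (header, seq) in enumerate(alignment):
        if header.split()[0] == genome.id:
            return i
    for i, (_, seq) in enumerate(alignment):
        if seq.replace("-", "").upper() == genome.sequence:
            return i
    raise MitoError(f"reference {genome.id} is not one of the aligned rows")
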