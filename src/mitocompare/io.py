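"""Reading and writing annotated mitogenomes.

GenBank flat files are parsed with Biopython and normalized into the internal
model: 0-based half-open coordinates, origin-wrapping ``join`` locations kept
as multi-segment features, gene symbols canonicalized through
:class:`~mitocompare.names.GeneNameMap`, and duplicated symbols disambiguated
in genome order (``trnM_1``, ``trnM_2`` ...).
"""

from __future__ import annotations

import io as _stdio
import re

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

from .model import CORE_PCGS, GeneFeature, MitoError, MitoGenome
from .names import GeneNameMap, disambiguate

_GB_TYPES = {"CDS", "rRNA", "tRNA", "intron"}

IUPAC_NT = set("ACGTUNRYSWKMBDHV-")


# --------------------------------------------------------------------------
# GenBank
# --------------------------------------------------------------------------

def read_genbank(path: str, name_map: GeneNameMap | None = None) -> MitoGenome:
    """Parse a GenBank flat file into a :class:`MitoGenome`.

    Raises :class:`MitoError` if the record carries no sequence; features
    whose coordinates fall outside the sequence raise with the feature named.
    """
    record = SeqIO.read(path, "genbank")
    if record.seq is None or len(record.seq) == 0:
        raise MitoError(f"{path}: GenBank record has no sequence")
    try:
        seq = str(record.seq)
    except Exception as exc:  # contentless sequence placeholder
        raise MitoError(f"{path}: GenBank record has no sequence") from exc
    name_map = name_map or GeneNameMap()
    is_circular = record.annotations.get("topology", "linear") == "circular"

    raw: list[dict] = []
    for feat in record.features:
        if feat.type not in _GB_TYPES:
            continue
        quals = feat.qualifiers
        label = (
            quals.get("gene", [None])[0]
            or quals.get("standard_name", [None])[0]
            or quals.get("locus_tag", [None])[0]
            or quals.get("product", ["unnamed"])[0]
        )
        product = quals.get("product", [None])[0]
        name, standard = name_map.normalize(label, product)
        segments, strand = _location_to_segments(feat, len(seq))
        for s, e in segments:
            if not (0 <= s < len(seq) and 0 < e <= len(seq)):
                raise MitoError(
                    f"{record.id}: feature {name!r} segment ({s},{e}) outside "
                    f"sequence of length {len(seq)}"
                )
        anticodon = None
        if feat.type == "tRNA":
            ac = quals.get("anticodon", [None])[0] or quals.get("note", [None])[0]
            if ac:
                m = re.search(r"(?:seq:)?([acgtu]{3,4})\)?$", ac.strip(), re.I)
                if m:
                    anticodon = m.group(1).upper()
        raw.append(
            dict(
                name=name,
                gbtype=feat.type,
                segments=segments,
                strand=strand,
                anticodon=anticodon,
                product=product or "",
                standard=standard,
            )
        )

    feats = _classify(raw, len(seq))
    genome = MitoGenome(
        id=record.id or record.name,
        sequence=seq,
        is_circular=is_circular,
        features=feats,
        metadata={
            "organism": record.annotations.get("organism", ""),
            "source": str(path),
        },
    )
    return genome


def _location_to_segments(feat, n: int) -> tuple[list[tuple[int, int]], int]:
    loc = feat.location
    strand = 1 if (loc.strand or 1) >= 0 else -1
    parts = list(loc.parts)
    segments = [(int(p.start), int(p.end)) for p in parts]
    if strand == -1:
        # GenBank complement(join(...)) lists segments in genomic order;
        # transcription order is genomically descending
        segments.sort(key=lambda se: -se[0])
    return segments, strand


def _classify(raw: list[dict], n: int) -> list[GeneFeature]:
    """Assign internal kinds; CDS-only records are typed by name/product and
    by containment inside another gene's genomic extent."""
    host_extents: list[tuple[str, list[tuple[int, int]]]] = []
    for r in raw:
        if r["gbtype"] == "rRNA" or (r["gbtype"] == "CDS" and r["name"] in CORE_PCGS):
            gf = GeneFeature(r["name"], "rRNA" if r["gbtype"] == "rRNA" else "PCG",
                             r["segments"], r["strand"])
            host_extents.append((r["name"], gf.genomic_extent(n)))

    feats: list[GeneFeature] = []
    for r in raw:
        name, gbtype = r["name"], r["gbtype"]
        product = r["product"].lower()
        if gbtype == "rRNA":
            kind = "rRNA"
        elif gbtype == "tRNA":
            kind = "tRNA"
            if not name.startswith("trn"):
                name = "trn" + name  # defensive: product-derived names
        elif gbtype == "intron":
            kind = "intron"
        else:  # CDS
            if name in CORE_PCGS:
                kind = "PCG"
            elif (
                name == "rps3"
                or "ribosomal protein s3" in product
                or "homing endonuclease" in product
                or "laglidadg" in product
                or "giy-yig" in product
                or _contained_in_any(r["segments"], host_extents, n)
            ):
                kind = "intronic_ORF"
            else:
                kind = "free_ORF"
        notes = r["product"] if r["product"] else ""
        if not r["standard"]:
            notes = (notes + "; " if notes else "") + "nonstandard name"
        feats.append(
            GeneFeature(name, kind, r["segments"], r["strand"], r["anticodon"], notes)
        )

    feats.sort(key=lambda f: f.min_start())
    new_names = disambiguate([f.name for f in feats])
    for f, nm in zip(feats, new_names):
        f.name = nm
    return feats


def _contained_in_any(segments, host_extents, n) -> bool:
    lo = min(s for s, _ in segments)
    hi = max(e for _, e in segments)
    for _, extents in host_extents:
        for a, b in extents:
            if a <= lo and hi <= b:
                return True
    return False


_KIND_TO_GB = {
    "PCG": "CDS",
    "free_ORF": "CDS",
    "intronic_ORF": "CDS",
    "rRNA": "rRNA",
    "tRNA": "tRNA",
    "intron": "intron",
}


def write_genbank(genome: MitoGenome, path: str, transl_table: int = 4) -> None:
    """Write the genome back to a GenBank flat file (round-trips with
    :func:`read_genbank` on the internal model)."""
    record = SeqRecord(
        Seq(genome.sequence),
        id=genome.id,
        name=genome.id.replace(".", "_")[:16],
        description=genome.metadata.get("organism", "synthetic mitogenome"),
    )
    record.annotations["molecule_type"] = "DNA"
    record.annotations["topology"] = "circular" if genome.is_circular else "linear"
    record.annotations["organism"] = genome.metadata.get("organism", "")
    record.features.append(
        SeqFeature(SimpleLocation(0, genome.length, 1), type="source",
                   qualifiers={"organism": record.annotations["organism"]})
    )
    for f in genome.features:
        locs = [SimpleLocation(s, e, f.strand) for s, e in f.segments]
        if f.strand == -1:
            locs = locs[::-1]  # genomic order inside complement(join(...))
        loc = locs[0] if len(locs) == 1 else CompoundLocation(locs)
        quals: dict[str, list[str]] = {"gene": [f.name]}
        if f.kind in ("PCG", "free_ORF", "intronic_ORF"):
            quals["transl_table"] = [str(transl_table)]
            quals["product"] = [_product_text(f)]
        elif f.kind == "tRNA":
            quals["product"] = [f"tRNA-{f.name[3]}"]
            if f.anticodon:
                quals["anticodon"] = [f.anticodon]
        record.features.append(SeqFeature(loc, type=_KIND_TO_GB[f.kind], qualifiers=quals))
    with open(path, "w") as fh:
        SeqIO.write(record, fh, "genbank")


def _product_text(f: GeneFeature) -> str:
    if f.notes and "nonstandard" not in f.notes:
        return f.notes.split(";")[0]
    if f.name.startswith("rps3"):
        return "ribosomal protein S3"
    if f.kind == "intronic_ORF":
        return "homing endonuclease"
    if f.kind == "free_ORF":
        return "hypothetical protein"
    return f.name


# --------------------------------------------------------------------------
# Feature table (TSV)
# --------------------------------------------------------------------------

_TABLE_HEADER = ["name", "kind", "strand", "segments", "length", "anticodon", "notes"]


def write_feature_table(genome: MitoGenome) -> str:
    """One row per feature; segments rendered 1-based inclusive as
    ``start..end`` pairs joined by commas (an origin-wrapping feature thus
    shows two coordinate pairs on one row).  Round-trips losslessly with
    :func:`read_feature_table`."""
    lines = ["\t".join(_TABLE_HEADER)]
    for f in genome.features:
        segs = ",".join(f"{s + 1}..{e}" for s, e in f.segments)
        lines.append(
            "\t".join(
                [
                    f.name,
                    f.kind,
                    "+" if f.strand == 1 else "-",
                    segs,
                    str(f.length),
                    f.anticodon or "",
                    f.notes.replace("\t", " "),
                ]
            )
        )
    return "\n".join(lines) + "\n"


def read_feature_table(text: str) -> list[GeneFeature]:
    """Inverse of :func:`write_feature_table` (feature list only)."""
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines or lines[0].split("\t") != _TABLE_HEADER:
        raise MitoError("feature table missing or malformed header")
    feats = []
    for ln in lines[1:]:
        name, kind, strand, segs, _length, anticodon, notes = (ln.split("\t") + [""])[:7]
        segments = []
        for pair in segs.split(","):
            a, b = pair.split("..")
            segments.append((int(a) - 1, int(b)))
        feats.append(
            GeneFeature(
                name, kind, segments, 1 if strand == "+" else -1,
                anticodon or None, notes,
            )
        )
    return feats


# --------------------------------------------------------------------------
# FASTA
# --------------------------------------------------------------------------

def read_fasta(path: str) -> list[tuple[str, str]]:
    """Read FASTA, preserving record order and full headers; sequences are
    uppercased; gap characters are allowed (alignments); non-IUPAC characters
    and duplicated headers are rejected."""
    records = list(SeqIO.parse(path, "fasta"))
    out: list[tuple[str, str]] = []
    seen: dict[str, int] = {}
    for rec in records:
        header = rec.description
        seq = str(rec.seq).upper()
        bad = set(seq) - IUPAC_NT
        if bad:
            raise MitoError(f"{header!r}: non-IUPAC characters {sorted(bad)}")
        seen[header] = seen.get(header, 0) + 1
        out.append((header, seq))
    dups = sorted(h for h, c in seen.items() if c > 1)
    if dups:
        raise MitoError(f"duplicate FASTA headers: {dups}")
    return out


def write_fasta(records: list[tuple[str, str]], path: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        for header, seq in records:
            fh.write(f">{header}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def fasta_string(records: list[tuple[str, str]], width: int = 70) -> str:
    buf = _stdio.StringIO()
    for header, seq in records:
        buf.write(f">{header}\n")
        for i in range(0, len(seq), width):
            buf.write(seq[i : i + width] + "\n")
    return buf.getvalue()
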