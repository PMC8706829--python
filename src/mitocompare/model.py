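"""Core data model for annotated circular mitochondrial genomes.

Coordinates are 0-based half-open internally; all file I/O converts from the
1-based inclusive GenBank convention at the boundary.  A feature that spans
the circular origin is stored as multiple segments, each with ``end > start``;
no coordinate ever exceeds the genome length.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

VALID_KINDS = ("PCG", "rRNA", "tRNA", "free_ORF", "intron", "intronic_ORF")

#: the 14 core protein-coding genes of fungal mitochondria
CORE_PCGS = (
    "nad1", "nad2", "nad3", "nad4", "nad4L", "nad5", "nad6",
    "cob", "cox1", "cox2", "cox3", "atp6", "atp8", "atp9",
)
#: core gene set used for gene-order comparison: 14 PCGs + both rRNAs
CORE_GENES = CORE_PCGS + ("rnl", "rns")

DNA_ALPHABET = set("ACGTN")


class MitoError(ValueError):
    """Base error for malformed genomes or features."""


@dataclass
class GeneFeature:
    """A named gene, ORF or intron with (possibly origin-wrapping) segments.

    ``segments`` are 0-based half-open intervals in genome orientation,
    listed in transcription order (for a minus-strand feature the first
    segment is therefore the genomically last one).
    """

    name: str
    kind: str
    segments: list[tuple[int, int]]
    strand: int = 1
    anticodon: str | None = None
    notes: str = ""

    def __post_init__(self) -> None:
        if self.kind not in VALID_KINDS:
            raise MitoError(f"unknown feature kind {self.kind!r} for {self.name!r}")
        if not self.segments:
            raise MitoError(f"feature {self.name!r} has no segments")
        for s, e in self.segments:
            if e <= s:
                raise MitoError(
                    f"feature {self.name!r}: segment ({s},{e}) not end>start; "
                    "wrap the origin with two segments instead"
                )
        if self.strand not in (1, -1):
            raise MitoError(f"feature {self.name!r}: strand must be +1/-1")
        if self.kind == "tRNA" and not self.name.startswith("trn"):
            raise MitoError(f"tRNA feature {self.name!r} must be named trn*")

    @property
    def length(self) -> int:
        """Summed exon length (introns in the host gene are excluded)."""
        return sum(e - s for s, e in self.segments)

    @property
    def start(self) -> int:
        """Genomic start of transcription (5' boundary on the strand)."""
        return self.segments[0][0] if self.strand == 1 else self.segments[0][1]

    @property
    def tx_start_boundary(self) -> int:
        """5' boundary in half-open convention along transcription: the
        coordinate where the feature begins (plus strand: segment start;
        minus strand: segment end)."""
        return self.segments[0][0] if self.strand == 1 else self.segments[0][1]

    @property
    def tx_end_boundary(self) -> int:
        """3' boundary in half-open convention along transcription."""
        return self.segments[-1][1] if self.strand == 1 else self.segments[-1][0]

    def min_start(self) -> int:
        return min(s for s, _ in self.segments)

    def genomic_extent(self, genome_length: int) -> list[tuple[int, int]]:
        """Full genomic span from first to last transcribed base, walking in
        transcription direction and crossing the origin if needed.  Introns of
        a multi-segment host gene fall inside this span.  Returns 1 interval,
        or 2 when the span wraps the origin."""
        if self.strand == 1:
            a, b = self.segments[0][0], self.segments[-1][1]
        else:
            a, b = self.segments[-1][0], self.segments[0][1]
        if a < b:
            return [(a, b)]
        return [(a, genome_length), (0, b)]

    def covered(self, genome_length: int) -> Iterator[int]:
        """All exon positions (modular)."""
        for s, e in self.segments:
            yield from range(s, e)


@dataclass
class MitoGenome:
    """An annotated (usually circular) mitochondrial genome."""

    id: str
    sequence: str
    is_circular: bool = True
    features: list[GeneFeature] = field(default_factory=list)
    metadata: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        bad = set(self.sequence) - DNA_ALPHABET
        if bad:
            raise MitoError(f"{self.id}: non-IUPAC characters {sorted(bad)}")
        if not self.sequence:
            raise MitoError(f"{self.id}: empty sequence")
        for f in self.features:
            for s, e in f.segments:
                if not (0 <= s < self.length and 0 < e <= self.length):
                    raise MitoError(
                        f"{self.id}: feature {f.name!r} segment ({s},{e}) "
                        f"outside [0,{self.length})"
                    )
        self.features.sort(key=lambda f: (f.min_start(), f.name))

    @property
    def length(self) -> int:
        return len(self.sequence)

    # -- feature access -----------------------------------------------------

    def features_of_kind(self, *kinds: str) -> list[GeneFeature]:
        return [f for f in self.features if f.kind in kinds]

    def genes(self) -> list[GeneFeature]:
        """Gene-level features: PCGs, rRNAs, tRNAs and free-standing ORFs
        (introns and intronic ORFs live inside host genes)."""
        return self.features_of_kind("PCG", "rRNA", "tRNA", "free_ORF")

    def get(self, name: str) -> GeneFeature:
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(f"{self.id}: no feature named {name!r}")

    def spliced(self, feature: GeneFeature) -> str:
        """Exon-concatenated sequence in transcription order."""
        parts = [self.sequence[s:e] for s, e in feature.segments]
        if feature.strand == -1:
            parts = [revcomp(p) for p in parts]
        return "".join(parts)

    def rotated(self, offset: int) -> "MitoGenome":
        """Genome with the circular origin moved to ``offset`` (new position 0
        is old position ``offset``); features re-normalized.  Only meaningful
        for circular genomes."""
        n = self.length
        offset %= n
        seq = self.sequence[offset:] + self.sequence[:offset]
        feats = []
        for f in self.features:
            segs: list[tuple[int, int]] = []
            for s, e in f.segments:
                ns, ne = (s - offset) % n, (e - offset) % n
                if ne == 0:
                    ne = n
                if ns < ne:
                    segs.append((ns, ne))
                else:  # segment now wraps: split
                    segs.append((ns, n))
                    segs.append((0, ne))
            segs = _coalesce(segs, f.strand)
            feats.append(
                GeneFeature(f.name, f.kind, segs, f.strand, f.anticodon, f.notes)
            )
        return MitoGenome(self.id, seq, self.is_circular, feats, dict(self.metadata))


def _coalesce(segs: list[tuple[int, int]], strand: int) -> list[tuple[int, int]]:
    """Merge segments that became contiguous after an origin rotation
    (a formerly wrapped feature unwraps into adjacent halves)."""
    out = [segs[0]]
    for s, e in segs[1:]:
        ps, pe = out[-1]
        if strand == 1 and s == pe:
            out[-1] = (ps, e)
        elif strand == -1 and e == ps:
            out[-1] = (s, pe)
        else:
            out.append((s, e))
    return out


_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]
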