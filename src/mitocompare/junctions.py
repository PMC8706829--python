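"""Gene-junction intervals and joining-state classification.

The joining interval of an adjacent same-strand gene pair is the signed
nucleotide count between them along the transcription direction: 0 means the
downstream gene starts immediately after the upstream gene ends (abutting),
-1 means a one-base overlap (the classic case where the last base of the
upstream TAA stop is the first base of the downstream ATG start), positive
values are intergenic separation.  Intervals wrap the circular origin.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from string import ascii_uppercase

import pandas as pd

from .gene_order import base_name
from .model import GeneFeature, MitoError, MitoGenome

#: interval -> state letter, as used for nad2/nad3 joining states
DEFAULT_STATE_MAP: dict[int, str] = {0: "A", -1: "B", 1: "C", 4: "D", 6: "E"}


@dataclass
class JunctionRecord:
    taxon: str
    upstream_gene: str
    downstream_gene: str
    interval_nt: int
    state_label: str | None = None
    flags: list[str] = field(default_factory=list)


def _candidates(genome: MitoGenome, symbol: str) -> list[GeneFeature]:
    exact = [f for f in genome.genes() if f.name == symbol]
    if exact:
        return exact
    return [f for f in genome.genes() if base_name(f.name) == symbol]


def _find_gene(genome: MitoGenome, symbol: str) -> GeneFeature:
    hits = _candidates(genome, symbol)
    if not hits:
        raise MitoError(f"{genome.id}: gene {symbol!r} absent")
    return hits[0]


def junction_interval(genome: MitoGenome, pair: tuple[str, str]) -> JunctionRecord:
    """Signed interval between ``pair = (upstream, downstream)``.

    The downstream feature is the next occurrence of its symbol after the
    upstream gene in transcription order (circularly).  Multi-segment genes
    contribute their transcription-order terminal boundaries, so introns never
    perturb the arithmetic.  Opposite-strand pairs are flagged, not computed.
    """
    up_sym, down_sym = pair
    up = _find_gene(genome, up_sym)
    down_candidates = _candidates(genome, down_sym)
    if not down_candidates:
        raise MitoError(f"{genome.id}: gene {down_sym!r} absent")
    n = genome.length

    if any(f.strand != up.strand for f in down_candidates):
        down_candidates = [f for f in down_candidates if f.strand == up.strand]
        if not down_candidates:
            rec = JunctionRecord(genome.id, up_sym, down_sym, 0)
            rec.flags.append("opposite strands: interval undefined")
            return rec

    # overlaps this small still count as "next in order" (clamped on tiny
    # genomes so the signed mapping stays unambiguous)
    MAX_OVERLAP = min(50, n // 3)

    def raw_gap(down: GeneFeature) -> int:
        if up.strand == 1:
            return (down.tx_start_boundary - up.tx_end_boundary) % n
        return (up.tx_end_boundary - down.tx_start_boundary) % n

    # next occurrence of the downstream symbol along transcription, treating a
    # small overlap (raw gap just below n) as immediate adjacency
    down = min(down_candidates, key=lambda f: (raw_gap(f) + MAX_OVERLAP) % n)
    raw = raw_gap(down)
    interval = raw - n if raw > n - MAX_OVERLAP else raw
    return JunctionRecord(genome.id, up_sym, down_sym, interval)


def classify_joining(
    records: list[JunctionRecord],
    state_map: dict[int, str] | None = None,
) -> tuple[list[JunctionRecord], pd.Series]:
    """Assign a state letter to each record from ``state_map`` (default: the
    nad2/nad3 map A:0, B:-1, C:1, D:4, E:6); intervals not in the map get new
    letters in order of appearance.  Returns the labelled records and a census
    of counts per state letter."""
    smap = dict(DEFAULT_STATE_MAP if state_map is None else state_map)
    used = set(smap.values())
    next_letters = (c for c in ascii_uppercase if c not in used)
    for rec in records:
        if rec.interval_nt not in smap:
            smap[rec.interval_nt] = next(next_letters)
        rec.state_label = smap[rec.interval_nt]
    census = pd.Series(
        [r.state_label for r in records], name="state", dtype="object"
    ).value_counts().sort_index()
    return records, census


def audit_fixed_junction(
    genomes: list[MitoGenome],
    pair: tuple[str, str] = ("nad4L", "nad5"),
    expected: int = -1,
) -> pd.DataFrame:
    """Compute ``pair`` across all genomes and report deviations from the
    expected interval (default -1: the invariant one-base nad4L/nad5 overlap)."""
    rows = []
    for g in genomes:
        try:
            rec = junction_interval(g, pair)
            rows.append((g.id, rec.interval_nt, rec.interval_nt != expected,
                         ";".join(rec.flags)))
        except MitoError as exc:
            rows.append((g.id, None, True, str(exc)))
    return pd.DataFrame(rows, columns=["taxon", "interval_nt", "deviates", "flags"])
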