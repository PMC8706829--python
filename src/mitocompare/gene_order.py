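"""Signed circular gene orders and arrangement-pattern classification.

A mitogenome's arrangement is summarized as the circular order of the 16 core
genes (14 core PCGs + rnl + rns), each carrying its strand as a sign.  Orders
are compared in a canonical form: orientation flipped so the majority of genes
are on the plus strand (these genomes are typically single-strand transcribed,
so inverted genes appear as minority minus signs), then rotated to start at
rnl (or the lexicographically smallest rotation if rnl is absent).  Two
genomes share an arrangement pattern iff their canonical core orders are
identical; patterns are lettered A, B, ... by descending membership.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .model import CORE_GENES, MitoError, MitoGenome

Signed = tuple[str, int]  # (gene symbol, +1/-1)


def base_name(name: str) -> str:
    """Strip a _N duplicate suffix: trnM_2 -> trnM."""
    stem, _, suffix = name.rpartition("_")
    return stem if stem and suffix.isdigit() else name


@dataclass
class GeneOrderSignature:
    taxon: str
    symbols: list[Signed]
    trn_track: list[Signed] | None = None
    missing: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        names = [g for g, _ in self.symbols]
        if len(set(names)) != len(names):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise MitoError(f"{self.taxon}: duplicated core gene(s) {dup}")

    def as_strings(self) -> list[str]:
        return [("-" if s < 0 else "") + g for g, s in self.symbols]

    @classmethod
    def from_strings(cls, taxon: str, tokens: list[str],
                     missing: frozenset[str] = frozenset()) -> "GeneOrderSignature":
        sym = [(t.lstrip("+-"), -1 if t.startswith("-") else 1) for t in tokens]
        return cls(taxon, sym, missing=missing)


@dataclass
class PatternAssignment:
    pattern_label: str
    member_taxa: list[str]
    representative: GeneOrderSignature
    description: str = ""
    partial_members: dict[str, str] = field(default_factory=dict)

    @property
    def size(self) -> int:
        return len(self.member_taxa)


def extract_order(genome: MitoGenome,
                  gene_set: tuple[str, ...] = CORE_GENES,
                  with_trn: bool = False) -> GeneOrderSignature:
    """Circular genomic order of ``gene_set`` members from the genome start,
    with strand as sign; genes absent from the annotation are recorded in
    ``missing``.  A core gene annotated twice is an error."""
    core: list[Signed] = []
    track: list[Signed] = []
    seen: set[str] = set()
    for f in sorted(genome.genes(), key=lambda f: f.min_start()):
        b = base_name(f.name)
        if b in gene_set:
            if b in seen:
                raise MitoError(f"{genome.id}: core gene {b} annotated more than once")
            seen.add(b)
            core.append((b, f.strand))
            track.append((b, f.strand))
        elif f.kind == "tRNA":
            track.append((b, f.strand))
    missing = frozenset(g for g in gene_set if g not in seen)
    return GeneOrderSignature(
        genome.id, core, trn_track=track if with_trn else None, missing=missing
    )


def _flip(symbols: list[Signed]) -> list[Signed]:
    return [(g, -s) for g, s in reversed(symbols)]


def _rotations(symbols: list[Signed]):
    n = len(symbols)
    for i in range(n):
        yield symbols[i:] + symbols[:i]


def _rotate_to(symbols: list[Signed], gene: str) -> list[Signed]:
    idx = next(i for i, (g, _) in enumerate(symbols) if g == gene)
    return symbols[idx:] + symbols[:idx]


def _rotate_canonical(symbols: list[Signed]) -> list[Signed]:
    if any(g == "rnl" for g, _ in symbols):
        return _rotate_to(symbols, "rnl")
    return list(min(_rotations(symbols), key=tuple))


def canonicalize(sig: GeneOrderSignature) -> GeneOrderSignature:
    """Canonical form: majority-plus orientation, then rotation to rnl (or the
    lexicographically smallest rotation when rnl is absent).  A sign tie is
    broken by preferring +rnl and then the lexicographically smaller rotated
    form, so all rotations and the reflected form of an order map to one
    canonical form."""
    symbols = list(sig.symbols)
    if not symbols:
        return sig
    n_minus = sum(1 for _, s in symbols if s < 0)
    n_plus = len(symbols) - n_minus
    if n_minus > n_plus:
        symbols = _rotate_canonical(_flip(symbols))
    elif n_minus == n_plus:
        key = lambda syms: (dict(syms).get("rnl", 1) != 1, tuple(syms))
        symbols = min(
            _rotate_canonical(symbols), _rotate_canonical(_flip(symbols)), key=key
        )
    else:
        symbols = _rotate_canonical(symbols)
    track = sig.trn_track
    if track is not None and any(g == "rnl" for g, _ in track):
        track = _rotate_to(list(track), "rnl")
    return GeneOrderSignature(sig.taxon, symbols, trn_track=track, missing=sig.missing)


def _adjacencies(symbols: list[Signed]) -> set[tuple[str, str]]:
    """Signed circular adjacency set; a minus-strand gene g is written -g."""
    toks = [("-" if s < 0 else "") + g for g, s in symbols]
    return {(toks[i], toks[(i + 1) % len(toks)]) for i in range(len(toks))}


def _describe(pattern: list[Signed], dominant: list[Signed]) -> str:
    """Minimal edit note for a pattern relative to the dominant one, from the
    difference of the two adjacency sets."""
    inverted = []
    dom_sign = dict(dominant)
    pat_sign = dict(pattern)
    for g, s in pat_sign.items():
        if g in dom_sign and dom_sign[g] != s:
            inverted.append(g)
    pat_adj = _adjacencies(pattern)
    dom_adj = _adjacencies([x for x in dominant if x[0] in pat_sign])
    changed: dict[str, int] = {}
    for a, b in pat_adj ^ dom_adj:
        for tok in (a, b):
            changed[tok.lstrip("-")] = changed.get(tok.lstrip("-"), 0) + 1
    notes = []
    order = [g for g, _ in pattern]
    moved = [
        g for g, c in changed.items()
        if c >= 3 and g not in inverted and g in pat_sign
    ]
    for g in sorted(moved, key=order.index):
        i = order.index(g)
        prev, nxt = order[i - 1], order[(i + 1) % len(order)]
        notes.append(f"{g} translocated to the {prev}/{nxt} intergenic region")
    for g in sorted(inverted, key=order.index):
        notes.append(f"{g} inverted")
    missing = [g for g, _ in dominant if g not in pat_sign]
    if missing:
        notes.append("lacking " + " and ".join(missing))
    return "; ".join(notes) if notes else ("identical to dominant pattern"
                                           if pat_adj == dom_adj else "rearranged")


def classify_patterns(sigs: list[GeneOrderSignature]) -> list[PatternAssignment]:
    """Group signatures by exact canonical core-order equality and letter the
    groups by descending size (ties by first appearance).  A signature with
    missing core genes joins the first pattern that reduces to it when those
    genes are deleted, recorded as a partial match."""
    if not sigs:
        raise MitoError("classify_patterns needs at least one signature")
    canon = [canonicalize(s) for s in sigs]
    complete = [s for s in canon if not s.missing]
    partial = [s for s in canon if s.missing]

    groups: dict[tuple, list[GeneOrderSignature]] = {}
    first_seen: dict[tuple, int] = {}
    for i, s in enumerate(complete):
        key = tuple(s.symbols)
        groups.setdefault(key, []).append(s)
        first_seen.setdefault(key, i)

    ordered = sorted(groups, key=lambda k: (-len(groups[k]), first_seen[k]))
    assignments = [
        PatternAssignment(
            pattern_label="",  # lettered below, after partials join
            member_taxa=[s.taxon for s in groups[k]],
            representative=groups[k][0],
        )
        for k in ordered
    ]

    leftovers: list[GeneOrderSignature] = []
    for s in partial:
        target = None
        for pa in assignments:
            reduced = [x for x in pa.representative.symbols if x[0] not in s.missing]
            if tuple(canonicalize(
                GeneOrderSignature(s.taxon, reduced)).symbols) == tuple(s.symbols):
                target = pa
                break
        if target is not None:
            target.member_taxa.append(s.taxon)
            target.partial_members[s.taxon] = (
                "partial match (lacking " + ", ".join(sorted(s.missing)) + ")"
            )
        else:
            leftovers.append(s)
    for s in leftovers:
        assignments.append(
            PatternAssignment("", [s.taxon], s,
                              partial_members={s.taxon: "incomplete gene set"})
        )

    assignments.sort(key=lambda pa: (-pa.size,
                                     sigs.index(next(x for x in sigs
                                                     if x.taxon == pa.member_taxa[0]))))
    dominant = assignments[0].representative.symbols
    for i, pa in enumerate(assignments):
        pa.pattern_label = chr(ord("A") + i)
        if i > 0:
            pa.description = _describe(pa.representative.symbols, dominant)
        else:
            pa.description = "dominant pattern"
    return assignments


def trn_cluster_report(sigs: list[GeneOrderSignature]) -> pd.DataFrame:
    """Per inter-core interval, the number of consecutive tRNA genes in each
    taxon; the ``variable`` column flags intervals whose count differs across
    taxa (or which do not exist in every taxon)."""
    if any(s.trn_track is None for s in sigs):
        raise MitoError("trn_cluster_report requires signatures with a trn track")
    canon = [canonicalize(s) for s in sigs]
    per_taxon: dict[str, dict[tuple[str, str], int]] = {}
    for s in canon:
        track = s.trn_track or []
        cores = [(i, g) for i, (g, _) in enumerate(track) if not g.startswith("trn")]
        intervals: dict[tuple[str, str], int] = {}
        for j, (i, g) in enumerate(cores):
            i2, g2 = cores[(j + 1) % len(cores)]
            if j + 1 < len(cores):
                count = i2 - i - 1
            else:  # wrap
                count = (len(track) - i - 1) + cores[0][0]
            intervals[(g, g2)] = count
        per_taxon[s.taxon] = intervals
    all_pairs: list[tuple[str, str]] = []
    for iv in per_taxon.values():
        for p in iv:
            if p not in all_pairs:
                all_pairs.append(p)
    df = pd.DataFrame(
        {
            taxon: [per_taxon[taxon].get(p) for p in all_pairs]
            for taxon in per_taxon
        },
        index=pd.Index([f"{a}->{b}" for a, b in all_pairs], name="interval"),
        dtype="Float64",
    )
    counts = df.to_numpy()
    variable = []
    for row in counts:
        vals = {v for v in row}
        variable.append(len(vals) > 1 or any(pd.isna(v) for v in row))
    df["variable"] = variable
    return df
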