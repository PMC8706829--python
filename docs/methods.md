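# Methods

This note documents the models, conventions and numerical choices behind
mitocompare, and what the synthetic test bed does and does not establish.

## Coordinate and data model

Internally all coordinates are 0-based half-open; GenBank I/O converts from
1-based inclusive at the boundary.  A feature that spans the circular origin
is stored as multiple segments in transcription order, each with end > start;
no coordinate ever exceeds the genome length, which keeps modular arithmetic
confined to one normalization step (rotation) and makes junction arithmetic
plain subtraction.  Gene symbols are canonicalized through a user-extensible
synonym table (ND4L→nad4L, CYTB→cob, LSU→rnl, tRNA-Met→trnM, …); duplicated
symbols are numbered `_1, _2, …` in genome order from the record start.  The
numbering of tRNA duplicates follows genome order rather than anticodon
identity — public records are inconsistent here, and genome order is the only
convention that is always recoverable.

CDS-only records are typed by product text and containment: a CDS whose
product mentions ribosomal protein S3 or a homing endonuclease, or whose span
lies inside another gene's extent, is an intronic ORF; other non-core CDSs
are free-standing ORFs.

## Composition and region accounting

AT% uses A+C+G+T as denominator; skews are (A−T)/(A+T) and (G−C)/(G+C).
N bases are excluded from all composition denominators but kept in genome
size — degenerate bases should not bias skews, and published tables count
them in length.  Genic nucleotides are the union of the genomic extents of
all gene-level features (core PCGs, rRNAs, tRNAs, free ORFs).  Introns count
as genic because they sit inside host-gene extents, and overlapping genes
(the one-base nad4L/nad5 overlap) are counted once; this union semantics is
forced by the requirement that genic + intergenic equal genome size exactly.
Intronic nucleotides are the summed intron lengths, intronic ORFs included.
Percentages are reported at one decimal, skews at two, matching the usual
table precision in this literature.

The codon audit splices each coding feature, reports first/last codon, and
flags non-ATG starts, absent stops, and lengths not divisible by three.  The
default genetic code is the mold mitochondrial code (NCBI table 4), under
which TGA encodes tryptophan and only TAA/TAG terminate; fungal mitochondria
require this table even though records rarely state it.

## Gene order and arrangement patterns

A genome's arrangement is the circular order of the 16 core genes with
strand signs.  Canonical form: if minus signs are the majority, the order is
reflected (reverse + negate) — these genomes are typically single-strand
transcribed, so inversions appear as minority minus signs; sign ties are
broken toward +rnl and then the lexicographically smaller form.  The order is
then rotated to start at rnl, or to the lexicographically smallest rotation
when rnl is missing.  Pattern identity is exact canonical equality, not a
rearrangement distance: the phenomenon being described is a small set of
discrete arrangement classes, so a metric would add assumptions without
adding information.  Patterns are lettered by descending membership.  A
genome lacking core genes joins the first pattern that reduces to it when
those genes are deleted, recorded as a partial match, so incomplete
annotations do not inflate the pattern count.  Edit notes per pattern come
from the symmetric difference of signed adjacency sets against the dominant
pattern: a gene with both neighbours changed and sign intact is reported as
translocated (with its new flanks), a sign change as inverted.

## Junctions

The joining interval of an ordered same-strand pair is
(downstream 5' boundary − upstream 3' boundary) along transcription, in
half-open coordinates with circular unwrapping: 0 means abutting, −1 the
classic one-base overlap in which the last base of the upstream TAA is the
first base of the downstream ATG, positive values are spacers.  Raw modular
gaps within 50 nt of a full circle are interpreted as overlaps (clamped to a
third of the genome on toy inputs).  Multi-segment hosts contribute their
outermost exon boundaries, so introns never perturb the arithmetic.
Opposite-strand pairs are flagged as unsupported rather than computed — the
interval is not well defined along a single transcription direction there.
The default interval→letter map is A:0, B:−1, C:1, D:4, E:6; unseen intervals
get fresh letters in order of appearance.

## Introns

Positional names follow the established homolog-coordinate convention:
mL<pos> for rnl introns, mS<pos> for rns, <gene>P<pos> for protein genes.
The position is read off a global affine alignment (match 2, mismatch −1,
gap open 6, extend 0.5) of the spliced host to a user-supplied reference
gene: the reference base aligned to the last upstream-exon base, falling back
to the nearest upstream aligned base when it sits in a reference gap.
References are explicit configuration — positional names are only meaningful
relative to a stated coordinate system — and alignments under 40% identity
are rejected as unreliable.  Group I subgroup labels (IA/IB) are metadata
passthrough; structural RNA classification is out of scope.  The boundary
diagnostic is the group I signature: upstream exon ends T, intron ends G.

ORF detection is sense-strand only (single-strand transcription), ATG to
in-frame stop inclusive, ≥300 nt by default, named orf<aa length>; for each
stop only the longest ORF survives and nested ORFs are suppressed.
Endonuclease classes are assigned by simple protein-motif regular expressions
(LAGLIDADG; GIY…YIG) and are flagged as heuristic.

## Intraspecific variation

Near-identical genomes are aligned with a hand-written banded affine global
aligner (Gotoh three states; match 1, mismatch −1, gap of length L costs
10 + 0.5·L) restricted to a diagonal band of half-width 200 that always
spans both end diagonals, so a single indel longer than the band is still
representable; if the optimal traceback touches the band edge the band is
doubled (to 4× the request) before erroring.  The numba-compiled kernel
aligns two 30 kb genomes in under a second; its scores equal an unbanded
full dynamic program on sequences where that is checkable.  Multiple
sequences are aligned progressively against the first as anchor and merged
on anchor coordinates (same-position insertions left-aligned and padded).
A pre-aligned FASTA can be supplied instead, to reproduce results from an
external aligner.

Columns are tallied into two disjoint classes — indel columns (≥1 gap) and
variable columns (gap-free, ≥2 distinct bases) — and divergence is
100·(indel + variable)/alignment length.  This definition is a documented
choice: variation tools report several divergence flavours, so the
variable-only rate is also written into the report metadata.  Sites map
through the reference row's ungapped coordinates to the genic/intergenic
union; insertion columns relative to the reference are attributed to the
nearest 5' reference base.  A variable coding site is synonymous iff every
alternate codon translates identically under table 4; sites whose codon
includes a gapped column are excluded from the syn/nonsyn census as
indel-adjacent rather than guessed.

## Ancestral reconstruction

One discrete character on a rooted tree with branch lengths evolves under
the k-state equal-rates Markov model,
P(i→j, t) = 1/k + (δ_ij − 1/k)·e^(−k·r·t/(k−1)), with a uniform root prior.
The likelihood is computed by post-order pruning with per-node rescaling;
multifurcations are handled natively and taxa absent from the state matrix
contribute all-ones partials.  The rate r (expected changes per unit branch
length) is estimated by golden-section search on log r over [10⁻⁶, 10³]
(tolerance 10⁻⁶); an invariant character drives the estimate to the lower
bound and is flagged as such rather than reported as a point estimate.
Node marginals combine upward partials with downward messages and are
reported as percentages ("occurrences"); transition counts compare
maximum-probability states across each branch, with ties broken by alphabet
order.  A reference Bayesian tool for this task integrates over rates by
MCMC; the default here is ML marginal reconstruction, because the scientific
question — which state is ancestral, and roughly how strongly — is answered
by marginals, and the package makes no claim of numerical equality with any
particular tool's posterior percentages.  A seeded Metropolis option
(uniform rate prior, log-rate random walk, thinned posterior average of the
marginals) is provided for posterior-style occurrences.

## Synthetic data

The generator emulates the study system: a circular ~30.7 kb single-strand
genome at 74% AT (with mild skews: T over A, G over C), carrying the 14 core
PCGs, both rRNAs, 28 tRNAs (clusters of 13/5/5 downstream of rnl/rns/nad6
plus singletons), two free ORFs, and two group I introns — one in rnl at
host position 2450 with an rps3 ORF, one in cox1 at position 1125 with a
LAGLIDADG ORF, 3,884 nt together.  The default core order places cox1
between rnl and nad2; the alternative dominant arrangement (cox1 between cob
and nad1) is provided as a constant.  These layouts are reconstructed from
the adjacency facts the study system reports (tRNA clusters, fixed
singletons, which intergenic regions host which ORFs); where the full order
was not printed, the choice was made once and is fixed here.

Coding sequences are generated codon-wise from a stop-free sampler (the
sampler aims 1.6 AT points above target to compensate for rejecting the
AT-rich stops); junction overrides are honored exactly, with the −1 overlap
built by sharing the TAA/ATG base; intron boundaries are forced to the T/G
rule with a codon repair step that never creates a stop.  Genome size is hit
exactly by distributing the residual over unconstrained spacers
(multinomial, minimum 20 nt).  An unrealizable request errors before any
sequence is emitted.  All randomness flows from one explicitly seeded
generator per operation; the same seed gives byte-identical output.

Mutated individuals keep the reference untouched and assign each planted
substitution/deletion to one random other individual, with footprints ≥30 nt
apart, away from sequence ends, and region-homogeneous, so alignment columns
map one-to-one to plants and the effect computed at plant time (syn/nonsyn
under table 4) is exact.  Defaults mirror the intraspecific regime this
package targets: 36 substitutions at a 0.64 genic fraction, 33 deletions of
1–9 nt at a 0.73 intergenic fraction, across 3 individuals.  Character
simulation draws the root from the uniform prior and applies the closed-form
branch transition probability; trees for testing come from a seeded Yule
process rescaled to unit depth, so rates read as changes per tree depth.

What passing synthetic tests do not show: real annotations are messier than
the generator (pseudo-features, nonstandard qualifiers, trans-spliced genes),
real intraspecific variation is not spatially separated or single-hit, codon
usage and tRNA sequences are not biologically realistic, and intron ORFs in
real data can overlap exon boundaries.  The parsers normalize what they can
and flag the rest; exact-tally guarantees hold only under the generator's
separation assumptions.

## Problem sizes used in the checks

The bundled checks run on one 30.7 kb genome (or small cohorts of ≤4), a
three-individual mutation cohort, enumeration oracles on trees of ≤6 leaves,
and 50-replicate simulation studies on 64–100-leaf trees — sizes at which
every oracle is exact or the sampling error is far below the asserted
margins, and the whole suite runs in well under a minute of compute after
JIT warm-up.

## Known limitations

Pattern descriptions are heuristic beyond single translocations/inversions
(compound rearrangements are reported as "rearranged"); the banded aligner
assumes high identity and cannot detect a superior alignment lying wholly
outside the band; positional intron names depend on the supplied reference
(no reference, no name); tRNA secondary structure, assembly, tree inference
and divergence dating are out of scope — trees are inputs.
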