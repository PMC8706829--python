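"""End-to-end orchestration of the comparative stages.

Stages communicate through files so each is independently usable; every
output TSV carries a provenance header (tool version, config hash, seed), and
a parse failure of one genome is collected rather than aborting the cohort.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .ancestral import CharacterStateMatrix, MkModel
from .gene_order import classify_patterns, extract_order, trn_cluster_report
from .io import read_fasta, read_genbank, write_feature_table
from .junctions import audit_fixed_junction, classify_joining, junction_interval
from .introns import catalog_introns
from .model import MitoError, MitoGenome
from .summary import region_accounting
from .variation import align_high_identity, tally_sites

log = logging.getLogger("mitocompare")


@dataclass
class RunConfig:
    genbank_paths: list[str]
    out_dir: str
    stages: tuple[str, ...] = ("parse", "summary", "order", "junctions",
                               "introns", "variation", "ancestral")
    transl_table: int = 4
    band: int = 200
    with_trn: bool = True
    junction_pairs: tuple[tuple[str, str], ...] = (("nad2", "nad3"),
                                                   ("nad4L", "nad5"))
    reference_fastas: dict[str, str] = field(default_factory=dict)
    aligned_fasta: str | None = None  # pre-aligned input bypasses the aligner
    variation_reference: str | None = None  # genome id; default: first parsed
    tree_path: str | None = None
    states_path: str | None = None
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {k: v for k, v in raw.items() if k in cls.__dataclass_fields__}
        if "junction_pairs" in known:
            known["junction_pairs"] = tuple(tuple(p) for p in known["junction_pairs"])
        if "stages" in known:
            known["stages"] = tuple(known["stages"])
        missing = {"genbank_paths", "out_dir"} - set(known)
        if missing:
            raise MitoError(f"run config missing {sorted(missing)}")
        return cls(**known)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _provenance(config: RunConfig) -> str:
    return (f"# mitocompare {__version__}\n"
            f"# config_hash {config.config_hash()}\n"
            f"# seed {config.seed}\n")


def run_pipeline(config: RunConfig) -> dict[str, object]:
    """Execute the configured stages in dependency order; returns the in-memory
    results keyed by stage.  Per-genome parse failures are collected in
    ``results['errors']``; an empty input set is fatal."""
    logging.basicConfig(level=config.log_level, stream=sys.stderr,
                        format="%(name)s %(levelname)s %(message)s")
    if not config.genbank_paths:
        raise MitoError("empty input set")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    header = _provenance(config)
    results: dict[str, object] = {"errors": []}

    genomes: list[MitoGenome] = []
    for p in config.genbank_paths:
        try:
            genomes.append(read_genbank(p))
        except Exception as exc:
            log.error("skipping %s: %s", p, exc)
            results["errors"].append(f"{p}: {exc}")
    if not genomes:
        raise MitoError("no genome could be parsed")
    results["genomes"] = genomes

    if "parse" in config.stages:
        for g in genomes:
            (out / f"{g.id}.features.tsv").write_text(header + write_feature_table(g))

    if "summary" in config.stages:
        summaries = [region_accounting(g, config.transl_table) for g in genomes]
        results["summary"] = summaries
        (out / "summary.tsv").write_text(
            header + "".join(s.to_tsv() + "\n" for s in summaries))

    sigs = None
    if "order" in config.stages:
        sigs = [extract_order(g, with_trn=config.with_trn) for g in genomes]
        patterns = classify_patterns(sigs)
        results["patterns"] = patterns
        lines = [header + "pattern\tn\ttaxa\tdescription"]
        for pa in patterns:
            lines.append(f"{pa.pattern_label}\t{pa.size}\t"
                         f"{','.join(pa.member_taxa)}\t{pa.description}")
        (out / "patterns.tsv").write_text("\n".join(lines) + "\n")
        if config.with_trn:
            results["trn_clusters"] = trn_cluster_report(sigs)
            (out / "trn_clusters.tsv").write_text(
                header + results["trn_clusters"].to_csv(sep="\t"))

    if "junctions" in config.stages:
        jlines = [header + "pair\ttaxon\tinterval\tstate"]
        jresults = {}
        for pair in config.junction_pairs:
            recs = []
            for g in genomes:
                try:
                    recs.append(junction_interval(g, pair))
                except MitoError as exc:
                    results["errors"].append(str(exc))
            recs, census = classify_joining(recs)
            jresults[pair] = (recs, census)
            for r in recs:
                jlines.append(f"{pair[0]}/{pair[1]}\t{r.taxon}\t"
                              f"{r.interval_nt}\t{r.state_label}")
        results["junctions"] = jresults
        results["nad4L_nad5_audit"] = audit_fixed_junction(genomes)
        (out / "junctions.tsv").write_text("\n".join(jlines) + "\n")

    if "introns" in config.stages:
        refs = {sym: read_fasta(path)[0][1]
                for sym, path in config.reference_fastas.items()}
        catalog = {g.id: catalog_introns(g, refs) for g in genomes}
        results["introns"] = catalog
        ilines = [header + "taxon\thost\tname\tref_pos\tboundary_T\tboundary_G\torf\torf_class"]
        for gid, recs in catalog.items():
            for r in recs:
                ilines.append(f"{gid}\t{r.host_gene}\t{r.name}\t{r.insertion_ref_pos}"
                              f"\t{r.boundary_ok[0]}\t{r.boundary_ok[1]}"
                              f"\t{r.orf or ''}\t{r.orf_class or ''}")
        (out / "introns.tsv").write_text("\n".join(ilines) + "\n")

    if "variation" in config.stages and len(genomes) >= 2:
        ref = genomes[0]
        if config.variation_reference:
            ref = next(g for g in genomes if g.id == config.variation_reference)
        if config.aligned_fasta:
            alignment = read_fasta(config.aligned_fasta)
        else:
            alignment = align_high_identity(
                [(g.id, g.sequence) for g in genomes], band=config.band)
        report = tally_sites(alignment, ref, config.transl_table)
        results["variation"] = report
        meta = "".join(f"# {k} {v}\n" for k, v in report.metadata.items())
        (out / "variation.tsv").write_text(header + meta + report.to_tsv())

    if "ancestral" in config.stages and config.tree_path and config.states_path:
        states = CharacterStateMatrix.from_tsv(config.states_path)
        res = MkModel(config.tree_path, states).fit(seed=config.seed)
        results["ancestral"] = res
        (out / "ancestral.tsv").write_text(header + res.to_tsv())
        (out / "ancestral.nwk").write_text(res.annotated_newick() + "\n")

    (out / "run_config.json").write_text(
        json.dumps(asdict(config), indent=2, default=str))
    return results
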