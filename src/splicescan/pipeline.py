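"""End-to-end per-species analysis: the library behind the `splicescan` CLI.

Given a genome, annotation and (optionally) coverage/count/variant/homolog
inputs, runs representative-transcript selection, intron extraction,
combination tabulation, RNA-Seq validation, usage, frame and diversity
summaries, and writes one TSV per result plus a machine-readable run log.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .annotation import (
    CombinationTable,
    GenomeSequence,
    IntronRecord,
    TranscriptModel,
    cds_offset,
    combination_table,
    extract_introns,
    flank_profile,
    introns_to_bed,
    parse_annotation,
    parse_genome,
    select_representative,
)
from .coverage import (
    build_expression_records,
    expression_bins,
    load_coverage,
    read_count_table,
    splice_usage,
    support_table,
    usage_table,
    validate_splice_site,
)
from .stats import frame_summary, intron_frame_check, species_summary, kingdom_table
from .variants import (
    internal_exonic_intervals,
    parse_vcf,
    splice_variant_rates,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    fasta: Path
    gff3: Path
    outdir: Path
    coverage: Path | None = None
    junctions: Path | None = None
    counts: Path | None = None
    vcf: Path | None = None
    species_id: str = "species"
    kingdom: str = "unknown"
    min_reads: int = 3
    drop: float = 0.2
    flank_exonic: int = 7
    flank_intronic: int = 7
    outlier_quantile: float = 0.99
    seed: int = 0

    def validate(self) -> None:
        for name in ("fasta", "gff3"):
            p = getattr(self, name)
            if not Path(p).exists():
                raise FileNotFoundError(f"{name} input does not exist: {p}")
        if not 0 < self.drop < 1:
            raise ValueError(f"drop must be in (0,1), got {self.drop}")
        if self.min_reads < 0:
            raise ValueError("min_reads must be non-negative")


@dataclass
class ReportBundle:
    table: CombinationTable
    transcripts: list[TranscriptModel]
    introns: list[IntronRecord]
    outputs: dict[str, Path] = field(default_factory=dict)


def _checksum(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def representative_transcripts(
    models: list[TranscriptModel],
) -> list[TranscriptModel]:
    by_gene: dict[str, list[TranscriptModel]] = {}
    for m in models:
        by_gene.setdefault(m.gene_id, []).append(m)
    return [select_representative(ts) for _, ts in sorted(by_gene.items())]


def run_species(cfg: RunConfig) -> ReportBundle:
    """Run the per-species pipeline and write the report tables.

    Coverage-dependent tables (support, usage) are produced only when
    coverage input is given; the run completes annotation-only otherwise,
    with a warning.
    """
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}

    genome = parse_genome(cfg.fasta)
    models = parse_annotation(cfg.gff3, genome)
    reps = representative_transcripts(models)
    introns: list[IntronRecord] = []
    introns_by_tx: dict[str, list[IntronRecord]] = {}
    for t in reps:
        recs = extract_introns(t, genome)
        introns.extend(recs)
        introns_by_tx[t.transcript_id] = recs

    table = combination_table(introns, species_id=cfg.species_id)
    outputs["combinations"] = outdir / "combination_table.tsv"
    table.write_tsv(outputs["combinations"])

    outputs["introns_bed"] = outdir / "introns.bed"
    introns_to_bed(introns).to_csv(outputs["introns_bed"], sep="\t",
                                   index=False, header=False)

    for site in ("5prime", "3prime"):
        profile = flank_profile(introns, genome, site,
                                exonic=cfg.flank_exonic,
                                intronic=cfg.flank_intronic)
        outputs[f"flank_{site}"] = outdir / f"flank_profile_{site}.tsv"
        profile.write_tsv(outputs[f"flank_{site}"])

    # frame analysis over CDS introns
    rep_by_tx = {t.transcript_id: t for t in reps}
    qualifies = [
        intron_frame_check(i, cds_offset(rep_by_tx[i.transcript_id], i))
        for i in introns
    ]
    frames = frame_summary(introns, qualifies, by="class")
    outputs["frame_summary"] = outdir / "frame_summary.tsv"
    pd.DataFrame(
        [
            {"class": f.class_label, "n_qualifying": f.n_qualifying,
             "n_total": f.n_total, "proportion": f.proportion}
            for f in frames
        ]
    ).to_csv(outputs["frame_summary"], sep="\t", index=False)

    summary = species_summary(cfg.species_id, cfg.kingdom, genome, reps,
                              introns, table)
    outputs["species_summary"] = outdir / "species_summary.tsv"
    kingdom_table([summary]).to_csv(outputs["species_summary"], sep="\t",
                                    index=False)

    track = None
    if cfg.coverage is not None:
        track = load_coverage(cfg.coverage, genome, junctions_path=cfg.junctions)
        results = [
            validate_splice_site(i, track, min_reads=cfg.min_reads, drop=cfg.drop)
            for i in introns
        ]
        outputs["support"] = outdir / "support_table.tsv"
        support_table(results).to_csv(outputs["support"], sep="\t", index=False)

        usages = [splice_usage(i, track) for i in introns]
        outputs["usage"] = outdir / "usage_table.tsv"
        usage_table(usages).to_csv(outputs["usage"], sep="\t", index=False)
    else:
        logger.warning(
            "no coverage input: support and usage tables are not produced"
        )

    if cfg.counts is not None:
        counts = read_count_table(cfg.counts)
        lengths = {t.gene_id: t.exonic_length for t in reps}
        classes: dict[str, set[str]] = {}
        for t in reps:
            labels = set()
            for i in introns_by_tx[t.transcript_id]:
                combo = i.combination
                if combo == "GT-AG":
                    labels.add("canonical")
                elif combo == "GC-AG":
                    labels.add("major:GC-AG")
                elif combo == "AT-AC":
                    labels.add("major:AT-AC")
                elif not i.ambiguous:
                    labels.add("minor")
            classes[t.gene_id] = labels
        records = build_expression_records(counts, lengths, classes)
        outputs["expression_bins"] = outdir / "expression_bins.tsv"
        expression_bins(records,
                        outlier_quantile=cfg.outlier_quantile).to_csv(
            outputs["expression_bins"], sep="\t", index=False)

    if cfg.vcf is not None:
        variants = parse_vcf(cfg.vcf)
        background = internal_exonic_intervals(reps)
        rates = splice_variant_rates(variants, introns, background)
        outputs["variant_rates"] = outdir / "variant_rates.tsv"
        rates.to_frame().to_csv(outputs["variant_rates"], sep="\t", index=False)

    run_log = {
        "splicescan_version": __version__,
        "species_id": cfg.species_id,
        "thresholds": {
            "min_reads": cfg.min_reads,
            "drop": cfg.drop,
            "flank_exonic": cfg.flank_exonic,
            "flank_intronic": cfg.flank_intronic,
            "outlier_quantile": cfg.outlier_quantile,
        },
        "seed": cfg.seed,
        "inputs": {
            name: {"path": str(p), "sha256_16": _checksum(p)}
            for name, p in (
                ("fasta", cfg.fasta), ("gff3", cfg.gff3),
                ("coverage", cfg.coverage), ("junctions", cfg.junctions),
                ("counts", cfg.counts), ("vcf", cfg.vcf),
            )
            if p is not None
        },
        "outputs": {k: str(v) for k, v in outputs.items()},
        "n_transcripts": len(reps),
        "n_introns": len(introns),
    }
    log_path = outdir / "run_log.json"
    with open(log_path, "w") as fh:
        json.dump(run_log, fh, indent=1)
    outputs["run_log"] = log_path

    return ReportBundle(table=table, transcripts=reps, introns=introns,
                        outputs=outputs)
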