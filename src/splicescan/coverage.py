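"""RNA-Seq evidence: junction validation, splice-site usage, expression bins.

An annotated splice site counts as supported when the intron is spanned by at
least ``min_reads`` split-aligned reads and the per-base coverage drops by at
least ``drop`` (default 20%) when moving from the exon into the intron at
both borders.  A retained intron keeps exonic depth across its body and fails
both conditions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .annotation import GenomeSequence, IntronRecord

logger = logging.getLogger(__name__)


@dataclass
class CoverageTrack:
    """Per-base read depth plus exact-junction split-read counts."""

    depth: dict[str, np.ndarray]
    junction_reads: dict[tuple[str, int, int], int]

    def depth_at(self, chrom: str, pos: int) -> int:
        arr = self.depth[chrom]
        if pos < 0 or pos >= len(arr):
            return 0
        return int(arr[pos])

    def junctions_spanning(self, chrom: str, start: int, end: int) -> int:
        return self.junction_reads.get((chrom, start, end), 0)


@dataclass
class SupportResult:
    intron: IntronRecord
    spanning_reads: int
    exon_cov_5: int
    intron_cov_5: int
    exon_cov_3: int
    intron_cov_3: int
    supported: bool
    flag: str = ""


@dataclass
class UsageRecord:
    intron: IntronRecord
    usage_5: float
    usage_3: float
    flag: str = ""

    @property
    def delta(self) -> float:
        return self.usage_5 - self.usage_3


@dataclass
class ExpressionRecord:
    """Per-gene expression with splice-class membership flags.

    A gene carries ``gt_ag_only`` when all of its introns are canonical, and
    independently any of ``has_gc_ag`` / ``has_at_ac`` / ``has_minor`` — a
    gene with several non-canonical combinations belongs to several groups.
    """

    gene_id: str
    read_count: int
    transcript_length: int
    fpkm: float
    gt_ag_only: bool = False
    has_gc_ag: bool = False
    has_at_ac: bool = False
    has_minor: bool = False


def load_coverage(
    path,
    genome: GenomeSequence,
    junctions_path=None,
) -> CoverageTrack:
    """Load per-base depth and junction counts.

    ``path`` is either a coordinate-sorted indexed BAM, or a 4-column
    interval-depth TSV (chrom, start, end, depth; 0-based half-open) taken as
    already filtered.  For TSV input, ``junctions_path`` points to a junction
    TSV (chrom, start, end, reads).  BAM alignments must show >=95% identity
    over >=90% of the read length; multi-mapped reads are excluded.
    """
    path = Path(path)
    if path.suffix == ".bam":
        return _load_bam(path, genome)
    depth = {c: np.zeros(genome.length(c), dtype=np.int64) for c in genome.sequences}
    cov = pd.read_csv(path, sep="\t", header=None, names=["chrom", "start", "end", "depth"],
                      comment="#")
    bad = set(cov["chrom"]) - set(depth)
    if bad:
        raise ValueError(f"coverage references unknown chromosomes: {sorted(bad)}")
    for chrom, start, end, d in cov.itertuples(index=False):
        depth[chrom][start:end] += int(d)
    junction_reads: dict[tuple[str, int, int], int] = {}
    if junctions_path is not None:
        jc = pd.read_csv(junctions_path, sep="\t", header=None,
                         names=["chrom", "start", "end", "reads"], comment="#")
        bad = set(jc["chrom"]) - set(depth)
        if bad:
            raise ValueError(f"junction table references unknown chromosomes: {sorted(bad)}")
        for chrom, start, end, n in jc.itertuples(index=False):
            junction_reads[(chrom, int(start), int(end))] = int(n)
    return CoverageTrack(depth=depth, junction_reads=junction_reads)


def _load_bam(path: Path, genome: GenomeSequence,
              min_identity: float = 0.95, min_cover: float = 0.90) -> CoverageTrack:
    import pysam

    depth = {c: np.zeros(genome.length(c), dtype=np.int64) for c in genome.sequences}
    junction_reads: dict[tuple[str, int, int], int] = {}
    with pysam.AlignmentFile(str(path), "rb") as bam:
        bad = set(bam.references) - set(depth)
        if bad:
            raise ValueError(f"BAM references unknown chromosomes: {sorted(bad)}")
        for read in bam.fetch():
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            if read.has_tag("NH") and read.get_tag("NH") > 1:
                continue  # multi-mapped
            qlen = read.query_length or 0
            aligned = read.query_alignment_length or 0
            if qlen and aligned / qlen < min_cover:
                continue
            if read.has_tag("NM") and aligned:
                if 1 - read.get_tag("NM") / aligned < min_identity:
                    continue
            chrom = read.reference_name
            for block_start, block_end in read.get_blocks():
                depth[chrom][block_start:block_end] += 1
            # N operations in the CIGAR are spliced-out junctions
            pos = read.reference_start
            for op, length in read.cigartuples or []:
                if op == 3:  # N
                    key = (chrom, pos, pos + length)
                    junction_reads[key] = junction_reads.get(key, 0) + 1
                if op in (0, 2, 3, 7, 8):  # consume reference
                    pos += length
    return CoverageTrack(depth=depth, junction_reads=junction_reads)


def _border_positions(i: IntronRecord) -> tuple[int, int, int, int]:
    """(exon5, intron5, intron3, exon3) genomic positions for an intron,
    respecting transcript orientation."""
    if i.strand == "+":
        return i.start - 1, i.start, i.end - 1, i.end
    return i.end, i.end - 1, i.start, i.start - 1


def validate_splice_site(
    i: IntronRecord,
    c: CoverageTrack,
    min_reads: int = 3,
    drop: float = 0.2,
) -> SupportResult:
    """Apply the >=3 spanning reads + >=20% coverage-drop rule.

    The drop comparison is inclusive: an intron base at exactly
    ``(1 - drop) * exon`` depth passes.  A border with zero exonic coverage
    cannot be evaluated and renders the site unsupported (flag "no-coverage").
    """
    exon5_pos, intron5_pos, intron3_pos, exon3_pos = _border_positions(i)
    exon5 = c.depth_at(i.chrom, exon5_pos)
    intron5 = c.depth_at(i.chrom, intron5_pos)
    exon3 = c.depth_at(i.chrom, exon3_pos)
    intron3 = c.depth_at(i.chrom, intron3_pos)
    spanning = c.junctions_spanning(i.chrom, i.start, i.end)
    flag = ""
    if exon5 == 0 or exon3 == 0:
        supported = False
        flag = "no-coverage"
    else:
        drop5 = intron5 <= (1 - drop) * exon5
        drop3 = intron3 <= (1 - drop) * exon3
        supported = spanning >= min_reads and drop5 and drop3
    return SupportResult(
        intron=i,
        spanning_reads=spanning,
        exon_cov_5=exon5,
        intron_cov_5=intron5,
        exon_cov_3=exon3,
        intron_cov_3=intron3,
        supported=supported,
        flag=flag,
    )


def splice_usage(i: IntronRecord, c: CoverageTrack) -> UsageRecord:
    """Per-border usage = relative coverage drop, clamped to [0, 1].

    usage 1 means every local transcript is spliced at that border; 0 means
    the intron is fully retained (or the border has no exonic coverage, in
    which case the record is flagged).
    """
    exon5_pos, intron5_pos, intron3_pos, exon3_pos = _border_positions(i)
    flag = ""

    def _usage(exon_pos: int, intron_pos: int) -> float:
        nonlocal flag
        exon = c.depth_at(i.chrom, exon_pos)
        intron = c.depth_at(i.chrom, intron_pos)
        if exon == 0:
            flag = "no-coverage"
            return 0.0
        return max(0.0, 1.0 - intron / exon)

    return UsageRecord(
        intron=i,
        usage_5=_usage(exon5_pos, intron5_pos),
        usage_3=_usage(exon3_pos, intron3_pos),
        flag=flag,
    )


def fpkm(read_count: int, transcript_length: int, total_assigned: int) -> float:
    """Fragments per kilobase of transcript per million assigned fragments."""
    if transcript_length <= 0:
        raise ValueError("transcript_length must be positive")
    if total_assigned <= 0:
        raise ValueError("total_assigned must be positive")
    return read_count / ((transcript_length / 1000) * (total_assigned / 1e6))


CLASS_COLUMNS = ("gt_ag_only", "has_gc_ag", "has_at_ac", "has_minor")


def build_expression_records(
    counts: dict[str, int],
    transcript_lengths: dict[str, int],
    intron_classes: dict[str, set[str]],
) -> list[ExpressionRecord]:
    """Join a count table with per-gene splice-class membership.

    ``intron_classes`` maps gene id to the set of combination class labels of
    its introns ("canonical" / "major:GC-AG" / "major:AT-AC" / "minor").
    """
    total = sum(counts.values())
    records = []
    for gene_id, n in counts.items():
        if gene_id not in transcript_lengths:
            logger.warning("gene %s in count table has no transcript length; skipped", gene_id)
            continue
        length = transcript_lengths[gene_id]
        classes = intron_classes.get(gene_id, set())
        records.append(
            ExpressionRecord(
                gene_id=gene_id,
                read_count=n,
                transcript_length=length,
                fpkm=fpkm(n, length, total) if total else 0.0,
                gt_ag_only=bool(classes) and classes <= {"canonical"},
                has_gc_ag="major:GC-AG" in classes,
                has_at_ac="major:AT-AC" in classes,
                has_minor="minor" in classes,
            )
        )
    return records


def expression_bins(
    records: Sequence[ExpressionRecord],
    bin_edges: Sequence[float] | None = None,
    outlier_quantile: float = 0.99,
) -> pd.DataFrame:
    """Cumulative relative FPKM bin sizes per gene class.

    Genes above the ``outlier_quantile`` of FPKM are excluded.  Returns one
    row per bin with per-class relative size and cumulative sum columns;
    classes without genes are omitted with a warning.
    """
    fpkms = np.array([r.fpkm for r in records], dtype=float)
    if len(fpkms) == 0:
        raise ValueError("no expression records")
    cutoff = np.quantile(fpkms, outlier_quantile)
    kept = [r for r in records if r.fpkm <= cutoff]
    if bin_edges is None:
        top = max(r.fpkm for r in kept) if kept else 1.0
        bin_edges = np.linspace(0, top, 11)
    bin_edges = np.asarray(bin_edges, dtype=float)
    out = {}
    for cls in CLASS_COLUMNS:
        members = [r.fpkm for r in kept if getattr(r, cls)]
        if not members:
            logger.warning("expression class %s empty; omitted from binning", cls)
            continue
        hist, _ = np.histogram(members, bins=bin_edges)
        rel = hist / hist.sum()
        out[f"{cls}_rel"] = rel
        out[f"{cls}_cum"] = np.cumsum(rel)
    frame = pd.DataFrame(out)
    frame.insert(0, "bin_low", bin_edges[:-1])
    frame.insert(1, "bin_high", bin_edges[1:])
    return frame


def isoform_presence(i: IntronRecord, c: CoverageTrack, e: ExpressionRecord) -> float:
    """Local minus global coverage: how much of a gene's expression carries
    this intron's splice site.

    Local expression is the mean depth at the two exonic bases flanking the
    intron; global is estimated as 200 bp (2 x 100 nt reads) times the gene's
    read count, normalised to transcript length.  Values near zero mean the
    intron's borders are in the dominant isoform; strongly negative values
    indicate a minor isoform.
    """
    if e.gene_id != i.gene_id:
        raise ValueError(f"gene mismatch: intron {i.gene_id} vs record {e.gene_id}")
    exon5_pos, _, _, exon3_pos = _border_positions(i)
    local = (c.depth_at(i.chrom, exon5_pos) + c.depth_at(i.chrom, exon3_pos)) / 2
    global_cov = 200 * e.read_count / e.transcript_length
    return local - global_cov


def support_table(results: Iterable[SupportResult]) -> pd.DataFrame:
    rows = [
        {
            "transcript_id": r.intron.transcript_id,
            "intron_index": r.intron.index,
            "chrom": r.intron.chrom,
            "start": r.intron.start,
            "end": r.intron.end,
            "combination": r.intron.combination,
            "spanning_reads": r.spanning_reads,
            "exon_cov_5": r.exon_cov_5,
            "intron_cov_5": r.intron_cov_5,
            "exon_cov_3": r.exon_cov_3,
            "intron_cov_3": r.intron_cov_3,
            "supported": r.supported,
            "flag": r.flag,
        }
        for r in results
    ]
    return pd.DataFrame(rows)


def usage_table(records: Iterable[UsageRecord]) -> pd.DataFrame:
    rows = [
        {
            "transcript_id": u.intron.transcript_id,
            "intron_index": u.intron.index,
            "combination": u.intron.combination,
            "usage_5": u.usage_5,
            "usage_3": u.usage_3,
            "delta": u.delta,
            "flag": u.flag,
        }
        for u in records
    ]
    return pd.DataFrame(rows)


def read_count_table(path) -> dict[str, int]:
    """Read a featureCounts-style two-column (gene-id, count) table."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None, names=["gene_id", "count"])
    return dict(zip(df["gene_id"], df["count"].astype(int)))
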