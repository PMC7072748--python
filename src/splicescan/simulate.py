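"""Synthetic species with known splice-site ground truth.

Generates multi-gene genomes (FASTA + GFF3) with controlled splice-site
combination mixtures, GC content and intron-length distributions, plus the
matching RNA-Seq evidence (interval-depth and junction tables), per-gene read
counts, and variant sets — everything the analysis consumes, with a
TruthManifest recording what was planted.

Kingdom presets mirror the broad genome properties reported for fungi
(~1.49 introns per gene, GC ~47%) and animals (~6.95 introns per gene,
GC ~39.4%).  An "antisense artifact" gene is a gene whose transcript is
spliced at canonical GT-AG sites but annotated on the wrong strand, so the
annotated-strand extraction sees CT-AC.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .annotation import (
    GenomeSequence,
    classify_combination,
    reverse_complement,
    reverse_complement_combination,
)

_BASES = np.array(list("ACGT"))
_VALID_COMBOS = {
    f"{d1}{d2}-{a1}{a2}"
    for d1 in "ACGT" for d2 in "ACGT" for a1 in "ACGT" for a2 in "ACGT"
}


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic species.

    ``mean_introns_per_gene`` feeds a Poisson draw (exon count = 1 + draw);
    intron lengths are ``min_intron_length - 1 + Geometric`` with the stated
    mean; the combination ``mixture`` must sum to 1 over valid dinucleotide
    pairs.  ``antisense_fraction`` genes are generated with canonical GT-AG
    introns but annotated on the opposite strand.
    """

    seed: int = 0
    n_genes: int = 100
    mean_introns_per_gene: float = 3.0
    mean_intron_length: float = 150.0
    min_intron_length: int = 20
    exon_length_range: tuple[int, int] = (60, 240)
    mixture: dict[str, float] = field(
        default_factory=lambda: {"GT-AG": 1.0}
    )
    gc_content: float = 0.42
    coverage_depth: float = 50.0
    coverage_noise: float = 0.0  # 0 = deterministic depth; else Poisson
    retained_fraction: float = 0.0
    antisense_fraction: float = 0.0
    minor_isoform_fraction: float = 0.0
    minor_isoform_weight: float = 0.2
    variant_rate_splice: float = 0.0
    variant_rate_background: float = 0.0
    fpkm_effect: dict[str, float] = field(default_factory=dict)
    exonic_context_5: str = ""  # planted at the 3' end of each upstream exon
    exonic_context_3: str = ""  # planted at the 5' start of each downstream exon
    genes_per_chromosome: int = 100
    species_id: str = "synthetic"

    def validate(self) -> None:
        total = sum(self.mixture.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"mixture must sum to 1, got {total}")
        bad = set(self.mixture) - _VALID_COMBOS
        if bad:
            raise ValueError(f"mixture contains invalid combinations: {sorted(bad)}")
        for name in ("retained_fraction", "antisense_fraction",
                     "minor_isoform_fraction", "gc_content",
                     "variant_rate_splice", "variant_rate_background"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.mean_intron_length < self.min_intron_length:
            raise ValueError("mean intron length below the minimum length")

    @classmethod
    def fungi_like(cls, **overrides) -> "SyntheticSpec":
        """Short-intron, GC-rich preset (~1.49 introns/gene, GC 47%)."""
        defaults = dict(mean_introns_per_gene=1.49, gc_content=0.471,
                        mean_intron_length=90.0, species_id="fungi_like")
        defaults.update(overrides)
        return cls(**defaults)

    @classmethod
    def animal_like(cls, **overrides) -> "SyntheticSpec":
        """Intron-rich preset (~6.95 introns/gene, GC 39.4%)."""
        defaults = dict(mean_introns_per_gene=6.95, gc_content=0.394,
                        mean_intron_length=200.0, species_id="animal_like")
        defaults.update(overrides)
        return cls(**defaults)

    @classmethod
    def from_config(cls, path) -> "SyntheticSpec":
        """Load from a JSON key-value config file (keys = field names)."""
        with open(path) as fh:
            data = json.load(fh)
        if "exon_length_range" in data:
            data["exon_length_range"] = tuple(data["exon_length_range"])
        spec = cls(**data)
        spec.validate()
        return spec


@dataclass
class IntronTruth:
    index: int  # 1-based, annotated transcript orientation
    start: int  # genomic 0-based half-open
    end: int
    true_combination: str
    annotated_combination: str
    retained: bool = False
    in_minor_isoform: bool = False


@dataclass
class GeneTruth:
    gene_id: str
    transcript_id: str
    chrom: str
    true_strand: str
    annotated_strand: str
    antisense: bool
    exons: list[tuple[int, int]]
    introns: list[IntronTruth]
    expression: float  # relative expression multiplier (mean ~1)
    transcript_length: int
    read_count: int = 0

    @property
    def expression_class_flags(self) -> set[str]:
        flags = set()
        combos = {i.true_combination for i in self.introns}
        if combos and all(c == "GT-AG" for c in combos):
            flags.add("gt_ag_only")
        if "GC-AG" in combos:
            flags.add("gc_ag")
        if "AT-AC" in combos:
            flags.add("at_ac")
        if any(classify_combination(*c.split("-")) == "minor_noncanonical"
               for c in combos):
            flags.add("minor")
        return flags


@dataclass
class TruthManifest:
    species_id: str
    genes: list[GeneTruth]
    chrom_lengths: dict[str, int]
    planted_variants: list[tuple[str, int]] = field(default_factory=list)

    @property
    def introns_by_interval(self) -> dict[tuple[str, int, int], IntronTruth]:
        return {
            (g.chrom, i.start, i.end): i
            for g in self.genes
            for i in g.introns
        }

    @property
    def n_introns(self) -> int:
        return sum(len(g.introns) for g in self.genes)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)

    @classmethod
    def load(cls, path) -> "TruthManifest":
        with open(path) as fh:
            data = json.load(fh)
        genes = []
        for g in data["genes"]:
            g["exons"] = [tuple(e) for e in g["exons"]]
            g["introns"] = [IntronTruth(**i) for i in g["introns"]]
            genes.append(GeneTruth(**g))
        return cls(
            species_id=data["species_id"],
            genes=genes,
            chrom_lengths=data["chrom_lengths"],
            planted_variants=[tuple(v) for v in data["planted_variants"]],
        )


@dataclass
class SpeciesFiles:
    fasta: Path
    gff3: Path
    manifest: TruthManifest


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    if length <= 0:
        return ""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(_BASES[rng.choice(4, size=length, p=p)])


def _sample_intron_length(rng: np.random.Generator, spec: SyntheticSpec) -> int:
    extra_mean = spec.mean_intron_length - spec.min_intron_length + 1
    return spec.min_intron_length - 1 + rng.geometric(1.0 / extra_mean)


def generate_species(spec: SyntheticSpec, outdir) -> SpeciesFiles:
    """Write FASTA + GFF3 for a synthetic species; return the ground truth.

    Deterministic under a fixed seed (byte-identical outputs).  Every intron
    border carries exactly the sampled combination; exonic GC tracks the
    configured target.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    mixture_combos = sorted(spec.mixture)
    mixture_probs = np.array([spec.mixture[c] for c in mixture_combos])

    chroms: dict[str, list[str]] = {}
    chrom_cursor: dict[str, int] = {}
    genes: list[GeneTruth] = []
    gff_lines: list[str] = []

    for gi in range(spec.n_genes):
        chrom = f"chr{gi // spec.genes_per_chromosome + 1}"
        parts = chroms.setdefault(chrom, [])
        if chrom not in chrom_cursor:
            chrom_cursor[chrom] = 0
        # intergenic spacer
        spacer = int(rng.integers(100, 300))
        parts.append(_random_seq(rng, spacer, spec.gc_content))
        chrom_cursor[chrom] += spacer
        gene_start = chrom_cursor[chrom]

        true_strand = "+" if rng.random() < 0.5 else "-"
        antisense = rng.random() < spec.antisense_fraction
        annotated_strand = (
            ("-" if true_strand == "+" else "+") if antisense else true_strand
        )
        n_introns = int(rng.poisson(spec.mean_introns_per_gene))
        n_exons = n_introns + 1
        exon_lengths = [
            int(rng.integers(*spec.exon_length_range)) for _ in range(n_exons)
        ]
        # keep the CDS a whole number of codons
        pad = (3 - sum(exon_lengths) % 3) % 3
        exon_lengths[-1] += pad

        # intron combinations in TRUE transcript orientation
        combos = []
        for _ in range(n_introns):
            if antisense:
                combos.append("GT-AG")
            else:
                combos.append(mixture_combos[rng.choice(len(mixture_probs),
                                                        p=mixture_probs)])
        intron_seqs = []
        for combo, _ in zip(combos, range(n_introns)):
            donor, acceptor = combo.split("-")
            ilen = _sample_intron_length(rng, spec)
            interior = _random_seq(rng, ilen - 4, spec.gc_content)
            intron_seqs.append(donor + interior + acceptor)

        exon_seqs = [_random_seq(rng, ln, spec.gc_content) for ln in exon_lengths]
        # planted exonic context around the borders (transcript orientation)
        if spec.exonic_context_5:
            ctx = spec.exonic_context_5
            exon_seqs = [
                (s[:-len(ctx)] + ctx if k < n_exons - 1 else s)
                for k, s in enumerate(exon_seqs)
            ]
        if spec.exonic_context_3:
            ctx = spec.exonic_context_3
            exon_seqs = [
                (ctx + s[len(ctx):] if k > 0 else s)
                for k, s in enumerate(exon_seqs)
            ]

        # assemble in transcript orientation, then place on the genome
        segments = []
        for k in range(n_exons):
            segments.append(("exon", exon_seqs[k]))
            if k < n_introns:
                segments.append(("intron", intron_seqs[k]))
        gene_seq_tx = "".join(s for _, s in segments)
        gene_len = len(gene_seq_tx)
        if true_strand == "+":
            genomic_seq = gene_seq_tx
        else:
            genomic_seq = reverse_complement(gene_seq_tx)

        # genomic intervals of each segment
        exon_intervals, intron_records = [], []
        cursor = 0
        tx_intervals = []
        for kind, s in segments:
            tx_intervals.append((kind, cursor, cursor + len(s)))
            cursor += len(s)
        for kind, ts, te in tx_intervals:
            if true_strand == "+":
                gs, ge = gene_start + ts, gene_start + te
            else:
                gs, ge = gene_start + gene_len - te, gene_start + gene_len - ts
            if kind == "exon":
                exon_intervals.append((gs, ge))
            else:
                intron_records.append((gs, ge))
        exon_intervals.sort()
        intron_records.sort()

        # map genomic intron intervals back to true-orientation combinations
        if true_strand == "+":
            ordered_combos = combos
        else:
            ordered_combos = combos[::-1]  # genomic order

        introns = []
        for genomic_idx, ((gs, ge), combo) in enumerate(
            zip(intron_records, ordered_combos)
        ):
            if annotated_strand == "+":
                ann_index = genomic_idx + 1
            else:
                ann_index = len(intron_records) - genomic_idx
            if annotated_strand == true_strand:
                ann_combo = combo
            else:
                ann_combo = reverse_complement_combination(combo)
            retained = rng.random() < spec.retained_fraction
            minor = (not retained) and rng.random() < spec.minor_isoform_fraction
            introns.append(
                IntronTruth(
                    index=ann_index,
                    start=gs,
                    end=ge,
                    true_combination=combo,
                    annotated_combination=ann_combo,
                    retained=retained,
                    in_minor_isoform=minor,
                )
            )
        introns.sort(key=lambda i: i.start)

        parts.append(genomic_seq)
        chrom_cursor[chrom] += gene_len

        gene_id = f"gene{gi + 1}"
        tx_id = f"mRNA{gi + 1}"
        expression = float(rng.lognormal(mean=0.0, sigma=0.5))
        flags = set()
        transcript_length = sum(e - s for s, e in exon_intervals)
        gene = GeneTruth(
            gene_id=gene_id,
            transcript_id=tx_id,
            chrom=chrom,
            true_strand=true_strand,
            annotated_strand=annotated_strand,
            antisense=antisense,
            exons=exon_intervals,
            introns=introns,
            expression=expression,
            transcript_length=transcript_length,
        )
        for flag in gene.expression_class_flags:
            if flag in spec.fpkm_effect:
                gene.expression *= spec.fpkm_effect[flag]
        gene.read_count = int(round(
            spec.coverage_depth * gene.expression * transcript_length / 200
        ))
        genes.append(gene)

        gene_end = gene_start + gene_len
        gff_lines.append(
            f"{chrom}\tsplicescan_sim\tgene\t{gene_start + 1}\t{gene_end}\t.\t"
            f"{annotated_strand}\t.\tID={gene_id}"
        )
        gff_lines.append(
            f"{chrom}\tsplicescan_sim\tmRNA\t{gene_start + 1}\t{gene_end}\t.\t"
            f"{annotated_strand}\t.\tID={tx_id};Parent={gene_id}"
        )
        phase_cursor = 0
        cds_order = exon_intervals if annotated_strand == "+" else exon_intervals[::-1]
        phases = []
        for s, e in cds_order:
            phases.append((3 - phase_cursor % 3) % 3)
            phase_cursor += e - s
        phase_by_interval = dict(zip(cds_order, phases))
        for k, (s, e) in enumerate(exon_intervals, start=1):
            gff_lines.append(
                f"{chrom}\tsplicescan_sim\texon\t{s + 1}\t{e}\t.\t"
                f"{annotated_strand}\t.\tID={tx_id}.exon{k};Parent={tx_id}"
            )
            gff_lines.append(
                f"{chrom}\tsplicescan_sim\tCDS\t{s + 1}\t{e}\t.\t"
                f"{annotated_strand}\t{phase_by_interval[(s, e)]}\t"
                f"ID={tx_id}.cds{k};Parent={tx_id}"
            )

    # trailing spacer so windows near the last gene are not truncated
    for chrom in chroms:
        tail = _random_seq(rng, 200, spec.gc_content)
        chroms[chrom].append(tail)
        chrom_cursor[chrom] += len(tail)

    fasta_path = outdir / f"{spec.species_id}.fasta"
    with open(fasta_path, "w") as fh:
        for chrom in sorted(chroms):
            fh.write(f">{chrom}\n")
            seq = "".join(chroms[chrom])
            for k in range(0, len(seq), 60):
                fh.write(seq[k:k + 60] + "\n")

    gff_path = outdir / f"{spec.species_id}.gff3"
    with open(gff_path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write("\n".join(gff_lines) + "\n")

    manifest = TruthManifest(
        species_id=spec.species_id,
        genes=genes,
        chrom_lengths={c: chrom_cursor[c] for c in sorted(chroms)},
    )
    return SpeciesFiles(fasta=fasta_path, gff3=gff_path, manifest=manifest)


def _round_or_poisson(rng: np.random.Generator, expected: float, noise: float) -> int:
    if expected <= 0:
        return 0
    return int(rng.poisson(expected)) if noise > 0 else int(round(expected))


def simulate_coverage(
    truth: TruthManifest,
    depth: float,
    noise: float,
    coverage_path,
    junctions_path,
    seed: int = 0,
    minor_weight: float = 0.2,
) -> None:
    """Emit interval-depth and junction TSVs matching the planted truth.

    Exonic segments of a gene get ``depth * expression`` (Poisson-sampled per
    segment when ``noise > 0``); spliced introns drop to zero; retained
    introns keep exonic depth; a minor-isoform intron's two flanking exonic
    bases and junction reads are scaled by the minor-isoform weight.
    """
    rng = np.random.default_rng(seed)
    cov_rows: list[tuple[str, int, int, int]] = []
    junc_rows: list[tuple[str, int, int, int]] = []
    for gene in truth.genes:
        gene_depth = depth * gene.expression
        span_start = gene.exons[0][0]
        span_end = gene.exons[-1][1]
        expected = np.zeros(span_end - span_start, dtype=float)
        for s, e in gene.exons:
            expected[s - span_start:e - span_start] = gene_depth
        for intron in gene.introns:
            weight = 1.0 if intron.retained else 0.0
            expected[intron.start - span_start:intron.end - span_start] = (
                gene_depth * weight
            )
            if not intron.retained:
                minor = intron.in_minor_isoform
                w = minor_weight if minor else 1.0
                junc_rows.append(
                    (gene.chrom, intron.start, intron.end,
                     _round_or_poisson(rng, gene_depth * w, noise))
                )
                if minor:
                    # flanking exonic bases carried only by the minor isoform
                    for pos in (intron.start - 1, intron.end):
                        if span_start <= pos < span_end:
                            expected[pos - span_start] = gene_depth * w
        if noise > 0:
            observed = rng.poisson(expected).astype(np.int64)
        else:
            observed = np.round(expected).astype(np.int64)
        # run-length encode into interval rows
        change = np.flatnonzero(np.diff(observed)) + 1
        starts = np.concatenate(([0], change))
        ends = np.concatenate((change, [len(observed)]))
        for s, e in zip(starts, ends):
            d = int(observed[s])
            if d > 0:
                cov_rows.append((gene.chrom, span_start + int(s),
                                 span_start + int(e), d))

    with open(coverage_path, "w") as fh:
        for chrom, s, e, d in cov_rows:
            fh.write(f"{chrom}\t{s}\t{e}\t{d}\n")
    with open(junctions_path, "w") as fh:
        for chrom, s, e, n in junc_rows:
            fh.write(f"{chrom}\t{s}\t{e}\t{n}\n")


def write_counts(truth: TruthManifest, path) -> None:
    """Per-gene read-count table (featureCounts-style: gene-id, count)."""
    with open(path, "w") as fh:
        for gene in truth.genes:
            fh.write(f"{gene.gene_id}\t{gene.read_count}\n")


def simulate_variants(
    truth: TruthManifest,
    genome: GenomeSequence,
    rate_splice: float,
    rate_background: float,
    path,
    seed: int = 0,
) -> list[tuple[str, int]]:
    """Plant variants by independent Bernoulli draws per base; write a VCF.

    Splice-border bases (the four border bases of every intron) are hit at
    ``rate_splice``; internal exonic bases at ``rate_background``.  Returns
    the planted positions (also recorded on the manifest).
    """
    rng = np.random.default_rng(seed)
    border: set[tuple[str, int]] = set()
    background: set[tuple[str, int]] = set()
    for gene in truth.genes:
        for intron in gene.introns:
            border.update(
                (gene.chrom, p)
                for p in (intron.start, intron.start + 1,
                          intron.end - 2, intron.end - 1)
            )
        if len(gene.exons) > 2:
            for s, e in gene.exons[1:-1]:
                background.update((gene.chrom, p) for p in range(s, e))
    background -= border

    planted: list[tuple[str, int]] = []
    for positions, rate in ((sorted(border), rate_splice),
                            (sorted(background), rate_background)):
        if rate <= 0 or not positions:
            continue
        hits = rng.random(len(positions)) < rate
        planted.extend(pos for pos, hit in zip(positions, hits) if hit)
    planted.sort()

    alt_of = {"A": "G", "C": "T", "G": "A", "T": "C", "N": "A"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in sorted(truth.chrom_lengths):
            fh.write(f"##contig=<ID={chrom},length={truth.chrom_lengths[chrom]}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for chrom, pos in planted:
            ref = genome[chrom][pos]
            fh.write(f"{chrom}\t{pos + 1}\t.\t{ref}\t{alt_of[ref]}\t50\tPASS\t.\n")
    truth.planted_variants = planted
    return planted


def flip_species(genome: GenomeSequence, transcripts) -> tuple[GenomeSequence, list]:
    """Reverse complement every chromosome and mirror the annotation.

    Intervals map to (L - end, L - start) and strands flip; splice-site
    extraction must be invariant under this transformation.
    """
    from .annotation import TranscriptModel

    flipped_genome = GenomeSequence(
        {c: reverse_complement(s) for c, s in genome.sequences.items()}
    )
    flipped = []
    for t in transcripts:
        L = genome.length(t.chrom)
        flipped.append(
            TranscriptModel(
                transcript_id=t.transcript_id,
                gene_id=t.gene_id,
                chrom=t.chrom,
                strand="-" if t.strand == "+" else "+",
                exons=sorted((L - e, L - s) for s, e in t.exons),
                cds=sorted((L - e, L - s) for s, e in t.cds),
            )
        )
    return flipped_genome, flipped


def generate_homolog_family(
    n_homologs: int,
    n_introns: int,
    query_position: int,
    query_combination: str = "AT-AC",
    conservation: float = 0.6,
    other_nc_prob: float = 0.0,
    seed: int = 0,
):
    """Synthetic ortholog family for conservation recovery tests.

    The query transcript carries ``query_combination`` at ``query_position``
    (0-based) and GT-AG elsewhere; each homolog keeps the same intron
    structure and, at the query position, shows the identical combination
    with probability ``conservation``, a different non-canonical combination
    with ``other_nc_prob``, and canonical GT-AG otherwise.

    Returns (query, homologs, truth) where truth maps homolog index to the
    planted category ("same" / "other_nc" / "canonical").
    """
    from .conservation import CombinationString, build_codebook

    rng = np.random.default_rng(seed)
    other_nc = "GC-AG" if query_combination != "GC-AG" else "CT-AC"
    codebook = build_codebook(
        {"GT-AG": 1000, query_combination: 100, other_nc: 10}
    )

    def _string(tid: str, combos: Sequence[str], species: str) -> CombinationString:
        return CombinationString(
            transcript_id=tid,
            species_id=species,
            symbols="".join(codebook[c] for c in combos),
            codebook=codebook,
        )

    query_combos = ["GT-AG"] * n_introns
    query_combos[query_position] = query_combination
    query = _string("query", query_combos, "query_species")

    homologs, truth = [], {}
    for h in range(n_homologs):
        combos = ["GT-AG"] * n_introns
        u = rng.random()
        if u < conservation:
            combos[query_position] = query_combination
            truth[h] = "same"
        elif u < conservation + other_nc_prob:
            combos[query_position] = other_nc
            truth[h] = "other_nc"
        else:
            truth[h] = "canonical"
        homologs.append(_string(f"homolog{h}", combos, f"species{h}"))
    return query, homologs, truth
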