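"""Genome/annotation parsing and splice-site dinucleotide extraction.

An intron's border dinucleotides — the donor (5') and acceptor (3') sites —
are read in transcript orientation, so a minus-strand intron is reverse
complemented before its first and last two bases are taken.  GT-AG is the
canonical combination processed by the major U2 spliceosome; GC-AG and AT-AC
are the two major non-canonical combinations; the remaining 253 dinucleotide
pairs are minor non-canonical.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

CANONICAL = "GT-AG"
MAJOR_NONCANONICAL = frozenset({"GC-AG", "AT-AC"})

#: class labels
CLASS_CANONICAL = "canonical"
CLASS_MAJOR = "major_noncanonical"
CLASS_MINOR = "minor_noncanonical"
CLASS_AMBIGUOUS = "ambiguous"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

BASES = "ACGT"


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class GenomeSequence:
    """Uppercase chromosome sequences over the {A,C,G,T,N} alphabet."""

    sequences: dict[str, str]

    def __getitem__(self, chrom: str) -> str:
        return self.sequences[chrom]

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sequences

    def length(self, chrom: str) -> int:
        return len(self.sequences[chrom])

    def gc_content(self) -> float:
        """Genome-wide GC fraction, N bases excluded from the denominator."""
        gc = acgt = 0
        for seq in self.sequences.values():
            gc += seq.count("G") + seq.count("C")
            acgt += len(seq) - seq.count("N")
        return gc / acgt if acgt else float("nan")


@dataclass
class TranscriptModel:
    """One gene's representative transcript: ordered exons/CDS on one strand.

    Intervals are 0-based half-open genomic coordinates, exons sorted by
    genomic start regardless of strand.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    cds: list[tuple[int, int]] = field(default_factory=list)

    @property
    def exonic_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds)

    @property
    def n_introns(self) -> int:
        return max(0, len(self.exons) - 1)


@dataclass
class IntronRecord:
    """One intron with donor/acceptor dinucleotides in transcript orientation."""

    transcript_id: str
    gene_id: str
    index: int  # 1-based in transcript orientation
    chrom: str
    start: int  # genomic, 0-based half-open
    end: int
    strand: str
    donor: str
    acceptor: str
    sequence: str  # transcript orientation

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def combination(self) -> str:
        return f"{self.donor}-{self.acceptor}"

    @property
    def ambiguous(self) -> bool:
        return "N" in self.donor or "N" in self.acceptor


@dataclass
class CombinationTable:
    """Per-species counts and frequencies of donor-acceptor combinations."""

    species_id: str
    counts: dict[str, int]
    total: int
    frequencies: dict[str, float]
    classes: dict[str, str]
    n_ambiguous: int = 0

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "combination": combo,
                "count": self.counts[combo],
                "frequency": self.frequencies.get(combo, float("nan")),
                "class": self.classes[combo],
            }
            for combo in sorted(self.counts, key=lambda c: (-self.counts[c], c))
        ]
        return pd.DataFrame(rows, columns=["combination", "count", "frequency", "class"])

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass
class FlankProfile:
    """Position frequency matrix around one splice site.

    ``matrix`` holds per-position base counts over ``exonic + intronic``
    positions in transcript orientation; for the 5' site the window runs from
    the last exonic bases into the intron (the donor dinucleotide included),
    for the 3' site from inside the intron (acceptor included) into the
    downstream exon.  ``n_per_column`` tracks per-column denominators, which
    drop below ``n`` where windows were truncated by sequence ends.
    """

    site: str  # "5prime" | "3prime"
    matrix: pd.DataFrame  # index: A/C/G/T/N, columns: positions
    n: int
    n_per_column: np.ndarray

    def consensus(self) -> str:
        return "".join(self.matrix.idxmax(axis=0))

    def write_tsv(self, path) -> None:
        self.matrix.to_csv(path, sep="\t")


def parse_genome(path) -> GenomeSequence:
    """Read a FASTA file; uppercase and map non-ACGTN characters to N."""
    sequences: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in sequences:
            raise ValueError(f"duplicate sequence id in FASTA: {record.id}")
        seq = str(record.seq).upper()
        seq = "".join(b if b in "ACGTN" else "N" for b in seq)
        sequences[record.id] = seq
    if not sequences:
        raise ValueError(f"no sequences found in FASTA file: {path}")
    return GenomeSequence(sequences)


def parse_annotation(path, genome: GenomeSequence) -> list[TranscriptModel]:
    """Read a GFF3 file into transcript models.

    GFF3 1-based inclusive coordinates are converted to 0-based half-open at
    this boundary.  Exons outside chromosome bounds and orphan exons are
    rejected with a logged warning.
    """
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    models: list[TranscriptModel] = []
    for mrna in db.features_of_type("mRNA"):
        parents = list(db.parents(mrna, featuretype="gene"))
        gene_id = parents[0].id if parents else mrna.attributes.get("Parent", [mrna.id])[0]
        if mrna.seqid not in genome:
            logger.warning("mRNA %s on unknown chromosome %s; rejected", mrna.id, mrna.seqid)
            continue
        chrom_len = genome.length(mrna.seqid)
        exons, cds = [], []
        ok = True
        for child in db.children(mrna, featuretype=("exon", "CDS")):
            start, end = child.start - 1, child.end  # to 0-based half-open
            if start < 0 or end > chrom_len:
                logger.warning(
                    "%s of %s outside chromosome bounds (%d-%d > %d); transcript rejected",
                    child.featuretype, mrna.id, start, end, chrom_len,
                )
                ok = False
                break
            (exons if child.featuretype == "exon" else cds).append((start, end))
        if not ok or not exons:
            continue
        exons.sort()
        cds.sort()
        models.append(
            TranscriptModel(
                transcript_id=mrna.id,
                gene_id=gene_id,
                chrom=mrna.seqid,
                strand=mrna.strand,
                exons=exons,
                cds=cds,
            )
        )
    # orphan exons: exons whose Parent is not a known mRNA
    known = {m.transcript_id for m in models}
    for exon in db.features_of_type("exon"):
        for parent_id in exon.attributes.get("Parent", []):
            try:
                db[parent_id]
            except gffutils.FeatureNotFoundError:
                logger.warning("orphan exon with unresolvable Parent=%s; rejected", parent_id)
    return models


def select_representative(transcripts: Sequence[TranscriptModel]) -> TranscriptModel:
    """Pick one transcript per gene: longest CDS, then longest exonic span,
    then lexicographically smallest transcript id."""
    if not transcripts:
        raise ValueError("empty transcript list")
    gene_ids = {t.gene_id for t in transcripts}
    if len(gene_ids) > 1:
        raise ValueError(f"transcripts from multiple genes: {sorted(gene_ids)}")
    return min(
        transcripts,
        key=lambda t: (-t.cds_length, -t.exonic_length, t.transcript_id),
    )


def extract_introns(
    t: TranscriptModel,
    g: GenomeSequence,
    min_length: int = 4,
) -> list[IntronRecord]:
    """Extract intron records between consecutive exons.

    Donor/acceptor are read in transcript orientation: for minus-strand
    transcripts the genomic slice is reverse complemented first, so the donor
    is always the biological 5' dinucleotide.  Introns shorter than
    ``min_length`` (donor and acceptor would overlap) are excluded with a
    logged count.
    """
    chrom_seq = g[t.chrom]
    gaps = [
        (t.exons[i][1], t.exons[i + 1][0])
        for i in range(len(t.exons) - 1)
    ]
    if t.strand == "-":
        gaps = gaps[::-1]  # transcript order: 5'-most intron first
    records = []
    n_short = 0
    for idx, (start, end) in enumerate(gaps, start=1):
        if end - start < min_length:
            n_short += 1
            continue
        seq = chrom_seq[start:end]
        if t.strand == "-":
            seq = reverse_complement(seq)
        records.append(
            IntronRecord(
                transcript_id=t.transcript_id,
                gene_id=t.gene_id,
                index=idx,
                chrom=t.chrom,
                start=start,
                end=end,
                strand=t.strand,
                donor=seq[:2],
                acceptor=seq[-2:],
                sequence=seq,
            )
        )
    if n_short:
        logger.warning(
            "%s: %d annotated gap(s) shorter than %d bases excluded",
            t.transcript_id, n_short, min_length,
        )
    return records


def classify_combination(donor: str, acceptor: str) -> str:
    """GT-AG -> canonical; GC-AG / AT-AC -> major non-canonical; anything
    else -> minor non-canonical; any N -> ambiguous."""
    combo = f"{donor}-{acceptor}"
    if "N" in combo:
        return CLASS_AMBIGUOUS
    if combo == CANONICAL:
        return CLASS_CANONICAL
    if combo in MAJOR_NONCANONICAL:
        return CLASS_MAJOR
    return CLASS_MINOR


def reverse_complement_combination(combo: str) -> str:
    """Map a combination to its appearance on the complementary strand.

    CT-AC maps to GT-AG: an antisense transcript spliced at a canonical site
    shows CT-AC on the annotated strand.  The map is an involution.
    """
    donor, acceptor = combo.split("-")
    return f"{reverse_complement(acceptor)}-{reverse_complement(donor)}"


def combination_table(
    introns: Iterable[IntronRecord],
    species_id: str = "species",
) -> CombinationTable:
    """Count and normalize donor-acceptor combinations.

    Records with an N in a border dinucleotide are excluded from the total so
    ambiguity cannot create phantom minor combinations.
    """
    counts: Counter[str] = Counter()
    n_ambiguous = 0
    for intron in introns:
        if intron.ambiguous:
            n_ambiguous += 1
            continue
        counts[intron.combination] += 1
    total = sum(counts.values())
    if total == 0:
        logger.warning("combination table for %s is empty; frequencies undefined", species_id)
    frequencies = {c: n / total for c, n in counts.items()} if total else {}
    classes = {c: classify_combination(*c.split("-")) for c in counts}
    return CombinationTable(
        species_id=species_id,
        counts=dict(counts),
        total=total,
        frequencies=frequencies,
        classes=classes,
        n_ambiguous=n_ambiguous,
    )


def combination_gc(combo: str) -> float:
    """GC fraction over the four border bases (AT-AC -> 0.25)."""
    bases = combo.replace("-", "")
    return (bases.count("G") + bases.count("C")) / 4


def weighted_splice_gc(table: CombinationTable) -> float:
    """GC content of the splice-site spectrum, weighted by occurrence."""
    if table.total == 0:
        logger.warning("weighted splice GC undefined for empty table %s", table.species_id)
        return float("nan")
    return sum(n * combination_gc(c) for c, n in table.counts.items()) / table.total


def flank_profile(
    introns: Sequence[IntronRecord],
    g: GenomeSequence,
    site: str,
    exonic: int = 7,
    intronic: int = 7,
) -> FlankProfile:
    """Per-position base counts around the 5' or 3' splice site.

    The window spans ``exonic`` exon-side positions and ``intronic``
    intron-side positions in transcript orientation; the intronic window
    includes the terminal dinucleotide.  Columns truncated at chromosome ends
    contribute to fewer counts, tracked in ``n_per_column``.
    """
    if site not in ("5prime", "3prime"):
        raise ValueError(f"site must be '5prime' or '3prime', got {site!r}")
    width = exonic + intronic
    counts = np.zeros((5, width), dtype=int)
    n_per_column = np.zeros(width, dtype=int)
    base_index = {b: i for i, b in enumerate("ACGTN")}

    for intron in introns:
        chrom_seq = g[intron.chrom]
        chrom_len = len(chrom_seq)
        # window on the genome in transcript orientation, then per-column fill
        if site == "5prime":
            # last `exonic` exon bases upstream + first `intronic` intron bases
            if intron.strand == "+":
                gstart, gend = intron.start - exonic, intron.start + intronic
            else:
                gstart, gend = intron.end - intronic, intron.end + exonic
        else:
            # last `intronic` intron bases + first `exonic` exon bases downstream
            if intron.strand == "+":
                gstart, gend = intron.end - intronic, intron.end + exonic
            else:
                gstart, gend = intron.start - exonic, intron.start + intronic
        lo, hi = max(0, gstart), min(chrom_len, gend)
        window = chrom_seq[lo:hi]
        left_pad = lo - gstart
        right_pad = gend - hi
        window = "." * left_pad + window + "." * right_pad
        if intron.strand == "-":
            window = reverse_complement(window)  # "." padding passes through
        for col, base in enumerate(window):
            if base == ".":
                continue
            counts[base_index[base], col] += 1
            n_per_column[col] += 1

    if site == "5prime":
        labels = [f"E{-(exonic - i)}" for i in range(exonic)] + [
            f"I{i + 1}" for i in range(intronic)
        ]
    else:
        labels = [f"I{-(intronic - i)}" for i in range(intronic)] + [
            f"E{i + 1}" for i in range(exonic)
        ]
    matrix = pd.DataFrame(counts, index=list("ACGTN"), columns=labels)
    return FlankProfile(site=site, matrix=matrix, n=len(introns), n_per_column=n_per_column)


def cds_offset(t: TranscriptModel, intron: IntronRecord) -> int | None:
    """Bases of CDS upstream of the intron in transcript orientation.

    Returns None (UTR intron, not evaluated) when the intron does not fall
    between CDS segments of the transcript.
    """
    if not t.cds:
        return None
    cds_start = min(s for s, _ in t.cds)
    cds_end = max(e for _, e in t.cds)
    if not (cds_start <= intron.start and intron.end <= cds_end):
        return None
    if t.strand == "+":
        return sum(min(e, intron.start) - s for s, e in t.cds if s < intron.start)
    return sum(e - max(s, intron.end) for s, e in t.cds if e > intron.end)


def introns_to_bed(introns: Iterable[IntronRecord]) -> pd.DataFrame:
    """Intron records as BED6 (0-based half-open, score = intron index)."""
    rows = [
        (i.chrom, i.start, i.end, f"{i.transcript_id}.intron{i.index}", i.index, i.strand)
        for i in introns
    ]
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score", "strand"])
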