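"""Cross-species statistics: diversity, GC correlations, group tests, frames.

Shannon diversity H' = -sum p ln p (nats) summarises the splice-site
combination spectrum of a species; computing it on the spectrum with GT-AG
and GC-AG excluded (mass renormalised) isolates the diversity of the rarer
combinations.  Frame analysis asks which introns could be retained in a
mature transcript without disrupting the reading frame: length divisible by
three and no stop codon in the frame continuing from the upstream CDS.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .annotation import (
    CombinationTable,
    GenomeSequence,
    IntronRecord,
    TranscriptModel,
    cds_offset,
    classify_combination,
    weighted_splice_gc,
)

logger = logging.getLogger(__name__)

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

#: default exclusion for the reduced-spectrum diversity
DEFAULT_EXCLUDE = frozenset({"GT-AG", "GC-AG"})


@dataclass
class SpeciesSummary:
    species_id: str
    kingdom: str
    genome_gc: float
    intron_gc: float
    splice_gc: float
    introns_per_gene: float
    table: CombinationTable
    h_all: float
    h_excl: float


@dataclass
class FrameSummary:
    class_label: str
    n_qualifying: int
    n_total: int

    @property
    def proportion(self) -> float:
        return self.n_qualifying / self.n_total


def shannon_diversity(
    freqs: Mapping[str, float],
    exclude: Iterable[str] = (),
) -> float:
    """Shannon diversity (nats) of a combination spectrum.

    Combinations in ``exclude`` are removed and the remaining mass is
    renormalised before the index is computed.  Returns NaN (with a warning)
    when nothing remains.
    """
    exclude = set(exclude)
    included = {c: p for c, p in freqs.items() if c not in exclude and p > 0}
    mass = sum(included.values())
    if mass == 0:
        logger.warning("no probability mass left after exclusion; H undefined")
        return float("nan")
    p = np.array(list(included.values())) / mass
    return float(-np.sum(p * np.log(p)))


def gc_correlation(points: Sequence[tuple[float, float]]) -> tuple[float, float]:
    """Pearson correlation (r, two-sided p) between two GC measures across
    species, e.g. genomic GC vs occurrence-weighted splice-site GC."""
    if len(points) < 3:
        raise ValueError("need at least 3 species for a correlation")
    x, y = zip(*points)
    if min(x) == max(x) or min(y) == max(y):
        logger.warning("zero variance in one axis; correlation undefined")
        return float("nan"), float("nan")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def compare_groups(*groups: Sequence[float]) -> tuple[float, float]:
    """Rank-based comparison of per-species frequency samples.

    Two groups: two-sided Mann-Whitney U (normal approximation with tie
    correction).  Three or more: Kruskal-Wallis H.  Returns (statistic, p).
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for g in groups:
        if len(g) < 2:
            raise ValueError("each group needs at least 2 observations")
    if len(groups) == 2:
        res = sps.mannwhitneyu(groups[0], groups[1], alternative="two-sided",
                               method="asymptotic")
    else:
        res = sps.kruskal(*groups)
    return float(res.statistic), float(res.pvalue)


def intron_frame_check(i: IntronRecord, cds_offset_bases: int | None) -> bool | None:
    """Could this intron be retained without a frameshift or premature stop?

    Qualifies iff its length is divisible by three and no TAA/TAG/TGA occurs
    in the reading frame continuing from the upstream CDS.  With
    ``cds_offset_bases mod 3 = r``, the first ``(3 - r) mod 3`` intronic bases
    complete the interrupted codon, and whole codons are scanned from there.
    Returns None for introns outside the CDS (not evaluated).
    """
    if cds_offset_bases is None:
        return None
    if i.length % 3 != 0:
        return False
    offset = (3 - cds_offset_bases % 3) % 3
    seq = i.sequence
    for pos in range(offset, len(seq) - 2, 3):
        if seq[pos:pos + 3] in STOP_CODONS:
            return False
    return True


def frame_summary(
    introns: Sequence[IntronRecord],
    qualifies: Sequence[bool | None],
    by: str = "combination",
) -> list[FrameSummary]:
    """Aggregate frame-check flags per combination (or per class label).

    Introns flagged None (UTR) are skipped; empty groups are omitted.
    ``by`` is "combination" for per-combination rows or "class" to pool by
    canonical / major / minor label.
    """
    groups: dict[str, list[bool]] = {}
    for intron, q in zip(introns, qualifies):
        if q is None:
            continue
        if by == "class":
            label = classify_combination(intron.donor, intron.acceptor)
        else:
            label = intron.combination
        groups.setdefault(label, []).append(q)
    return [
        FrameSummary(class_label=label, n_qualifying=sum(flags), n_total=len(flags))
        for label, flags in sorted(groups.items())
    ]


def intron_gc(introns: Iterable[IntronRecord]) -> float:
    """Pooled GC fraction over all intron sequences (N excluded)."""
    gc = acgt = 0
    for i in introns:
        gc += i.sequence.count("G") + i.sequence.count("C")
        acgt += i.length - i.sequence.count("N")
    return gc / acgt if acgt else float("nan")


def species_summary(
    species_id: str,
    kingdom: str,
    genome: GenomeSequence,
    transcripts: Sequence[TranscriptModel],
    introns: Sequence[IntronRecord],
    table: CombinationTable,
) -> SpeciesSummary:
    n_genes = len({t.gene_id for t in transcripts})
    return SpeciesSummary(
        species_id=species_id,
        kingdom=kingdom,
        genome_gc=genome.gc_content(),
        intron_gc=intron_gc(introns),
        splice_gc=weighted_splice_gc(table),
        introns_per_gene=len(introns) / n_genes if n_genes else float("nan"),
        table=table,
        h_all=shannon_diversity(table.frequencies),
        h_excl=shannon_diversity(table.frequencies, exclude=DEFAULT_EXCLUDE),
    )


def kingdom_table(summaries: Sequence[SpeciesSummary]) -> pd.DataFrame:
    """One row per species: headline combination frequencies, GC metrics and
    diversity values."""
    rows = []
    for s in summaries:
        f = s.table.frequencies
        others = 1.0 - f.get("GT-AG", 0) - f.get("GC-AG", 0) - f.get("AT-AC", 0)
        rows.append(
            {
                "species": s.species_id,
                "kingdom": s.kingdom,
                "n_introns": s.table.total,
                "freq_GT-AG": f.get("GT-AG", 0.0),
                "freq_GC-AG": f.get("GC-AG", 0.0),
                "freq_AT-AC": f.get("AT-AC", 0.0),
                "freq_others": max(0.0, others) if s.table.total else float("nan"),
                "genome_gc": s.genome_gc,
                "intron_gc": s.intron_gc,
                "splice_gc": s.splice_gc,
                "introns_per_gene": s.introns_per_gene,
                "H_all": s.h_all,
                "H_excl": s.h_excl,
            }
        )
    return pd.DataFrame(rows)
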