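"""Sequence-variant overlap with splice-site dinucleotide positions.

Compares the per-base variant rate over the four border bases of each intron
(donor + acceptor dinucleotides) with the rate over a background region
(internal exonic bases by default), yielding an enrichment ratio.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .annotation import IntronRecord, TranscriptModel

logger = logging.getLogger(__name__)


@dataclass
class VariantSet:
    """Variant positions as (chromosome, 0-based position) pairs."""

    positions: set[tuple[str, int]]
    source: str = ""

    def __len__(self) -> int:
        return len(self.positions)


@dataclass
class VariantRates:
    rate_splice: float
    rate_background: float
    n_splice_variants: int
    n_splice_bases: int
    n_background_variants: int
    n_background_bases: int

    @property
    def ratio(self) -> float:
        if self.rate_background == 0:
            logger.warning("background variant rate is 0; enrichment ratio undefined")
            return float("nan")
        return self.rate_splice / self.rate_background

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "rate_splice": self.rate_splice,
                    "rate_background": self.rate_background,
                    "ratio": self.ratio,
                    "n_splice_variants": self.n_splice_variants,
                    "n_splice_bases": self.n_splice_bases,
                    "n_background_variants": self.n_background_variants,
                    "n_background_bases": self.n_background_bases,
                }
            ]
        )


def parse_vcf(path, pass_only: bool = True) -> VariantSet:
    """Read variant positions from a VCF (v4.x) file.

    One 0-based position per record (indels contribute their POS).  Records
    with a non-PASS filter are excluded by default; malformed records are
    skipped with a warning.
    """
    import pysam

    positions: set[tuple[str, int]] = set()
    with pysam.VariantFile(str(path)) as vcf:
        for record in vcf:
            try:
                if pass_only and record.filter.keys() not in ([], ["PASS"], ["."]):
                    continue
                positions.add((record.chrom, record.pos - 1))
            except Exception as exc:  # malformed record
                logger.warning("skipping malformed VCF record: %s", exc)
    return VariantSet(positions=positions, source=str(path))


def splice_border_positions(introns: Iterable[IntronRecord]) -> set[tuple[str, int]]:
    """The four genomic border bases (donor + acceptor dinucleotides) of each
    intron."""
    positions: set[tuple[str, int]] = set()
    for i in introns:
        positions.update(
            (i.chrom, p)
            for p in (i.start, i.start + 1, i.end - 2, i.end - 1)
        )
    return positions


def internal_exonic_intervals(
    transcripts: Iterable[TranscriptModel],
) -> list[tuple[str, int, int]]:
    """Internal exonic bases of representative transcripts: every exon except
    the transcript's first and last (which flank UTR/adjacent genes)."""
    intervals = []
    for t in transcripts:
        if len(t.exons) <= 2:
            continue
        intervals.extend((t.chrom, s, e) for s, e in t.exons[1:-1])
    return intervals


def splice_variant_rates(
    variants: VariantSet,
    introns: Sequence[IntronRecord],
    background: Sequence[tuple[str, int, int]],
) -> VariantRates:
    """Per-base variant rates at splice borders vs background, plus ratio.

    Background intervals are (chrom, start, end) 0-based half-open.  Splice
    border bases that also fall into the background are excluded from the
    background denominator so the two rates are computed on disjoint sets.
    """
    border = splice_border_positions(introns)
    bg_bases: set[tuple[str, int]] = set()
    for chrom, start, end in background:
        bg_bases.update((chrom, p) for p in range(start, end))
    bg_bases -= border
    if not bg_bases:
        raise ValueError("background region is empty")
    n_splice = len(border & variants.positions)
    n_background = len(bg_bases & variants.positions)
    return VariantRates(
        rate_splice=n_splice / len(border) if border else 0.0,
        rate_background=n_background / len(bg_bases),
        n_splice_variants=n_splice,
        n_splice_bases=len(border),
        n_background_variants=n_background,
        n_background_bases=len(bg_bases),
    )
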