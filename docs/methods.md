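# Methods

## Coordinate and orientation conventions

All internal coordinates are 0-based half-open; GFF3 (1-based inclusive) is
converted once, at the parser boundary. Exons are stored sorted by genomic
start regardless of strand. Intron indices are 1-based in transcript
orientation, so intron 1 of a minus-strand transcript is the genomically
last inter-exon gap. Donor and acceptor dinucleotides are always read in
transcript orientation: a minus-strand intron's genomic slice is reverse
complemented before its first two (donor) and last two (acceptor) bases are
taken. This makes the whole analysis invariant under reverse-complementing
the genome and mirroring the annotation, a property the test suite checks
exhaustively on synthetic species.

## Representative transcripts

One transcript per gene enters all counting, to avoid isoform
double-counting: the transcript with the longest total CDS, ties broken by
longest exonic span, then lexicographically smallest transcript id. The rule
is isolated in `select_representative` so an alternative convention can be
swapped in without touching anything else.

## Extraction and classification

Annotated gaps shorter than 4 bases are excluded (donor and acceptor would
overlap) and logged. An `N` in either border dinucleotide marks the record
ambiguous; ambiguous records are excluded from combination totals so
sequence ambiguity cannot manufacture phantom minor combinations. Exactly
one combination (GT-AG) is canonical and exactly two (GC-AG, AT-AC) are
major non-canonical; the remaining 253 are minor. `CT-AC` deserves special
mention: it is the reverse complement of GT-AG, so transcripts annotated on
the wrong strand surface as CT-AC — the generator can plant this artifact
and the classifier's `reverse_complement_combination` (an involution) maps
it back.

## Flank profiles

Position frequency matrices span 7 exonic and 7 intronic positions per
splice site, in transcript orientation, with the terminal dinucleotide
included in the intronic window (so 5 additional interior bases). Both
window widths are parameters. Windows truncated by chromosome ends reduce
that column's denominator rather than being dropped, and per-column
denominators are carried on the profile.

## RNA-Seq support and usage

Coverage is consumed, never produced: either a coordinate-sorted BAM
(alignments filtered to ≥95% identity over ≥90% of the read length where
tags permit; secondary/supplementary and multi-mapped reads excluded;
junctions taken from CIGAR `N` operations) or a pre-filtered 4-column
interval-depth TSV plus a junction TSV. A site is supported when the exact
intron interval is spanned by at least `min_reads` (default 3) split reads
AND the depth at the first/last intronic base is at most `(1 − drop)` times
the depth at the adjacent exonic base at both borders, with `drop = 0.2` by
default. The comparison is inclusive — a drop of exactly 20% passes —
because the threshold names the boundary itself. Requiring exact-interval
split reads (not just depth) is what distinguishes a spliced intron from a
retained one. A border with zero exonic depth cannot be evaluated; the
result is unsupported and flagged `no-coverage`.

Usage per border is the relative drop clamped to [0, 1]; the per-intron
delta (5′ minus 3′) is antisymmetric under swapping the borders, which the
suite checks as a property. Expression records bin genes by FPKM
(`count / (length/1000 · total/10^6)`) after excluding genes above the 99th
percentile (configurable); cumulative relative bin sizes are reported per
splice-class group, and a gene with several non-canonical combinations
belongs to several groups. The isoform-presence estimate compares local
coverage (mean depth of the two exonic bases flanking an intron) with the
transcript-wide expectation `200 · read_count / transcript_length`, the 200
reflecting 2 × 100 nt read pairs.

## Statistics

Shannon diversity uses natural logarithms. Two variants are computed per
species: over the full spectrum, and with GT-AG and GC-AG excluded and the
remaining mass renormalised, which isolates the diversity of the rare tail.
Group comparisons use the two-sided Mann–Whitney U (normal approximation,
average ranks, tie-corrected variance, via scipy) for two groups and
Kruskal–Wallis for three or more. GC correlations are plain Pearson r with
two-sided p; degenerate (zero-variance) inputs return NaN with a warning
rather than raising.

The frame check anchors the reading frame to the upstream CDS phase: with
`r = cds_offset mod 3`, the first `(3 − r) mod 3` intronic bases complete
the interrupted codon and whole codons are scanned from there for
TAA/TAG/TGA. Introns outside the CDS are not evaluated. The frame is not
self-evident from the data alone — anchoring to the upstream phase is the
biologically meaningful choice for retention, since that is the frame a
ribosome would read through a retained intron.

## Conservation scoring

Combinations are encoded one symbol per intron: GT-AG is pinned to a fixed
symbol, the next 18 globally most frequent combinations get fixed distinct
amino-acid-style letters (descending count, ties lexicographic), and all
others share a single rare symbol — 20 symbols total, matching an
amino-acid alphabet so the strings behave like peptide sequences under
alignment. Alignment is global Needleman–Wunsch with match +1, mismatch 0,
gap −1 (all configurable) and a deterministic traceback preference
(diagonal, then gap in the first argument, then gap in the second), so
results are reproducible to the byte. Scoring was cross-checked against an
exhaustive enumeration of all alignments for short strings and against an
independently configured Biopython aligner. Conservation is counted per
query non-canonical position over pairwise query–homolog alignments (one
homolog per species, supplied externally as a pair table): identical
combination / other non-canonical / canonical GT-AG partition the aligned
non-gap homologs; gap-only alignments are counted separately.

## Variant overlap

The splice-site footprint is the 4 border bases per intron. The default
background is the internal exonic bases of representative transcripts
(terminal exons excluded as UTR-contaminated); border bases are removed
from the background so the two rates are measured on disjoint sets. The
enrichment ratio is undefined (NaN, flagged) when the background rate is
zero. Only PASS (or unfiltered) VCF records count by default.

## Synthetic data: what it emulates, and what it does not

The generator emits genes as alternating exon/intron segments on both
strands, assembled into chromosomes with random intergenic spacers. Defaults
follow the study conditions the analysis targets: exon counts are
1 + Poisson with kingdom presets of 1.49 introns/gene (fungi-like, GC 0.471,
short introns) and 6.95 introns/gene (animal-like, GC 0.394); intron
lengths are shifted geometric with a 20 bp minimum; bases are drawn iid at
the GC target, which concentrates exonic GC within well under 2 points of
target over 100 kb. Intron borders carry exactly the sampled mixture
combination. Antisense-artifact genes are generated with canonical GT-AG
introns and annotated on the opposite strand. Coverage is piecewise
constant per segment at `depth · expression` (expression lognormal,
σ = 0.5), optionally Poisson-noised per base, with spliced introns at zero,
retained introns at exonic depth, and exact-interval junction read counts;
a minor-isoform intron scales its junction reads and its two flanking
exonic bases by the minor-isoform weight (default 0.2). Variants are
independent Bernoulli draws per border/background base. Read counts per
gene are derived from coverage depth and transcript length assuming 200 bp
fragments, so FPKM, coverage and isoform estimates are mutually consistent.

What it deliberately does not model: splice-site motifs beyond the border
dinucleotides (no branch point, no polypyrimidine tract), sequencing error,
mappability structure, overlapping genes, alternative transcription starts,
and read-level alignment artifacts. Passing tests therefore demonstrate
that the analysis recovers planted structure through the standard file
formats — not that real RNA-Seq noise regimes are handled; on real data the
validation thresholds (3 reads, 20%) carry that burden, exactly as they do
in the published analyses this tooling supports.

## Numerical and degenerate-input choices

Empty combination tables report undefined frequencies and are flagged, not
raised. Shannon diversity of an empty post-exclusion spectrum is NaN with a
warning. Frequencies sum to 1 within 1e−9 by construction. The acceptance
script sizes its simulations at 2,000 genes (~14,000 introns) for
extraction/mixture recovery, 300–600 genes for validation, antisense and
variant recovery, and 1,000 Mann–Whitney null replicates — large enough
that 3-standard-error recovery bands are a few tenths of a percentage point
for mixture frequencies while the whole run stays near ten seconds.

## Known limitations

- GFF3 parsing expects gene → mRNA → exon/CDS with resolvable `Parent`
  attributes; `transcript` feature types are not aliased to `mRNA`.
- BAM similarity filtering needs `NM` tags; without them alignments pass
  the identity filter.
- The conservation module consumes homolog pairs; it does not search for
  homologs, and pairwise (not multiple) alignment is used per query–homolog
  pair.
- Usage is a per-border coverage ratio; it does not deconvolve overlapping
  isoforms.
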