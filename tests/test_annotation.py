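"""Genome parsing, intron extraction and combination classification."""

import itertools

import pytest

from splicescan.annotation import (
    classify_combination,
    combination_gc,
    combination_table,
    extract_introns,
    flank_profile,
    parse_annotation,
    parse_genome,
    reverse_complement,
    reverse_complement_combination,
    select_representative,
    weighted_splice_gc,
    GenomeSequence,
    TranscriptModel,
    cds_offset,
)
from splicescan.pipeline import representative_transcripts
from splicescan.simulate import flip_species

from conftest import make_intron

ALL_COMBOS = [
    f"{d1}{d2}-{a1}{a2}"
    for d1, d2, a1, a2 in itertools.product("ACGT", repeat=4)
]


class TestParseGenome:
    def test_case_normalisation(self, tmp_path):
        p = tmp_path / "g.fasta"
        p.write_text(">chr1\nacgt\n")
        assert parse_genome(p).sequences == {"chr1": "ACGT"}

    def test_ambiguity_to_n(self, tmp_path):
        p = tmp_path / "g.fasta"
        p.write_text(">c\nACRT\n")
        assert parse_genome(p).sequences == {"c": "ACNT"}

    def test_duplicate_id_rejected(self, tmp_path):
        p = tmp_path / "g.fasta"
        p.write_text(">a\nACGT\n>a\nTTTT\n")
        with pytest.raises(ValueError, match="duplicate"):
            parse_genome(p)

    def test_empty_file_rejected(self, tmp_path):
        p = tmp_path / "g.fasta"
        p.write_text("")
        with pytest.raises(ValueError):
            parse_genome(p)

    def test_synthetic_round_trip(self, mixture_species):
        _, files = mixture_species
        g = parse_genome(files.fasta)
        assert set(g.sequences) == set(files.manifest.chrom_lengths)
        for chrom, length in files.manifest.chrom_lengths.items():
            assert g.length(chrom) == length


class TestParseAnnotation:
    def test_single_exon_mrna(self, tmp_path, tiny_genome):
        gff = tmp_path / "a.gff3"
        gff.write_text(
            "##gff-version 3\n"
            "chr1\tsrc\tgene\t1\t40\t.\t+\t.\tID=g1\n"
            "chr1\tsrc\tmRNA\t1\t40\t.\t+\t.\tID=t1;Parent=g1\n"
            "chr1\tsrc\texon\t1\t40\t.\t+\t.\tID=e1;Parent=t1\n"
        )
        models = parse_annotation(gff, tiny_genome)
        assert len(models) == 1
        assert models[0].exons == [(0, 40)]
        assert models[0].n_introns == 0

    def test_minus_strand_exons_sorted_by_genomic_start(self, tmp_path, tiny_genome):
        gff = tmp_path / "a.gff3"
        gff.write_text(
            "##gff-version 3\n"
            "chr1\tsrc\tgene\t1\t40\t.\t-\t.\tID=g1\n"
            "chr1\tsrc\tmRNA\t1\t40\t.\t-\t.\tID=t1;Parent=g1\n"
            "chr1\tsrc\texon\t29\t40\t.\t-\t.\tID=e1;Parent=t1\n"
            "chr1\tsrc\texon\t1\t8\t.\t-\t.\tID=e2;Parent=t1\n"
        )
        models = parse_annotation(gff, tiny_genome)
        assert models[0].exons == [(0, 8), (28, 40)]

    def test_out_of_bounds_exon_rejected(self, tmp_path, tiny_genome, caplog):
        gff = tmp_path / "a.gff3"
        gff.write_text(
            "##gff-version 3\n"
            "chr1\tsrc\tgene\t1\t999\t.\t+\t.\tID=g1\n"
            "chr1\tsrc\tmRNA\t1\t999\t.\t+\t.\tID=t1;Parent=g1\n"
            "chr1\tsrc\texon\t1\t999\t.\t+\t.\tID=e1;Parent=t1\n"
        )
        assert parse_annotation(gff, tiny_genome) == []

    def test_synthetic_round_trip(self, mixture_species):
        _, files = mixture_species
        g = parse_genome(files.fasta)
        models = parse_annotation(files.gff3, g)
        assert len(models) == len(files.manifest.genes)
        by_id = {m.transcript_id: m for m in models}
        for gene in files.manifest.genes:
            m = by_id[gene.transcript_id]
            assert m.exons == gene.exons
            assert m.strand == gene.annotated_strand


class TestSelectRepresentative:
    def _t(self, tid, cds_len, exon_len=100):
        return TranscriptModel(
            transcript_id=tid, gene_id="g", chrom="c", strand="+",
            exons=[(0, exon_len)], cds=[(0, cds_len)],
        )

    def test_single_transcript_is_itself(self):
        t = self._t("t1", 300)
        assert select_representative([t]) is t

    def test_longest_cds_wins(self):
        assert select_representative(
            [self._t("t1", 300), self._t("t2", 450)]
        ).transcript_id == "t2"

    def test_tie_breaks_lexicographic(self):
        assert select_representative(
            [self._t("t2", 300), self._t("t1", 300)]
        ).transcript_id == "t1"

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            select_representative([])


class TestExtractIntrons:
    def test_single_exon_yields_nothing(self, tiny_genome):
        t = TranscriptModel("t1", "g1", "chr1", "+", exons=[(0, 40)])
        assert extract_introns(t, tiny_genome) == []

    def test_plus_strand_canonical(self, tiny_genome, plus_transcript):
        (intron,) = extract_introns(plus_transcript, tiny_genome)
        assert (intron.donor, intron.acceptor) == ("GT", "AG")
        assert (intron.start, intron.end) == (8, 28)
        assert intron.sequence == tiny_genome["chr1"][8:28]

    def test_minus_strand_matches_flipped_plus_gene(self, tiny_genome, plus_transcript):
        """Brute-force strand oracle: the same gene on the minus strand of
        the reverse-complemented genome yields identical donor/acceptor."""
        L = tiny_genome.length("chr1")
        flipped = GenomeSequence({"chr1": reverse_complement(tiny_genome["chr1"])})
        t = TranscriptModel(
            "t1", "g1", "chr1", "-",
            exons=sorted((L - e, L - s) for s, e in plus_transcript.exons),
        )
        (a,) = extract_introns(plus_transcript, tiny_genome)
        (b,) = extract_introns(t, flipped)
        assert (a.donor, a.acceptor, a.sequence) == (b.donor, b.acceptor, b.sequence)

    def test_short_gap_excluded(self, tiny_genome):
        t = TranscriptModel("t1", "g1", "chr1", "+", exons=[(0, 8), (10, 20)])
        assert extract_introns(t, tiny_genome) == []

    def test_minus_strand_intron_index_is_transcript_order(self):
        # two introns; on '-' the genomically-last gap is intron 1
        seq = ("A" * 10 + "GT" + "C" * 16 + "AG" + "A" * 10
               + "GC" + "C" * 16 + "AG" + "A" * 10)
        g = GenomeSequence({"c": reverse_complement(seq)})
        L = len(seq)
        exon_plus = [(0, 10), (30, 40), (60, 70)]
        t = TranscriptModel(
            "t1", "g1", "c", "-",
            exons=sorted((L - e, L - s) for s, e in exon_plus),
        )
        introns = extract_introns(t, g)
        assert [i.index for i in introns] == [1, 2]
        assert introns[0].combination == "GT-AG"
        assert introns[1].combination == "GC-AG"

    def test_synthetic_truth_oracle(self, mixture_species):
        _, files = mixture_species
        g = parse_genome(files.fasta)
        reps = representative_transcripts(parse_annotation(files.gff3, g))
        truth = files.manifest.introns_by_interval
        n = 0
        for t in reps:
            for i in extract_introns(t, g):
                expected = truth[(i.chrom, i.start, i.end)]
                assert i.combination == expected.annotated_combination
                n += 1
        assert n == files.manifest.n_introns


class TestClassification:
    @pytest.mark.parametrize(
        "donor,acceptor,label",
        [
            ("GT", "AG", "canonical"),
            ("GC", "AG", "major_noncanonical"),
            ("AT", "AC", "major_noncanonical"),
            ("GA", "AG", "minor_noncanonical"),
            ("CT", "AC", "minor_noncanonical"),
            ("GN", "AG", "ambiguous"),
        ],
    )
    def test_labels(self, donor, acceptor, label):
        assert classify_combination(donor, acceptor) == label

    def test_class_partition_over_all_combinations(self):
        labels = [classify_combination(*c.split("-")) for c in ALL_COMBOS]
        assert labels.count("canonical") == 1
        assert labels.count("major_noncanonical") == 2
        assert labels.count("minor_noncanonical") == 253


class TestReverseComplementCombination:
    def test_ct_ac_is_antisense_canonical(self):
        assert reverse_complement_combination("CT-AC") == "GT-AG"
        assert reverse_complement_combination("GT-AG") == "CT-AC"

    def test_involution_over_all_256(self):
        for combo in ALL_COMBOS:
            assert reverse_complement_combination(
                reverse_complement_combination(combo)
            ) == combo


class TestCombinationTable:
    def test_frequencies(self):
        introns = [make_intron("GT", "AG")] * 98 + [make_intron("GC", "AG")] * 2
        table = combination_table(introns)
        assert table.total == 100
        assert table.frequencies["GT-AG"] == pytest.approx(0.98)
        assert abs(sum(table.frequencies.values()) - 1) < 1e-9

    def test_single_at_ac(self):
        table = combination_table([make_intron("AT", "AC")])
        assert table.frequencies["AT-AC"] == 1.0
        assert table.classes["AT-AC"] == "major_noncanonical"

    def test_ambiguous_excluded(self):
        table = combination_table(
            [make_intron("GT", "AG"), make_intron("GN", "AG")]
        )
        assert table.total == 1
        assert table.n_ambiguous == 1

    def test_empty_flagged(self):
        table = combination_table([])
        assert table.total == 0
        assert table.frequencies == {}


class TestGC:
    @pytest.mark.parametrize(
        "combo,gc", [("AT-AC", 0.25), ("GC-GC", 1.0), ("AT-AT", 0.0), ("GT-AG", 0.5)]
    )
    def test_combination_gc(self, combo, gc):
        assert combination_gc(combo) == gc

    def test_weighted_gc_mixture(self):
        introns = [make_intron("AT", "AC")] * 50 + [make_intron("GC", "GC", start=100)] * 50
        assert weighted_splice_gc(combination_table(introns)) == pytest.approx(0.625)

    def test_weighted_gc_equals_per_record_mean(self, mixture_species):
        """Oracle: table-weighted GC equals the brute-force mean over records."""
        _, files = mixture_species
        g = parse_genome(files.fasta)
        reps = representative_transcripts(parse_annotation(files.gff3, g))
        introns = [i for t in reps for i in extract_introns(t, g)]
        table = combination_table(introns)
        brute = sum(combination_gc(i.combination) for i in introns) / len(introns)
        assert weighted_splice_gc(table) == pytest.approx(brute, abs=1e-12)


class TestStrandSymmetry:
    def test_combination_table_invariant_under_genome_flip(self, mixture_species):
        _, files = mixture_species
        g = parse_genome(files.fasta)
        reps = representative_transcripts(parse_annotation(files.gff3, g))
        introns = [i for t in reps for i in extract_introns(t, g)]
        fg, ft = flip_species(g, reps)
        flipped_introns = [i for t in ft for i in extract_introns(t, fg)]
        t1 = combination_table(introns)
        t2 = combination_table(flipped_introns)
        assert t1.counts == t2.counts
        assert t1.to_frame().to_csv(sep="\t") == t2.to_frame().to_csv(sep="\t")


class TestFlankProfile:
    def test_canonical_donor_columns(self, mixture_species):
        _, files = mixture_species
        g = parse_genome(files.fasta)
        reps = representative_transcripts(parse_annotation(files.gff3, g))
        introns = [
            i for t in reps for i in extract_introns(t, g)
            if i.combination == "GT-AG"
        ]
        profile = flank_profile(introns, g, "5prime")
        n = len(introns)
        assert profile.matrix.loc["G", "I1"] == n
        assert profile.matrix.loc["T", "I2"] == n
        # column sums equal the per-column denominators
        assert (profile.matrix.sum(axis=0).to_numpy() == profile.n_per_column).all()

    def test_acceptor_columns(self, mixture_species):
        _, files = mixture_species
        g = parse_genome(files.fasta)
        reps = representative_transcripts(parse_annotation(files.gff3, g))
        introns = [
            i for t in reps for i in extract_introns(t, g)
            if i.combination == "GT-AG"
        ]
        profile = flank_profile(introns, g, "3prime")
        n = len(introns)
        assert profile.matrix.loc["A", "I-2"] == n
        assert profile.matrix.loc["G", "I-1"] == n

    def test_planted_exonic_context_recovered(self, tmp_path):
        """A GA-AG species with planted upstream exonic AG shows the planted
        consensus in the exonic columns of the 5' profile."""
        from splicescan.simulate import SyntheticSpec, generate_species

        spec = SyntheticSpec(
            seed=5, n_genes=60, mean_introns_per_gene=2.0,
            mixture={"GA-AG": 1.0}, exonic_context_5="AG",
            species_id="gaag",
        )
        files = generate_species(spec, tmp_path)
        g = parse_genome(files.fasta)
        reps = representative_transcripts(parse_annotation(files.gff3, g))
        introns = [i for t in reps for i in extract_introns(t, g)]
        assert introns and all(i.combination == "GA-AG" for i in introns)
        profile = flank_profile(introns, g, "5prime")
        assert profile.consensus()[5:9] == "AGGA"  # E-2 E-1 | I1 I2

    def test_single_intron_counts(self, tiny_genome, plus_transcript):
        (intron,) = extract_introns(plus_transcript, tiny_genome)
        profile = flank_profile([intron], tiny_genome, "5prime")
        assert profile.n == 1
        assert (profile.matrix.sum(axis=0) <= 1).all()

    def test_truncated_window_reduces_denominator(self):
        g = GenomeSequence({"c": "AAGT" + "C" * 16 + "AGGG"})
        t = TranscriptModel("t1", "g1", "c", "+", exons=[(0, 2), (22, 24)])
        (intron,) = extract_introns(t, g)
        profile = flank_profile([intron], g, "5prime")
        # only 2 exonic bases exist; the 5 outermost exonic columns are empty
        assert list(profile.n_per_column) == [0, 0, 0, 0, 0, 1, 1, 1, 1, 1, 1, 1, 1, 1]


class TestCdsOffset:
    def test_offset_accumulates_exonic_cds(self, tiny_genome, plus_transcript):
        (intron,) = extract_introns(plus_transcript, tiny_genome)
        assert cds_offset(plus_transcript, intron) == 8

    def test_utr_intron_not_evaluated(self, tiny_genome):
        t = TranscriptModel(
            "t1", "g1", "chr1", "+", exons=[(0, 8), (28, 40)], cds=[(30, 40)]
        )
        (intron,) = extract_introns(t, tiny_genome)
        assert cds_offset(t, intron) is None
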