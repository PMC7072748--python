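import pytest

from splicescan.annotation import GenomeSequence, IntronRecord, TranscriptModel
from splicescan.simulate import SyntheticSpec, generate_species

MIXTURE = {"GT-AG": 0.97, "GC-AG": 0.02, "AT-AC": 0.005, "GA-AG": 0.005}


@pytest.fixture
def tiny_genome():
    #        exon1      intron (GT..AG)        exon2
    # chr1:  0-8        8-28                   28-40
    intron = "GT" + "C" * 16 + "AG"
    seq = "ATGGCCAA" + intron + "GGCTTACCGGAT"
    return GenomeSequence({"chr1": seq})


@pytest.fixture
def plus_transcript():
    return TranscriptModel(
        transcript_id="t1", gene_id="g1", chrom="chr1", strand="+",
        exons=[(0, 8), (28, 40)], cds=[(0, 8), (28, 40)],
    )


def make_intron(donor="GT", acceptor="AG", length=20, strand="+",
                chrom="chr1", start=8, interior="C", index=1,
                transcript_id="t1", gene_id="g1"):
    seq = donor + interior * (length - 4) + acceptor
    return IntronRecord(
        transcript_id=transcript_id, gene_id=gene_id, index=index,
        chrom=chrom, start=start, end=start + length, strand=strand,
        donor=donor, acceptor=acceptor, sequence=seq,
    )


@pytest.fixture(scope="session")
def mixture_species(tmp_path_factory):
    """A mid-size synthetic species with a known combination mixture."""
    spec = SyntheticSpec.animal_like(
        seed=11, n_genes=300, mixture=dict(MIXTURE), species_id="mix300"
    )
    outdir = tmp_path_factory.mktemp("mixture_species")
    files = generate_species(spec, outdir)
    return spec, files
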