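import pytest

from methscreen.models import GeneModel, Methylome, ModificationCall


def make_call(position, strand="+", mod_type="m4C", seqid="chr", score=None, coverage=None):
    return ModificationCall(
        seqid=seqid, position=position, strand=strand, mod_type=mod_type,
        score=score, coverage=coverage,
    )


def make_methylome(positions, sample_id="s", **kwargs):
    return Methylome(sample_id, (make_call(p, **kwargs) for p in positions))


@pytest.fixture
def plus_gene():
    """A 621 bp '+' CDS at [1000, 1620] — the archetype regulator span."""
    return GeneModel(
        gene_id="orf4759", orf_ordinal=4759, seqid="chr",
        start=1000, end=1620, strand="+",
        product="Transcriptional regulator, TetR family",
    )


@pytest.fixture
def minus_gene():
    return GeneModel(
        gene_id="orf10", orf_ordinal=10, seqid="chr",
        start=1000, end=1620, strand="-", product="Regulatory protein",
    )
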