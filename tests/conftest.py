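import numpy as np
import pytest

from teadapt.annotations import GeneModel, Transcript
from teadapt.te_frequency import TEInsertion


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_te(te_id="TE0001", chrom="2L", start=10_000, end=13_000, canonical=6_000,
            family="jockey", order="nonLTR"):
    return TEInsertion(te_id=te_id, family=family, order=order, chrom=chrom,
                       start=start, end=end, canonical_length=canonical)


def make_gene(gene_id="G0001", chrom="2L", start=20_000, end=26_000,
              exons=None, cds=None, utrs=None, strand="+"):
    """A single-transcript gene; defaults give a 3-exon coding model with UTRs."""
    if exons is None:
        exons = [(start, start + 1_000), (start + 2_000, start + 3_000), (start + 5_000, end)]
    tx = Transcript(
        tx_id=f"{gene_id}.t1", strand=strand, exons=exons,
        cds=cds if cds is not None else [(start + 300, start + 1_000),
                                         (start + 2_000, start + 3_000),
                                         (start + 5_000, end - 400)],
        utrs=utrs if utrs is not None else [(start, start + 300), (end - 400, end)],
    )
    return GeneModel(gene_id=gene_id, chrom=chrom, start=start, end=end, strand=strand,
                     transcripts=[tx])


@pytest.fixture
def gene():
    return make_gene()
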