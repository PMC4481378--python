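import numpy as np
import pytest

from ricechip.models import Feature, GeneModel


@pytest.fixture
def rng():
    return np.random.default_rng(20150626)


@pytest.fixture
def coding_gene():
    """A + strand gene: CDS 101-109 / intron 110-129 / CDS 130-141,
    flanked by utr5 and utr3; sequence chosen so codons are readable."""
    # utr5 (100) + CDS1 "ATGGGTCCC" + intron (20 x T) + CDS2 "GCTAAAGGATGA" + utr3
    seq = "A" * 100 + "ATGGGTCCC" + "T" * 20 + "GCTAAAGGATGA" + "C" * 59
    return GeneModel(
        gene_id="gene1",
        chrom="1",
        start=1,
        end=200,
        strand="+",
        features=[
            Feature("utr5", 1, 100),
            Feature("CDS", 101, 109),
            Feature("intron", 110, 129),
            Feature("CDS", 130, 141),
            Feature("utr3", 142, 200),
        ],
        sequence=seq,
    )
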