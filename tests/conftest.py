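import numpy as np
import pytest

from rnasomatic.gene_models import TranscriptModel
from rnasomatic.synthetic_data import CohortConfig, simulate_cohort
from rnasomatic.variant_filters import VariantCall


@pytest.fixture
def toy_model():
    # MK*  -> ATG AAA TGA, plus-strand transcript space
    return TranscriptModel(
        gene_id="toy",
        transcript_id="toy.1",
        chrom="toy.1",
        strand="+",
        cds_intervals=((0, 9),),
        cds_sequence="ATGAAATGA",
    )


@pytest.fixture
def make_variant():
    def _make(chrom="toy.1", pos=0, ref="A", alt="G", qual=50.0, depth=30,
              alt_support=15, sample_id="s1", **kw):
        return VariantCall(chrom=chrom, pos=pos, ref=ref, alt=alt, qual=qual,
                           depth=depth, alt_support=alt_support, sample_id=sample_id, **kw)

    return _make


@pytest.fixture(scope="session")
def default_cohort():
    config = CohortConfig(
        n_genes=40,
        seed=11,
        smg_genes=[("G0001", 10.0)],
        tdg_genes=["G0002", "G0003"],
        deg_genes=[("G0004", 2.0)],
    )
    return simulate_cohort(config)
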