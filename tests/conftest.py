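import numpy as np
import pytest
from hypothesis import settings

from intronseek.gene_models import GenomeSequence, TranscriptModel
from intronseek.synthetic_data import table1_fixture

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def bundle(tmp_path_factory):
    """The case-series fixture world, written once per session."""
    out = tmp_path_factory.mktemp("table1")
    return table1_fixture(out_dir=str(out))


@pytest.fixture(scope="session")
def tx_by_gene(bundle):
    return {t.gene: t for t in bundle.models}


@pytest.fixture
def toy_tx():
    """Small plus-strand 3-exon transcript with CDS spanning all exons."""
    return TranscriptModel(
        transcript_id="TOY-1",
        gene="TOY",
        contig="chrT",
        strand="+",
        exons=[(100, 160), (260, 320), (420, 480)],
        cds_start=100,
        cds_end=480,
    )


@pytest.fixture
def toy_genome(toy_tx):
    rng = np.random.default_rng(11)
    seq = "".join(rng.choice(list("ACGT"), size=600))
    return GenomeSequence({"chrT": seq})
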