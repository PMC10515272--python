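import pytest

from sspminer.sequence_io import GenomeAnnotation
from sspminer.ssp_filter import PredictorConfig
from sspminer.synthetic import make_genome, make_proteome


@pytest.fixture(scope="session")
def heuristic_predictor():
    return PredictorConfig(heuristic=True)


@pytest.fixture(scope="session")
def proteome_seed7():
    """Default planted proteome (40 positives + 50 decoys), seed 7."""
    records, manifest = make_proteome(seed=7)
    return records, manifest


@pytest.fixture(scope="session")
def genome_seed11():
    """Planted genome: 12 secreted sORFs, 8 non-SP, 2 nested pairs, 3 CDS."""
    seqs, features, manifest = make_genome(seed=11)
    ann = GenomeAnnotation(sequences=seqs, features=features)
    return ann, manifest
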