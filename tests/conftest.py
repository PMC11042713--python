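import numpy as np
import pytest

from jaydiet import synthetic_data as sd
from jaydiet.read_qc import PrimerPair

PRIMER_F = "ACGTACGTAC"
PRIMER_R = "TGCATGCATG"


@pytest.fixture(scope="session")
def primers() -> PrimerPair:
    return PrimerPair(PRIMER_F, PRIMER_R)


@pytest.fixture(scope="session")
def clean_gap_library():
    """Small library with a clean barcode gap (intra << inter); even taxon
    count so every species has a congener and every genus a confamilial."""
    spec = sd.RefLibrarySpec(n_taxa=4, seqs_per_taxon=3, seq_length=240,
                             intra_divergence=0.005, inter_divergence=0.12,
                             seed=42)
    return sd.gen_reference_library(spec)


@pytest.fixture(scope="session")
def study_frame():
    from jaydiet.fixtures import study_observations
    return study_observations()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
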