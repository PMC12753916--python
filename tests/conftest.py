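import numpy as np
import pytest
from hypothesis import settings

from neoforge import TranscriptModel, generate_fixture_bundle
from neoforge.aaindex import default_aaindex_table

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def aaindex_table():
    return default_aaindex_table()


@pytest.fixture()
def toy_transcript():
    # CDS: ATG GCT GAA AAA CCC GGG TTT AAA CAT GAG -> MAEKPGFKHE
    cdna = "ATGGCTGAAAAACCCGGGTTTAAACATGAG"
    return TranscriptModel("TX1", "GENE1", "+", cdna, 0, 30)


@pytest.fixture(scope="session")
def tiny_bundle(tmp_path_factory):
    out = tmp_path_factory.mktemp("bundle")
    return generate_fixture_bundle(seed=7, scale="tiny", out_dir=out)


def random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=length))
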