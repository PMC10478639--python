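import numpy as np
import pytest
from hypothesis import settings

from mrprep import SyntheticSpec, generate_model

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")

TWO_RES_PDB = """\
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00 88.00           N
ATOM      2  CA  ALA A   1      11.639   6.071  -5.147  1.00 88.00           C
ATOM      3  C   ALA A   1      12.759   7.092  -4.955  1.00 88.00           C
ATOM      4  N   GLY A   2      13.300   7.151  -3.741  1.00 42.00           N
ATOM      5  CA  GLY A   2      14.390   8.075  -3.443  1.00 42.00           C
END
"""


@pytest.fixture
def two_res_pdb() -> str:
    return TWO_RES_PDB


@pytest.fixture
def two_domain_model():
    """Well-separated 2-domain fixture with a bridging linker."""
    spec = SyntheticSpec(
        domain_sizes=(60, 60), linker_lengths=(25,), separation=60.0, seed=11
    )
    model, truth = generate_model(spec)
    return model, truth


@pytest.fixture
def three_domain_model():
    spec = SyntheticSpec(
        domain_sizes=(60, 60, 60), linker_lengths=(25, 25), separation=60.0, seed=5
    )
    model, truth = generate_model(spec)
    return model, truth
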