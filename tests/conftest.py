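import pytest

from helixcov.msa_io import Alignment
from helixcov.simulate import SimulationParams, random_structure, simulate_structured_alignment


MINIMAL_STOCKHOLM = """# STOCKHOLM 1.0
seq1 GGACCUUCCA
seq2 GGACCAUCCA
#=GC SS_cons <<<....>>>
//
"""


@pytest.fixture
def minimal_stockholm(tmp_path):
    path = tmp_path / "minimal.sto"
    path.write_text(MINIMAL_STOCKHOLM)
    return path


@pytest.fixture
def small_alignment():
    return Alignment(
        names=["s1", "s2", "s3", "s4"],
        rows=["GGACCUUCCA", "GGACCAUCCA", "GCACCUUCGA", "GCACGAUCGA"],
        ss_cons="<<<....>>>",
    )


@pytest.fixture(scope="session")
def sim_alignment():
    """One structured simulator alignment under default study conditions."""
    params = SimulationParams(structure=random_structure(5), seed=5)
    return simulate_structured_alignment(params)
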