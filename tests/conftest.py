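import numpy as np
import pytest

from ededock import synthetic


@pytest.fixture(scope="session")
def toy_complex_path(tmp_path_factory):
    """3-residue peptide + 4-atom ligand with controlled contact distances."""
    path = tmp_path_factory.mktemp("toy") / "toy.pdb"
    synthetic.make_toy_complex(3, 4, [2.5, 3.5, 2.9], seed=1, out_path=path)
    return path


@pytest.fixture(scope="session")
def preset():
    """Small 4-state preset (800 frames) for unit tests."""
    return synthetic.four_state_preset(seed=3, n_frames=800)


@pytest.fixture(scope="session")
def preset_large():
    """Full-size 4-state preset (5000 frames) for recovery checks."""
    return synthetic.four_state_preset(seed=3, n_frames=5000)


@pytest.fixture(scope="session")
def preset_jitter():
    """Same preset with per-frame random rigid transforms applied."""
    return synthetic.four_state_preset(seed=3, n_frames=300, rigid_jitter=True)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
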