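import pytest

from psclip.build import build_clip_model
from psclip.classify import load_family_registry
from psclip.sequence import load_reference_clips
from psclip.synthetic import gen_helix


@pytest.fixture(scope="session")
def clips():
    """Shipped reference CLiP sequences keyed by name."""
    return load_reference_clips()


@pytest.fixture(scope="session")
def registry():
    """The 17-family motif-tree registry."""
    return load_family_registry()


@pytest.fixture(scope="session")
def orfamide_model(clips):
    """Closed de novo model of orfamide A (10:8), shared across tests."""
    return build_clip_model(clips["orfamide A"])


@pytest.fixture(scope="session")
def alpha_l_helix():
    """Noiseless 10-residue left-handed helix."""
    return gen_helix(10, "L", 0.0, seed=0)
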