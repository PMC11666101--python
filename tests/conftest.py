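import numpy as np
import pytest

from glycoshield.glycan_tree import load_representative_tree
from glycoshield.graft_sample import SamplerParams, graft, sample_ensemble
from glycoshield.synthetic_data import (
    ToyChannelParams,
    make_toy_channel,
    make_toy_ig,
)


@pytest.fixture(scope="session")
def representative_tree():
    return load_representative_tree()


@pytest.fixture(scope="session")
def toy_channel():
    return make_toy_channel()


@pytest.fixture(scope="session")
def small_toy_channel():
    """Two-loop channel: cheaper sampling for ensemble-level tests."""
    return make_toy_channel(ToyChannelParams(n_loops=2, glycosite_loops=(0, 1)))


@pytest.fixture(scope="session")
def small_ensemble(small_toy_channel, representative_tree):
    """Default-protocol ensemble (30 frames) on the two-loop toy channel."""
    tc = small_toy_channel
    grafts = [
        graft(tc.structure, site, representative_tree, seed=i,
              sequence=tc.sequence.residues, membrane=tc.membrane)
        for i, site in enumerate(tc.glycosites)
    ]
    return sample_ensemble(
        tc.structure, grafts, membrane=tc.membrane, params=SamplerParams(seed=11)
    )


@pytest.fixture(scope="session")
def toy_ig():
    return make_toy_ig()


def brute_force_clashes(xyz_a, xyz_b=None, cutoff=2.4, exclusion_mask=None):
    """Independent all-pairs clash counter used as the oracle in tests.

    Computes every pairwise distance directly (no spatial indexing, no
    shared code with the package's energy path).
    """
    from scipy.spatial.distance import cdist

    a = np.asarray(xyz_a, float)
    if xyz_b is None:
        d = cdist(a, a)
        close = d < cutoff
        np.fill_diagonal(close, False)
        if exclusion_mask is not None:
            close &= ~exclusion_mask
        return int(close.sum()) // 2
    b = np.asarray(xyz_b, float)
    return int((cdist(a, b) < cutoff).sum())
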