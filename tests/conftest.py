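import numpy as np
import pytest
from scipy.spatial.distance import cdist

from stygovector import CommunitySpec, simulate_community


@pytest.fixture(scope="session")
def euclidean_config():
    """Planar points and their exact Euclidean distance matrix."""
    rng = np.random.default_rng(42)
    pts = rng.normal(size=(12, 2))
    return pts, cdist(pts, pts)


@pytest.fixture(scope="session")
def three_group_community():
    """A moderately separated 3-group community table with metadata."""
    counts, meta = simulate_community(
        CommunitySpec(groups=(("a", 5), ("b", 5), ("c", 5)), n_taxa=30,
                      depth_mean=1000, effect_size=1.0, seed=2)
    )
    return counts, meta
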