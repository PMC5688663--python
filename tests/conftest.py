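import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

sys.path.insert(0, str(Path(__file__).parent))  # for _oracles

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_atlas():
    """Compact orthogonal atlas: 5 cell types + 2 controls, 2 sources."""
    from xcellkit.atlas import generate_atlas

    return generate_atlas(
        n_cell_types=5, n_sources=2, genes_per_signature=20, n_genes=600,
        samples_per_type=4, seed=11,
    )


@pytest.fixture(scope="session")
def overlap_atlas():
    """Atlas with one related pair (50% marker overlap) for spillover tests."""
    from xcellkit.atlas import generate_atlas

    return generate_atlas(
        n_cell_types=5, n_sources=2, genes_per_signature=20, n_genes=600,
        samples_per_type=4, marker_overlap={("CT01", "CT02"): 0.5}, seed=11,
    )


@pytest.fixture(scope="session")
def hierarchy_atlas():
    """Atlas with a parent/child pair (CT02 is a child of CT01)."""
    from xcellkit.atlas import generate_atlas

    return generate_atlas(
        n_cell_types=4, n_sources=2, genes_per_signature=15, n_genes=400,
        samples_per_type=3, parent_map={"CT02": "CT01"}, seed=5,
    )


@pytest.fixture(scope="session")
def small_signatures(small_atlas):
    from xcellkit.signatures import learn_signatures

    sig_set, _ = learn_signatures(small_atlas)
    return sig_set


@pytest.fixture(scope="session")
def small_params(small_atlas, small_signatures):
    from xcellkit.calibration import learn_params

    return learn_params(small_atlas, small_signatures)


@pytest.fixture
def tiny_expr():
    """A 6-gene, 3-sample expression matrix with distinct per-sample ranks."""
    rng = np.random.default_rng(3)
    return pd.DataFrame(
        rng.uniform(1.0, 100.0, size=(6, 3)),
        index=[f"G{i}" for i in range(1, 7)],
        columns=["s1", "s2", "s3"],
    )
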