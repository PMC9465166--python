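import numpy as np
import pytest

import herbscreen as hs


@pytest.fixture
def tiny_compounds() -> hs.CompoundSet:
    return hs.CompoundSet(
        [
            hs.LabeledCompound("c1", "CCc1ccccc1", hs.ACTIVE),
            hs.LabeledCompound("c2", "CCO", hs.ACTIVE),
            hs.LabeledCompound("c3", "C1CCCCC1", hs.INACTIVE),
        ]
    )


@pytest.fixture
def small_world():
    """A small but complete synthetic world for pipeline-level tests."""
    spec = hs.SyntheticSpec(
        seed=11,
        n_active=60,
        n_inactive=20,
        n_herbs=120,
        n_candidates=12,
        n_hepato_like=6,
        n_enriched=9,
        n_enriched_hepato_like=6,
        planted_degree=12,
    )
    compounds = hs.generate_compounds(spec)
    herbs = hs.generate_herbs(spec)
    edges = hs.generate_edges(spec, compounds, herbs)
    return spec, compounds, herbs, edges


@pytest.fixture
def separable_xy():
    """Two well-separated Gaussian clouds (d' = 4), n = 400."""
    rng = np.random.default_rng(42)
    n, d = 400, 5
    X = rng.normal(0, 1, (n, d))
    X[n // 2:, 0] += 4.0  # all separation on one axis

    y = np.r_[np.zeros(n // 2), np.ones(n // 2)].astype(int)
    return X, y
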