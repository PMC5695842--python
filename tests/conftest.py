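import numpy as np
import pandas as pd
import pytest

from ecobaci import SyntheticConfig, TaxonCountMatrix, simulate_dataset


def make_matrix(counts, **meta_overrides):
    """Small TaxonCountMatrix builder for hand-crafted tests.

    ``counts``: dict taxon -> list of values.  Metadata defaults to a single
    bulk design cell; override any column with a list or scalar.
    """
    counts = pd.DataFrame(counts, dtype=float)
    n = len(counts)
    meta = {
        "sample_id": [f"s{i:03d}" for i in range(n)],
        "location": ["L01"] * n,
        "treatment": ["control"] * n,
        "habitat": ["lawn"] * n,
        "occasion": ["pre"] * n,
        "sample_type": ["bulk"] * n,
    }
    for key, val in meta_overrides.items():
        meta[key] = [val] * n if np.isscalar(val) else list(val)
    return TaxonCountMatrix(counts, pd.DataFrame(meta))


@pytest.fixture(scope="session")
def default_dataset():
    """One draw from the generator at its study-design defaults."""
    return simulate_dataset(SyntheticConfig(seed=7))


@pytest.fixture(scope="session")
def small_null_config():
    """A light config (few taxa, one post occasion) with no treatment effect,
    used by Monte-Carlo tests that re-simulate many times."""
    return SyntheticConfig(
        seed=11,
        n_taxa=8,
        occasions_bulk=("pre", "post1"),
        n_pitfall_locations=0,
        n_pitfall_late_locations=0,
        n_dirty_pitfall=0,
    )


@pytest.fixture(scope="session")
def small_bulk_pooled(small_null_config):
    _, pooled = simulate_dataset(small_null_config)
    return pooled.select((pooled.meta["sample_type"] == "bulk").to_numpy())
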