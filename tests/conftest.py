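import dendropy
import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from divfacets import Grid, LandscapeConfig, TraitTable


@pytest.fixture
def small_config():
    return LandscapeConfig(n_rows=8, n_cols=8, n_species=12, seed=7)


@pytest.fixture
def toy_tree():
    return dendropy.Tree.get(data="((A:1.0,B:1.0):1.0,C:2.0);", schema="newick")


@pytest.fixture
def toy_grid():
    return Grid(n_rows=3, n_cols=4, cell_size_km=5.0)


@pytest.fixture
def square_traits():
    """Four species at the corners of the unit square in a 2-trait space."""
    return TraitTable(
        pd.DataFrame(
            {"t1": [0.0, 1.0, 1.0, 0.0], "t2": [0.0, 0.0, 1.0, 1.0]},
            index=["a", "b", "c", "d"],
        )
    )
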