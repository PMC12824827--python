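import numpy as np
import pandas as pd
import pytest

from betashift.panels import CommunityPanel, TraitBlock, TraitDatabase
from betashift.simulate import SimConfig, generate_metacommunity


@pytest.fixture(scope="session")
def small_dataset():
    """Two-basin simulated dataset shared across read-only tests."""
    cfg = SimConfig(
        n_basins=2, sites_per_basin=6, years_per_basin=8, n_taxa_pool=60, seed=42
    )
    panels, metadata, traits, truth = generate_metacommunity(cfg)
    return {"config": cfg, "panels": panels, "metadata": metadata,
            "traits": traits, "truth": truth}


@pytest.fixture
def tiny_trait_db():
    """Hand-built trait database with two blocks and a known hierarchy.

    sp_a, sp_b are congeners in genus gA (family fX); sp_c sits alone in gB.
    sp_miss (genus gA) has no data of its own; sp_lost (genus gC, family fZ)
    can resolve nothing.  Genus-level row gA carries its own entry.
    """
    blocks = [
        TraitBlock("feed", ["m0", "m1"], "ten_point", "biological"),
        TraitBlock("sapro", ["m0", "m1", "m2"], "ten_point", "ecological"),
    ]
    cols = ["feed::m0", "feed::m1", "sapro::m0", "sapro::m1", "sapro::m2"]
    values = pd.DataFrame(
        {
            "sp_a": [10.0, 0.0, 3.0, 3.0, 4.0],
            "sp_b": [0.0, 10.0, 2.0, 2.0, 6.0],
            "sp_c": [5.0, 5.0, 0.0, 0.0, 10.0],
            "sp_miss": [np.nan] * 5,
            "sp_lost": [np.nan] * 5,
            "gA": [2.0, 8.0, np.nan, np.nan, np.nan],
        },
        index=cols,
    ).T
    hierarchy = pd.DataFrame(
        {
            "genus": ["gA", "gA", "gB", "gA", "gC", ""],
            "family": ["fX", "fX", "fX", "fX", "fZ", "fX"],
            "order": ["oQ", "oQ", "oQ", "oQ", "oZ", "oQ"],
        },
        index=["sp_a", "sp_b", "sp_c", "sp_miss", "sp_lost", "gA"],
    )
    return TraitDatabase(blocks, values, hierarchy)


@pytest.fixture
def toy_panel():
    abundance = np.zeros((3, 2, 3))
    abundance[0] = [[3.0, 0.0, 1.0], [1.0, 2.0, 0.0]]
    abundance[1] = [[3.0, 1.0, 1.0], [1.0, 2.0, 1.0]]
    abundance[2] = [[2.0, 1.0, 2.0], [1.0, 3.0, 1.0]]
    return CommunityPanel(
        "b1", ["s1", "s2"], [2000, 2001, 2002], ["t1", "t2", "t3"], abundance
    )
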