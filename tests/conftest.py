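"""Shared fixtures: small seeded synthetic worlds for each test family."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from hydrotraits import SynthConfig, generate_dataset
from hydrotraits.datatypes import TRAITS, TraitTable


@pytest.fixture(scope="session")
def small_dataset():
    """A small but complete synthetic world (72 species, 400 plots)."""
    cfg = SynthConfig(
        seed=7,
        n_families=6,
        genera_per_family=3,
        species_per_genus=4,
        n_plots=400,
        trees_per_plot=20,
    )
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def default_dataset():
    """The default study conditions (200 species, 2000 plots)."""
    return generate_dataset(SynthConfig(seed=1))


@pytest.fixture()
def toy_taxonomy():
    """Two genera in one family plus a second family, 7 species."""
    return pd.DataFrame(
        {
            "species": [f"Alpha sp{i}" for i in range(1, 4)]
            + [f"Beta sp{i}" for i in range(1, 3)]
            + [f"Gamma sp{i}" for i in range(1, 3)],
            "genus": ["Alpha"] * 3 + ["Beta"] * 2 + ["Gamma"] * 2,
            "family": ["Famone"] * 5 + ["Famtwo"] * 2,
            "functional_group": ["BD"] * 3 + ["BE"] * 2 + ["NC"] * 2,
        }
    )


def make_trait_table(values: dict[str, dict[str, float]]) -> TraitTable:
    """Build a TraitTable from {species: {trait: value}} (NaN = missing)."""
    df = pd.DataFrame.from_dict(values, orient="index").reindex(
        index=list(values), columns=list(TRAITS)
    )
    df.index.name = "species"
    prov = df.where(df.isna(), "observed").where(df.notna())
    return TraitTable(df.astype(float), prov)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
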