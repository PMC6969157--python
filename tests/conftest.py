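import numpy as np
import pandas as pd
import pytest

from fishp import synthetic_data as sd


@pytest.fixture(scope="session")
def small_config():
    return sd.SynthConfig(n_species=24, n_orders=6, n_countries=4,
                          year_range=(1995, 2010), wild_plateau_year=2002,
                          aquaculture_takeoff_year=2000, seed=11)


@pytest.fixture(scope="session")
def small_tables(small_config):
    return sd.generate_all(small_config)


@pytest.fixture(scope="session")
def degenerate_config():
    """Zero-variance configuration: every random stage collapses."""
    return sd.SynthConfig(
        n_species=9, n_orders=3, n_countries=2, year_range=(2000, 2003),
        order_cv=0.0, species_cv=0.0, thin_fraction=0.0, dry_fraction=0.0,
        records_per_species=2, pue_sigma=0.0, pue_per_group=1,
        other_invert_share=0.0, seed=7)


@pytest.fixture(scope="session")
def degenerate_tables(degenerate_config):
    return sd.generate_all(degenerate_config)


@pytest.fixture
def rng():
    return np.random.default_rng(123)


@pytest.fixture
def tiny_production():
    """Three hand-written records with known weights."""
    return pd.DataFrame({
        "year": [2000, 2000, 2001],
        "country": ["A", "B", "A"],
        "species": ["sp1", "sp2", "sp1"],
        "order": ["o1", "o1", "o1"],
        "group": ["finfish", "finfish", "finfish"],
        "environment": ["marine", "freshwater", "marine"],
        "source": ["capture", "aquaculture", "capture"],
        "weight": [1.0, 2.0, 4.0],
    })


@pytest.fixture
def tiny_concentrations():
    return pd.DataFrame({
        "species": ["sp1", "sp1", "sp2", "sp2", "sp3"],
        "order": ["o1"] * 5,
        "group": ["finfish"] * 5,
        "value": [0.004, 0.006, 0.005, 0.007, 0.0055],
        "basis": ["wet"] * 5,
        "moisture": [np.nan] * 5,
        "origin": ["wild", "raised", "raised", "raised", "wild"],
    })
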