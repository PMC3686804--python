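import numpy as np
import pandas as pd
import pytest

import cbctrend as ct

TOY_CSV = """circle_id,latitude,longitude,coast_distance_km,year,species,count,effort_hours,boat_used
C1,48.5,-123.1,5,2000,WEST,90,10,0
C1,48.5,-123.1,5,2000,CLARK,10,10,0
C1,48.5,-123.1,5,2000,UNID,20,10,0
"""


@pytest.fixture
def toy_csv(tmp_path):
    path = tmp_path / "toy.csv"
    path.write_text(TOY_CSV)
    return path


@pytest.fixture(scope="session")
def default_sim():
    """One realisation of the shipped default scenario (read-only)."""
    return ct.simulate_dataset(ct.default_config(seed=42))


@pytest.fixture(scope="session")
def small_fit():
    """A small, seeded single-region fit shared by read-only tests."""
    cfg = ct.recovery_config(-5.0, n_circles=6, mean_count=40, seed=2,
                             sigma_circle=0.8)
    cfg.n_years = 20
    dataset, truth = ct.simulate_dataset(cfg)
    dataset, _ = ct.filter_circles(dataset)
    model = ct.CircleCountModel(dataset)
    results = model.fit(ct.MCMCConfig(n_chains=2, burn_in=2000,
                                      n_samples=1500, seed=5))
    return cfg, truth, results
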