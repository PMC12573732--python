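"""Shared fixtures: one clean mid-sized cross reused across modules."""

import numpy as np
import pandas as pd
import pytest

from aphidqtl import simulate


@pytest.fixture(scope="session")
def clean_cross():
    """Error-free, fully typed 192-clone cross with 30 markers/chromosome."""
    cfg = simulate.CrossConfig(
        n_f2=192, n_markers=30, error_rate=0.0, missing_rate=0.0, seed=11
    )
    founders = simulate.simulate_founders(cfg)
    genotypes, truth = simulate.simulate_f2_genotypes(founders, cfg)
    return cfg, founders, genotypes, truth


@pytest.fixture(scope="session")
def marker_info(clean_cross):
    _cfg, founders, _geno, _truth = clean_cross
    return founders.markers.set_index("marker")


def make_founders_from_map(markers: pd.DataFrame) -> simulate.Founders:
    """Founders object for a hand-constructed marker table."""
    m = len(markers)
    f0 = np.empty((4, m), dtype=np.int8)
    f0[0] = f0[1] = simulate.AA
    f0[2] = f0[3] = simulate.BB
    f1 = np.full((2, m), simulate.AB, dtype=np.int8)
    markers = markers.copy()
    for col in ("uninformative", "f0_het", "distorted"):
        if col not in markers:
            markers[col] = False
    return simulate.Founders(markers=markers, f0=f0, f1=f1)
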