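"""Shared fixtures: small hand-built tables and cached synthetic panels."""

import numpy as np
import pandas as pd
import pytest

from shiftmap import (
    ShiftTable,
    default_registry,
    fit_all_pairs,
    serum_panel_spec,
    simulate_shift_table,
)


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture()
def toy_table():
    """Four samples, three correlated systems, one missing value."""
    df = pd.DataFrame(
        {
            "valine_CH3": [0.9860, 0.9900, 0.9840, 0.9880],
            "lactate_CH3": [1.3310, 1.3390, 1.3270, np.nan],
            "alanine_CH3": [1.4780, 1.4820, 1.4760, 1.4800],
        },
        index=pd.Index(["s1", "s2", "s3", "s4"], name="sample"),
    )
    return ShiftTable(df, precision=4)


@pytest.fixture(scope="session")
def serum_like_table():
    """Moderate-size serum-like panel shared across read-only tests."""
    return simulate_shift_table(serum_panel_spec(), 400, seed=11)


@pytest.fixture(scope="session")
def serum_like_models(serum_like_table):
    return fit_all_pairs(serum_like_table, min_n=50)
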