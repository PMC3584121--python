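"""Shared fixtures: everything is generated, no network or external data."""

from __future__ import annotations

import numpy as np
import pytest

from subnucpred.extract import ExtractionConfig, extract_blocks
from subnucpred.properties import load_property_table
from subnucpred.synthetic import default_fixture, make_profiles, sample_dataset


@pytest.fixture(scope="session")
def table():
    return load_property_table()


@pytest.fixture(scope="session")
def small_ds():
    """3 classes x 8 sequences, high separation: cheap end-to-end material."""
    profiles = make_profiles(3, "high", seed=11)
    return sample_dataset(profiles, 8, seed=12)


@pytest.fixture(scope="session")
def fixture_data():
    """The default acceptance fixture with the acceptance-scale feature
    blocks (laac + gd) and single-label class vector."""
    ds = default_fixture()
    blocks, names = extract_blocks(ds, ExtractionConfig(methods=("laac", "gd")))
    y = np.array([next(iter(r.labels)) for r in ds.records])
    return ds, blocks, names, y
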