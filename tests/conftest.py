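"""Shared fixtures: small simulated datasets and fixture directories."""

import numpy as np
import pytest
from hypothesis import settings

import clinepar as cp

settings.register_profile("ci", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_sim():
    """Two species, both tissues, 400 genes; planted effects at defaults."""
    cfg = cp.SimConfig(n_genes=400, species_list=("A", "B"), seed=11)
    return cfg, cp.simulate_dataset(cfg)


@pytest.fixture(scope="session")
def three_species_sim():
    cfg = cp.SimConfig(n_genes=300, seed=23)
    return cfg, cp.simulate_dataset(cfg)


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    """An emitted on-disk fixture for reader and pipeline tests."""
    out = tmp_path_factory.mktemp("fixture")
    cfg = cp.SimConfig(n_genes=300, seed=7)
    manifest = cp.emit_fixture(cfg, out)
    return cfg, out, manifest


@pytest.fixture(scope="session")
def de_tables_pair(small_sim):
    """Per-species DE tables for the AG of the small two-species dataset."""
    _, res = small_sim
    return {
        sp: cp.de_pipeline(res.datasets[sp], sp, "AG", "Panama", "Maine")
        for sp in ("A", "B")
    }
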