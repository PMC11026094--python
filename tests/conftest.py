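"""Shared fixtures: one default synthetic study reused across test modules."""

import numpy as np
import pytest

from tethym.sc_core import aggregate_subfamilies, normalize_lognorm, qc_filter_cells
from tethym.synthetic import (
    SimulationConfig,
    simulate_regulatory_fixtures,
    simulate_single_cell_dataset,
    simulate_te_annotation,
)


@pytest.fixture(scope="session")
def default_config():
    return SimulationConfig(seed=7)


@pytest.fixture(scope="session")
def annotation(default_config):
    ann, truth = simulate_te_annotation(default_config)
    return ann, truth


@pytest.fixture(scope="session")
def sc_dataset(default_config, annotation):
    """QC-filtered, normalized, subfamily-aggregated default dataset."""
    ann, _ = annotation
    adata = simulate_single_cell_dataset(default_config, ann)
    adata, _ = qc_filter_cells(adata)
    adata = normalize_lognorm(adata)
    return aggregate_subfamilies(adata, ann)


@pytest.fixture(scope="session")
def regulatory(default_config, annotation):
    ann, _ = annotation
    cfg = SimulationConfig(
        seed=default_config.seed,
        planted_tf_te_pairs=(("TFA", "L1syn-1", 0.5),),
    )
    return simulate_regulatory_fixtures(ann, cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240101)
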