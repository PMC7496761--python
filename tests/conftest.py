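"""Shared fixtures: small synthetic worlds and one end-to-end roster run.

The end-to-end fixture runs the full pipeline once per session on a 1° world
(the package's test-scale world; the library default is 0.5°) and is shared by
the model-quality and change-direction tests, so the expensive fitting happens
exactly once.
"""

from __future__ import annotations

import numpy as np
import pytest

from stacksdm._seeding import derive_seed
from stacksdm.config import RunConfig, WorldConfig
from stacksdm.grid import GridSpec
from stacksdm.synthetic import ScenarioConfig, make_scenarios

#: Master seed for the session-scoped end-to-end run.
E2E_SEED = 3


@pytest.fixture(scope="session")
def small_world():
    """Coarse 4° global world — fast enough for per-module tests."""
    cfg = ScenarioConfig(seed=7, grid=GridSpec(45, 90, -180.0, -90.0, 4.0))
    return make_scenarios(cfg)


@pytest.fixture(scope="session")
def small_present(small_world):
    return small_world["present"]


@pytest.fixture(scope="session")
def world_1deg():
    """1° world matching the end-to-end run's seed lineage."""
    cfg = ScenarioConfig(
        seed=derive_seed(E2E_SEED, "world"), grid=GridSpec(180, 360, -180.0, -90.0, 1.0)
    )
    return make_scenarios(cfg)


@pytest.fixture(scope="session")
def e2e_run(tmp_path_factory):
    """Full pipeline run (all stages, all families, five replicates) at 1°."""
    from stacksdm.pipeline import run

    outdir = tmp_path_factory.mktemp("e2e")
    cfg = RunConfig(seed=E2E_SEED, world=WorldConfig(n_rows=180, n_cols=360, cell_size=1.0))
    run(cfg, outdir)
    return outdir


@pytest.fixture(scope="session")
def e2e_seed():
    return E2E_SEED


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
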