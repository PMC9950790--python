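"""Shared fixtures: desk-scale synthetic universes and pipeline runs.

The full planted-signal pipeline is expensive (tens of seconds per master
seed), so it runs once per session and is shared by the ensemble, vote and
recovery tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from synergyscreen.pipeline import run_synthetic_pipeline
from synergyscreen.synthetic_data import UniverseSpec, generate_universe

#: master seeds of the multi-seed recovery check (fixed, spans the suite)
RECOVERY_SEEDS = list(range(1, 11))


@pytest.fixture(scope="session")
def toy_pipeline():
    """One full pipeline run (R=50, planted S_Pathway/S_np signal), seed 1."""
    return run_synthetic_pipeline(master_seed=RECOVERY_SEEDS[0])


@pytest.fixture(scope="session")
def screen_runs(toy_pipeline):
    """Feature-screen reports for the ten recovery master seeds."""
    out = {RECOVERY_SEEDS[0]: toy_pipeline.screen}
    for seed in RECOVERY_SEEDS[1:]:
        out[seed] = run_synthetic_pipeline(seed, train_ensemble=False).screen
    return out


@pytest.fixture(scope="session")
def small_universe():
    """A tiny universe for I/O and featurization tests (6 drugs, 20 targets)."""
    spec = UniverseSpec(n_drugs=6, n_targets=20, n_go_terms=15, n_pathways=6,
                        ppi_nodes=40, fingerprint_len=64, seed=7)
    return generate_universe(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
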