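from __future__ import annotations

import numpy as np
import pytest

import massdiv as md


@pytest.fixture(scope="session")
def small_study():
    """A compact 2x5x2 synthetic study reused across tests."""
    return md.simulate_study(n_formulas=80, seed=11)


@pytest.fixture(scope="session")
def small_pipeline(small_study):
    cfg = md.PipelineConfig(n_perm=500, seed=11)
    return md.run_pipeline(small_study.spectra, small_study.replicate_map,
                           small_study.metadata, cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
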