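import numpy as np
import pytest

from flimglia import decay_fit, phantom, pipeline
from flimglia.tcspc_io import RunConfig

import helpers


@pytest.fixture(scope="session")
def culture_fovs():
    """Eight small culture-preset FOVs shared by the pipeline tests."""
    cfg = helpers.tiny_culture_config()
    return pipeline.simulate_fovs(cfg, 8, seed=3)


@pytest.fixture(scope="session")
def culture_maps(culture_fovs):
    """Fitted parameter maps for the shared FOVs (computed once)."""
    return pipeline.fit_fovs(culture_fovs, RunConfig(rng_seed=3))


@pytest.fixture(scope="session")
def fbm_experiment(culture_fovs, culture_maps):
    """A complete small FBM detection experiment (6 train + 2 test FOVs)."""
    return pipeline.run_detection_experiment(
        culture_fovs[:6], culture_fovs[6:], RunConfig(rng_seed=3),
        mode="fbm", seed=3,
        train_maps=culture_maps[:6], test_maps=culture_maps[6:])
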