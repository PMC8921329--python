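"""Shared fixtures: phantoms and pipeline runs are expensive, so build once."""

from __future__ import annotations

import numpy as np
import pytest

from pli_incline import PhantomSpec, PipelineConfig, generate_phantom, run_pipeline


@pytest.fixture(scope="session")
def default_phantom():
    """The default 512x512 noise-free phantom (seed 0)."""
    return generate_phantom(PhantomSpec(seed=0))


@pytest.fixture(scope="session")
def pipeline_iv(default_phantom):
    """Full pipeline run (scenario iv) on the default phantom."""
    return run_pipeline(
        maps=default_phantom.maps, config=PipelineConfig(scenario="iv", seed=0)
    )


@pytest.fixture(scope="session")
def small_phantom():
    """A 128x128 phantom for fast I/O and CLI tests."""
    return generate_phantom(PhantomSpec(shape=(128, 128), seed=3))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
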