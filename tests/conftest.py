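"""Shared fixtures: generated datasets at desk and toy scale."""

from __future__ import annotations

import numpy as np
import pytest

from aeromode.generate import GeneratorConfig, generate_dataset


@pytest.fixture(scope="session")
def default_dataset():
    """The default 405-image dataset at 128x128, seed 1, with ground truth."""
    return generate_dataset(GeneratorConfig(seed=1))


@pytest.fixture(scope="session")
def small_dataset():
    """A cheap 32x32 dataset for IO/classification plumbing tests."""
    return generate_dataset(GeneratorConfig(seed=5, image_height=32, image_width=32))


@pytest.fixture(scope="session")
def noiseless_free_dataset():
    """Noiseless, control-free run: purely autonomous planted dynamics."""
    cfg = GeneratorConfig(seed=11, noise_sd=0.0, planted_control=np.zeros((8, 3)))
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def noiseless_default_dataset():
    """Noiseless run with the default (severity-driven) control operator."""
    return generate_dataset(GeneratorConfig(seed=11, noise_sd=0.0))
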