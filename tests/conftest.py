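"""Shared fixtures: toy structures and the expensively trained pipeline models.

The trained-model fixtures are session-scoped so that training happens once
per test run and is shared between the unit tests that need a trained model
and the acceptance checks.
"""

from __future__ import annotations

import numpy as np
import pytest

from vqfold.geometry import build_ideal_backbone, random_rotation
from vqfold.synthetic import ToyDatasetConfig, make_toy_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def helix20():
    return build_ideal_backbone("H" * 20)


@pytest.fixture
def strand20():
    return build_ideal_backbone("E" * 20)


@pytest.fixture
def toy_fold(rng):
    """A small mixed-topology backbone with mild coordinate jitter."""
    from vqfold.synthetic import build_toy_backbone
    return build_toy_backbone("HHHHHHHHCCCEEEEECCHHHHHHHHCCEEEEE", 0.2, rng)


@pytest.fixture
def toy_dataset_small():
    return make_toy_dataset(ToyDatasetConfig(n_structures=4, seed=7))


def rigid_copy(s, rng):
    rot = random_rotation(rng)
    trans = rng.normal(scale=20.0, size=3)
    return s.transformed(rot, trans), rot, trans


@pytest.fixture(scope="session")
def reconstruction_run():
    """Miniature VQ-VAE benchmark (trained once per session)."""
    from vqfold.protocols import reconstruction_benchmark
    return reconstruction_benchmark(seed=0)


@pytest.fixture(scope="session")
def overfit_run():
    """Five-structure memorization run (trained once per session)."""
    from vqfold.protocols import overfit_benchmark
    return overfit_benchmark(seed=0)


@pytest.fixture(scope="session")
def hinge_run():
    """Two-state hinge conditional-sampling pipeline (trained once)."""
    from vqfold.protocols import hinge_conditional_benchmark
    return hinge_conditional_benchmark(seed=0)
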