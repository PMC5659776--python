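"""Shared fixtures: phantom training sets and fitted segmenters.

Model fitting is session-scoped because the tendon and sheath segmenters are
reused across the pipeline and acceptance tests; everything is seeded so the
suite is deterministic.
"""

import logging

import numpy as np
import pytest

from atasm.phantom import PhantomSpec, generate_phantom, generate_training_set
from atasm.pipeline import AtasmSegmenter

logging.getLogger("atasm").setLevel(logging.ERROR)

TRAIN_SEED = 42
N_TRAIN = 20


@pytest.fixture(scope="session")
def training_set():
    return generate_training_set(N_TRAIN, seed=TRAIN_SEED)


@pytest.fixture(scope="session")
def training_images(training_set):
    return [t[0] for t in training_set]


@pytest.fixture(scope="session")
def training_tendons(training_set):
    return [t[1]["tendon"] for t in training_set]


@pytest.fixture(scope="session")
def training_sheaths(training_set):
    return [t[1]["sheath"] for t in training_set]


@pytest.fixture(scope="session")
def tendon_segmenter(training_images, training_tendons):
    seg = AtasmSegmenter(target="tendon", random_state=0)
    seg.fit(training_images, training_tendons)
    return seg


@pytest.fixture(scope="session")
def sheath_segmenter(training_images, training_sheaths):
    seg = AtasmSegmenter(target="sheath", random_state=0)
    seg.fit(training_images, training_sheaths)
    return seg


@pytest.fixture(scope="session")
def speckled_phantom():
    """One held-out speckled clear-boundary phantom with its ground truth."""
    image, truth, group = generate_phantom(PhantomSpec(rng_seed=777))
    return image, truth, group


@pytest.fixture(scope="session")
def clean_phantom():
    """Noise-free, unperturbed phantom (exact analytic region intensities)."""
    spec = PhantomSpec(speckle_strength=0.0, perturb_amplitudes=(0.0, 0.0),
                       rng_seed=1)
    image, truth, group = generate_phantom(spec)
    return image, truth, group


def circle_points(n=40, r=50.0, center=(0.0, 0.0)):
    theta = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return np.stack([center[0] + r * np.cos(theta),
                     center[1] + r * np.sin(theta)], axis=1)
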