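"""Shared fixtures: small scenes and a small trained cascade.

The session-scoped cascade is deliberately tiny (few stages, small training
set) so the whole suite stays fast; the full-size study runs only in the
acceptance tests.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from stomapore.cascade import CascadeConfig, train_cascade
from stomapore.synth import SceneSpec, make_training_set, render_scene

SMALL_SPEC = SceneSpec(width_px=512, height_px=512, n_stomata=4, seed=7)


@pytest.fixture(scope="session")
def small_scene():
    """One rendered scene plus its ground truth."""
    return render_scene(SMALL_SPEC)


@pytest.fixture(scope="session")
def small_training_set():
    return make_training_set(SceneSpec(seed=42), n_pos=60, n_neg=30)


@pytest.fixture(scope="session")
def small_cascade(small_training_set):
    positives, negatives = small_training_set
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # pool exhaustion is expected here
        return train_cascade(
            positives, negatives, CascadeConfig(n_stages=3, seed=3)
        )


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
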