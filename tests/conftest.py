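"""Shared fixtures: small phantoms and cohorts generated at test time."""

from __future__ import annotations

import numpy as np
import pytest

from ebusml.synthetic import PhantomSpec, generate_phantom

# smaller canvas for unit tests: same probe/ring/lesion geometry, less padding
SMALL = dict(image_size_px=320, lesion_radius_mm=(9.0, 11.0))


@pytest.fixture(scope="session")
def benign_phantom():
    return generate_phantom(PhantomSpec(class_label=0, rng_seed=42, **SMALL))


@pytest.fixture(scope="session")
def malignant_phantom():
    return generate_phantom(PhantomSpec(class_label=1, rng_seed=43, **SMALL))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
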