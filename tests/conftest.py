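import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def sample_disk(rng, n, radius, center=(0.0, 0.0)):
    """Uniform points on a disk (shared fixture helper)."""
    r = radius * np.sqrt(rng.uniform(size=n))
    theta = rng.uniform(0, 2 * np.pi, size=n)
    return np.asarray(center) + np.column_stack(
        [r * np.cos(theta), r * np.sin(theta)])
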