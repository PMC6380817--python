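import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import greymarkov as gm

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

# the study's custom, expert-chosen ratio-state boundaries
STUDY_BOUNDARIES = (0.9491, 0.9919, 1.0133, 1.0561)


@pytest.fixture
def constant_series():
    return gm.ObservedSeries(np.arange(2005, 2011), np.full(6, 7.0))


@pytest.fixture
def declining_series():
    """Deterministic declining series of study-like shape (noise-free)."""
    series, _, _ = gm.generate(gm.GeneratorConfig(noise_sd=0.0, seed=0))
    return series


@pytest.fixture
def study_partition():
    return gm.partition_states(
        [1.0], method="custom", custom_boundaries=STUDY_BOUNDARIES
    )


def normal_equations_oracle(values):
    """Closed-form 2x2 normal-equations solve for (a, u), written
    independently of the package's least-squares path."""
    x1 = [sum(values[: i + 1]) for i in range(len(values))]
    z = [0.5 * (x1[k] + x1[k - 1]) for k in range(1, len(values))]
    y = list(values[1:])
    n = len(z)
    szz = sum(v * v for v in z)
    sz = sum(z)
    szy = sum(zi * yi for zi, yi in zip(z, y))
    sy = sum(y)
    # minimise sum (y_k + a z_k - u)^2: normal equations in (a, u)
    det = szz * n - sz * sz
    a = (sz * sy - n * szy) / det
    u = (sy + a * sz) / n
    return a, u


def random_positive_series(rng, n=None):
    n = n or rng.integers(5, 12)
    labels = np.arange(2000, 2000 + n)
    values = rng.uniform(0.5, 100.0, n)
    return gm.ObservedSeries(labels, values)
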