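import numpy as np
import pandas as pd
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_long_table(rng, n_clusters=9, slope=0.0, icept_sd=0.5, noise_sd=0.3,
                    slope_sd=0.0, intensities=(45.0, 65.0, 85.0, 105.0)):
    """Random-intercept (optionally random-slope) clustered regression data."""
    x = np.tile(np.asarray(intensities, dtype=float), n_clusters)
    g = np.repeat(np.arange(n_clusters), len(intensities))
    a = rng.normal(0.0, icept_sd, n_clusters)
    b = slope + (rng.normal(0.0, slope_sd, n_clusters) if slope_sd > 0 else 0.0)
    b = np.broadcast_to(b, (n_clusters,))
    y = a[g] + b[g] * x + rng.normal(0.0, noise_sd, x.size)
    return pd.DataFrame(
        dict(subject_id=[f"s{i:03d}" for i in g], intensity=x, value=y)
    )


@pytest.fixture
def long_table(rng):
    return make_long_table(rng)
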