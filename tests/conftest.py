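import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import ovaclass as ov

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_data() -> ov.LabeledExpressionMatrix:
    """Desk-scale synthetic cohort: 300 genes, 10 samples per class."""
    return ov.generate_dataset(
        ov.SyntheticConfig(
            n_genes=300, n_per_class=10, de_fraction=0.1, effect_size=2.0, seed=3
        )
    )


@pytest.fixture(scope="session")
def separable_1d():
    """Two trivially separable 1-D classes at -10 and +10, 5 samples each."""
    X = np.array([[-10.2], [-10.1], [-10.0], [-9.9], [-9.8],
                  [9.8], [9.9], [10.0], [10.1], [10.2]])
    y = np.array([0, 0, 0, 0, 0, 1, 1, 1, 1, 1])
    return X, y
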