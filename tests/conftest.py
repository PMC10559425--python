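import numpy as np
import pandas as pd
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_phenotypes():
    """Five birds with hand-checkable raw measurements."""
    return pd.DataFrame(
        {
            "bird_id": [f"b{i}" for i in range(1, 6)],
            "group": ["WL", "WL", "YY", "YY", "YW"],
            "dfc": [100.0, 105.0, 90.0, 95.0, 103.0],
            "bw_start": [1600.0, 1650.0, 1800.0, 1750.0, 1700.0],
            "bw_end": [1600.0, 1700.0, 1830.0, 1770.0, 1730.0],
            "total_egg_mass": [1400.0, 1500.0, 1100.0, 0.0, 1300.0],
            "test_days": [28, 28, 28, 28, 28],
        }
    )


@pytest.fixture
def small_counts():
    counts = pd.DataFrame(
        {
            "s1": [10, 0, 100, 7],
            "s2": [20, 5, 110, 0],
            "s3": [15, 2, 95, 3],
        },
        index=["g1", "g2", "g3", "g4"],
    )
    counts.index.name = "feature"
    return counts
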