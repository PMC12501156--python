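import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def relative_deviation(a, b, floor=1e-12):
    """Worst per-component relative deviation over components above floor."""
    a = np.asarray(a)
    b = np.asarray(b)
    mask = (a > floor) | (b > floor)
    if not mask.any():
        return 0.0
    return float(np.max(np.abs(a[mask] - b[mask]) / np.maximum(a[mask], b[mask])))
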