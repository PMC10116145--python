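import numpy as np
import pytest

from c3b import norms


@pytest.fixture(scope="session")
def models():
    return norms.builtin_models()


def sample_with_moments(n: int, mean: float, sd: float, rng: np.random.Generator) -> np.ndarray:
    """Draw n values, then rescale to the exact requested mean and SD."""
    x = rng.normal(size=n)
    x = (x - x.mean()) / x.std(ddof=1)
    return mean + sd * x
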