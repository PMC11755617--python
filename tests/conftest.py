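import numpy as np
import pytest

from mabscale.datasets import load_dataset


@pytest.fixture(scope="session")
def packaged():
    """The curated 25-antibody cross-species dataset."""
    return load_dataset("packaged")


@pytest.fixture(scope="session")
def schedule():
    """Standard single-dose sampling times (h)."""
    from mabscale.simulate import DEFAULT_SCHEDULE_H

    return np.asarray(DEFAULT_SCHEDULE_H, dtype=float)
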