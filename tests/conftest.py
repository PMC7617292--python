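import numpy as np
import pytest

import medgrowth as mg


@pytest.fixture(scope="session")
def default_trial():
    """One default-calibration synthetic trial (n=424, fixed seed)."""
    return mg.generate_dataset(mg.default_config(seed=20240424))


@pytest.fixture(scope="session")
def complete_trial():
    """A fully observed trial (retention 1 everywhere), fixed seed."""
    cfg = mg.default_config(seed=99, retention_t=(1.0,) * 5)
    return mg.generate_dataset(cfg)


@pytest.fixture(scope="session")
def big_trial():
    """A large trial for low-noise parameter-recovery checks."""
    return mg.generate_dataset(mg.default_config(n=5000, seed=7))


def monte_carlo_se(values):
    values = np.asarray(values, dtype=float)
    return values.std(ddof=1) / np.sqrt(len(values))
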