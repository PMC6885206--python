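import numpy as np
import pytest

from clustsig import SyntheticConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """300-gene cohort with 3 well-separated planted signature genes."""
    cfg = SyntheticConfig(
        n_samples=450, n_genes=300, n_signature_genes=3, shift=2.5,
        true_log_hr=float(np.log(5.0)), seed=5,
    )
    return generate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
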