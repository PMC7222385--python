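import numpy as np
import pytest

import sonoextract as sx


@pytest.fixture(scope="session")
def uae2_tpc_dataset():
    """Noiseless reference curves for the fastest sonicated TPC process."""
    return sx.reference_dataset("UAE2", "TPC")


@pytest.fixture(scope="session")
def noisy_generated():
    """One seeded noisy triplicate dataset from mid-range true parameters."""
    design = sx.SyntheticDesign(
        true_params=sx.WeibullArrheniusParams(5.09e-7, 43058.2, 0.529),
        equilibrium={5.0: 74.7, 15.0: 74.7, 25.0: 74.7},
        noise_sd=2.0,
        seed=42,
    )
    return sx.generate_extraction_dataset(design)


@pytest.fixture
def rng():
    return np.random.default_rng(7)
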