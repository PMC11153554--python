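import numpy as np
import pytest

from sgtm_cascade import CascadeConfig, SyntheticSpec, fit_cascade, make_polynomial_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def quartic_cascade_3l():
    """A 3-level quadratic cascade fitted on a generic 2-feature quartic surface.

    Session-scoped: several interpretability and equivalence tests probe the
    same fitted model.
    """
    ds, _ = make_polynomial_dataset(
        SyntheticSpec(n_samples=800, n_features=2, degree=4, noise_sd=0.0, seed=3)
    )
    return fit_cascade(ds, CascadeConfig(levels=3, degree=2, seed=1)), ds
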