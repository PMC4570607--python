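import numpy as np
import pytest

from splicemix import reference
from splicemix.params import GaussianMixtureParams, LMMMixtureParams


@pytest.fixture(scope="session")
def fmm_reference_params() -> GaussianMixtureParams:
    """The published 3-component pooled-replicate mixture estimate."""
    return reference.FMM_ESTIMATE


@pytest.fixture(scope="session")
def fmlmm_reference_params() -> LMMMixtureParams:
    """The published 3-component mixture-of-LMMs estimate."""
    return reference.FMLMM_ESTIMATE


@pytest.fixture(scope="session")
def separated_blobs():
    """Two far-apart spherical clusters: trivial ground truth for EM."""
    rng = np.random.default_rng(42)
    a = rng.normal([-10.0, -10.0], 1.0, size=(60, 2))
    b = rng.normal([10.0, 10.0], 1.0, size=(40, 2))
    pts = np.vstack([a, b])
    labels = np.repeat([0, 1], [60, 40])
    return pts, labels
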