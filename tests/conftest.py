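import numpy as np
import pytest

from edemascan import csfseg
from edemascan.phantom import (
    EdemaTrajectory,
    PhantomSpec,
    default_infarct,
    make_head_phantom,
    make_phantom_cohort,
)


@pytest.fixture(scope="session")
def default_phantom():
    """Default head phantom at standard noise, with an infarct."""
    spec = PhantomSpec(seed=3, infarct=default_infarct())
    vol, masks = make_head_phantom(spec)
    return spec, vol, masks


@pytest.fixture(scope="session")
def noiseless_phantom():
    spec = PhantomSpec(seed=3, noise_sd=0.0)
    vol, masks = make_head_phantom(spec)
    return spec, vol, masks


@pytest.fixture(scope="session")
def trained_classifier():
    """Small forest trained on four varied phantoms (shared across tests)."""
    specs = make_phantom_cohort(4, seed=2, infarct_frac=0.5)
    data = [make_head_phantom(s) for s in specs]
    clf = csfseg.train_csf_classifier(
        [(v, m["cranial"], m["csf"]) for v, m in data], seed=7, per_class_cap=3000
    )
    return clf


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
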