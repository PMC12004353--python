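import numpy as np
import pytest

from spectrocube import PhantomConfig, make_dataset, make_scan


@pytest.fixture(scope="session")
def tiny_cfg():
    """Small phantom for plumbing tests (not the desk-scale defaults)."""
    return PhantomConfig(
        grid=(10, 12), bands=24, n_classes=3, n_scans=6, n_subjects=3, seed=7
    )


@pytest.fixture(scope="session")
def tiny_scans(tiny_cfg):
    return make_dataset(tiny_cfg)


@pytest.fixture(scope="session")
def tiny_scan(tiny_cfg):
    return make_scan(tiny_cfg, "subjectX", scan_seed=42)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
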