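import numpy as np
import pytest

import kspace_design as kd


@pytest.fixture(scope="session")
def _session_train():
    spec = kd.PhantomSpec(N0=16, L=2, T=4)
    return kd.assemble_training_set(spec, w0=8)


@pytest.fixture()
def small_train(_session_train):
    """Desk-top fixture: 16x16 grid, 2 coils, 4 phantoms, 8x budget.

    Returns a fresh TrainingSet wrapper per test (datasets shared read-only)
    so tests can rebind the noise model without cross-contamination.
    """
    t = _session_train
    return kd.TrainingSet(
        datasets=t.datasets, noise=kd.NoiseModel(sigma=0.0, seed=0), w0=t.w0, N0=t.N0,
        split={k: list(v) for k, v in t.split.items()},
    )


@pytest.fixture(scope="session")
def ds16(_session_train):
    return _session_train.datasets[0]


@pytest.fixture(scope="session")
def single_coil_ds(ds16):
    """Single-coil (S = 1) version of the first phantom dataset."""
    img = kd.coil_combine(kd.ifft2c(ds16.s), ds16.maps)
    s = kd.fft2c(img[:, :, None])
    return kd.KSpaceDataset(s=s, maps=np.ones((16, 16, 1), dtype=complex), fov_mm=220.0, id="single")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
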