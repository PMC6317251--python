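import numpy as np
import pytest

import parenchymaseg as ps


@pytest.fixture(scope="session")
def clean_phantom():
    """Noise-free 128px two-lung phantom, no lesions."""
    spec = ps.default_spec(n_slices=4, slice_shape=(128, 128), noise_sigma=0.0, seed=1)
    return ps.generate_phantom(spec)


@pytest.fixture(scope="session")
def noisy_phantom():
    """128px phantom with realistic CT noise (sigma = 20 HU)."""
    spec = ps.default_spec(n_slices=4, slice_shape=(128, 128), noise_sigma=20.0, seed=2)
    return ps.generate_phantom(spec)


@pytest.fixture(scope="session")
def lesion_phantom():
    """Noise-free 256px phantom with one lesion fully interior to a lung."""
    size = 256
    spec = ps.default_spec(
        n_slices=4, slice_shape=(size, size), noise_sigma=0.0, seed=3,
        lesions=[ps.Lesion(center=(0.40 * size, 0.32 * size), radius=size / 16)],
    )
    return ps.generate_phantom(spec)


@pytest.fixture(scope="session")
def separable_patches():
    """A trivially separable patch dataset: LP near -850 HU, NLP near +40 HU."""
    rng = np.random.default_rng(0)
    n = 1200
    X = np.concatenate([
        rng.normal(-850.0, 20.0, (n // 2, 32, 32)),
        rng.normal(40.0, 20.0, (n // 2, 32, 32)),
    ])
    y = np.concatenate([np.ones(n // 2, dtype=int), np.zeros(n // 2, dtype=int)])
    perm = rng.permutation(n)
    return X[perm], y[perm]


@pytest.fixture(scope="session")
def tiny_trained_model(separable_patches):
    """A quickly trained classifier for pipeline tests."""
    X, y = separable_patches
    cfg = ps.default_config()
    cfg["epochs"] = 3
    model = ps.PatchNetClassifier(random_state=0, **cfg)
    model.fit(X[:800], y[:800])
    return model
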