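import numpy as np
import pytest

from eiaofs.preprocess import SpectraSet


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_spectra(rng):
    """10 samples x 12 bands, two classes, mild structure."""
    wavelengths = np.linspace(400.0, 900.0, 12)
    base = 0.3 + 0.2 * np.sin(wavelengths / 150.0)
    labels = np.array(["a"] * 5 + ["b"] * 5)
    reflectance = base + rng.normal(0, 0.02, size=(10, 12))
    reflectance[5:, 3] += 0.3  # class b offset
    return SpectraSet(
        wavelengths=wavelengths,
        reflectance=reflectance,
        labels=labels,
        sample_ids=np.array([f"s{i}" for i in range(10)]),
    )


@pytest.fixture
def tiny_benchmark():
    """Separable 2-class tabular data: 60 samples, 8 columns, 2 informative."""
    from eiaofs.synthetic import generate_fs_benchmark

    return generate_fs_benchmark(60, 8, 2, class_sep=4.0, seed=7)
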