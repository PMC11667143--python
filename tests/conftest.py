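import pytest

from mprkit import phantom


@pytest.fixture(scope="session")
def block_spec() -> phantom.PhantomSpec:
    """Noise-free block phantom matching the default validation conditions."""
    return phantom.PhantomSpec()


@pytest.fixture(scope="session")
def block_slices(block_spec):
    return phantom.generate_phantom(block_spec)


@pytest.fixture()
def small_spec() -> phantom.PhantomSpec:
    """Tiny series for fast DICOM round-trip tests."""
    return phantom.PhantomSpec(matrix=(16, 16), n_slices=5,
                               insert_extents=(8.0, 8.0, 6.0))


@pytest.fixture()
def small_slices(small_spec):
    return phantom.generate_phantom(small_spec)
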