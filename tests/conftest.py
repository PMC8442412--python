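import pytest

from kickcut import default_spec, generate_dataset, load_thresholds


@pytest.fixture(scope="session")
def thresholds():
    return load_thresholds()


@pytest.fixture(scope="session")
def small_spec():
    """Scaled-down default spec: fast but covers all 40 strata."""
    return default_spec(scale=0.1)


@pytest.fixture(scope="session")
def small_dataset(small_spec):
    return generate_dataset(small_spec)


@pytest.fixture(scope="session")
def full_dataset():
    """Full-size default synthetic dataset (about 3.6k events)."""
    return generate_dataset(default_spec())
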