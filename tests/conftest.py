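import numpy as np
import pytest

from peridvc import PhantomSpec, Volume, insert_screw, make_trabecular_volume


@pytest.fixture(scope="session")
def small_spec() -> PhantomSpec:
    return PhantomSpec(dims=(64, 64, 64), seed=42, screw_radius_um=300.0)


@pytest.fixture(scope="session")
def small_phantom(small_spec) -> Volume:
    """64^3 trabecular phantom with a 300 μm screw, screw mask in meta."""
    return insert_screw(make_trabecular_volume(small_spec), small_spec)


@pytest.fixture(scope="session")
def texture_only() -> Volume:
    """Screw-free 64^3 trabecular texture."""
    spec = PhantomSpec(dims=(64, 64, 64), seed=7, screw_radius_um=0.0)
    return make_trabecular_volume(spec)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
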