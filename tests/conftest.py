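import numpy as np
import pytest

from fetalshim import (
    Grid,
    PhantomSpec,
    compute_fieldmap,
    generate_phantom,
    scenario_library,
    unwrap_fieldmap,
)


@pytest.fixture(scope="session")
def pure_sh_phantom():
    """Noise-free phantom whose background field is exactly in the shim span."""
    return generate_phantom(scenario_library()["pure-sh"])


@pytest.fixture(scope="session")
def pure_sh_fieldmap(pure_sh_phantom):
    d = pure_sh_phantom
    wrapped = compute_fieldmap(d.echo1, d.echo2)
    return unwrap_fieldmap(wrapped, d.echo2.te - d.echo1.te)


@pytest.fixture(scope="session")
def fat_conflict_phantom():
    return generate_phantom(scenario_library()["fat-conflict"])


@pytest.fixture
def small_grid():
    return Grid.centered((12, 10, 3), (5.0, 5.0, 10.0))


@pytest.fixture
def rng():
    return np.random.default_rng(42)
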