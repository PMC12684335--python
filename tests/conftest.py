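import numpy as np
import pytest

from nmrkin import FieldContext, cpmg, synth


@pytest.fixture(scope="session")
def field600() -> FieldContext:
    return FieldContext(600.0)


@pytest.fixture(scope="session")
def field950() -> FieldContext:
    return FieldContext(950.0)


@pytest.fixture(scope="session")
def nu_grid() -> np.ndarray:
    return np.array(synth.DEFAULT_GRID)


@pytest.fixture(scope="session")
def planted_network() -> cpmg.KineticNetwork:
    return synth.default_network()


@pytest.fixture(scope="session")
def study() -> synth.SyntheticStudy:
    """One shared synthetic two-arm study (cheap to build, reused widely)."""
    return synth.make_study_bundle(synth.GeneratorConfig(seed=20250101))
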