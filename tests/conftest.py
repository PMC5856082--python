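import numpy as np
import pytest

from fallbench import AdlScenario, DatasetSpec, FallScenario, generate_adl, generate_dataset, generate_fall


@pytest.fixture(scope="session")
def fall():
    """Default noisy fall recording + ground truth."""
    return generate_fall(FallScenario(seed=1))


@pytest.fixture(scope="session")
def clean_fall():
    """Zero-noise fall for geometry checks."""
    sc = FallScenario(noise_sd_g=0.0, gyro_noise_rads=0.0, seed=2)
    return generate_fall(sc)


@pytest.fixture(scope="session")
def adls():
    """One default recording per ADL kind."""
    return {
        kind: generate_adl(AdlScenario(kind=kind, seed=3))
        for kind in ("walking", "jogging", "jumping", "sitting", "lying", "standing")
    }


@pytest.fixture(scope="session")
def corpus40():
    """Small balanced corpus (20 falls + 20 ADLs) for protocol tests."""
    recs, manifest = generate_dataset(DatasetSpec(n_falls=20, n_adls=20, seed=5))
    return recs, manifest


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
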