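import numpy as np
import pytest

from tubemech import IndentationProtocol, SensorSpec, SpeciesParams, TubeSample


@pytest.fixture(scope="session")
def lily() -> SpeciesParams:
    return SpeciesParams("lily", 17.4, 2.5)


@pytest.fixture
def protocol() -> IndentationProtocol:
    return IndentationProtocol()


@pytest.fixture
def quiet_sensor() -> SensorSpec:
    """Noiseless, capillary-free sensor for closed-form checks."""
    return SensorSpec(k_sensor=10.0, force_noise_sd_nN=0.0, capillary_slope=0.0)


@pytest.fixture
def noisy_sensor() -> SensorSpec:
    return SensorSpec(k_sensor=10.0, force_noise_sd_nN=10.0, capillary_slope=0.017)


@pytest.fixture
def tube() -> TubeSample:
    return TubeSample(
        id="t000",
        diameter=17.4,
        wall_thickness=0.2,
        turgor=0.2,
        growing=True,
        k_load_true=2.2,
        k_unload_true=3.3,
    )


def spawn_seeds(master: int, n: int) -> list[int]:
    """Deterministic list of independent 31-bit seeds."""
    return [
        int(s.generate_state(1)[0] % (2**31))
        for s in np.random.SeedSequence(master).spawn(n)
    ]
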