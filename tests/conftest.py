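import numpy as np
import pytest

from fmblocks.pwm import PositionWeightMatrix, pwm_to_energy


def random_pwm(rng, length=None, name="pwm", dominance=0.8):
    """An informative random PWM for property tests."""
    L = length or int(rng.integers(4, 9))
    cons = rng.integers(0, 4, size=L)
    probs = np.full((L, 4), (1 - dominance) / 3)
    probs[np.arange(L), cons] = dominance
    return PositionWeightMatrix(name=name, probs=probs)


def random_seq(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def toy_pwm():
    return PositionWeightMatrix(
        name="toy",
        probs=np.array(
            [
                [0.7, 0.1, 0.1, 0.1],
                [0.1, 0.7, 0.1, 0.1],
                [0.1, 0.1, 0.7, 0.1],
                [0.1, 0.1, 0.1, 0.7],
                [0.7, 0.1, 0.1, 0.1],
            ]
        ),
    )


@pytest.fixture
def toy_model(toy_pwm):
    return pwm_to_energy(toy_pwm)


@pytest.fixture(scope="session")
def scenario():
    """One default synthetic cohort shared by read-only tests."""
    from fmblocks.simulate import ScenarioConfig, generate_scenario

    return generate_scenario(ScenarioConfig(seed=4021))


@pytest.fixture(scope="session")
def scenario_dir(tmp_path_factory, scenario):
    from fmblocks.simulate import write_scenario

    d = tmp_path_factory.mktemp("scenario")
    write_scenario(scenario, d)
    return d
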