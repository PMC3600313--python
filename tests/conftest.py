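import numpy as np
import pytest

from dentage import (
    SEXES,
    STAGES,
    TEETH,
    StageWeightTable,
    load_builtin,
    load_demo_weights,
)


@pytest.fixture(scope="session")
def demo_weights():
    return {sex: load_demo_weights(sex) for sex in SEXES}


@pytest.fixture(scope="session")
def saudi_tables():
    return {
        "male": load_builtin("saudi_male_table"),
        "female": load_builtin("saudi_female_table"),
    }


@pytest.fixture(scope="session")
def saudi_cubics():
    return {
        "male": load_builtin("saudi_male_cubic"),
        "female": load_builtin("saudi_female_cubic"),
    }


@pytest.fixture(scope="session")
def toy_weights():
    """Only three teeth carry weight; the rest stay at zero for all stages.

    Small enough for exhaustive enumeration of all 9**3 stage combinations.
    """
    carriers = {"I1": 40.0, "I2": 35.0, "C": 25.0}
    fracs = (0.0, 0.1, 0.2, 0.35, 0.5, 0.65, 0.8, 0.9, 1.0)
    weights = {}
    for tooth in TEETH:
        mx = carriers.get(tooth, 0.0)
        weights[tooth] = {s: round(mx * f, 6) for s, f in zip(STAGES, fracs)}
        weights[tooth]["H"] = mx
    return StageWeightTable(sex="male", weights=weights, provenance="toy")


def exact_moments_sample(rng, mean, sd, n):
    """A sample with exactly the requested mean and (n-1)-denominator sd."""
    z = rng.standard_normal(n)
    z = (z - z.mean()) / z.std(ddof=1)
    return mean + sd * z


@pytest.fixture(scope="session")
def moments_sampler():
    return exact_moments_sample
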