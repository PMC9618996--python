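import numpy as np
import pytest

from metalrisk import (
    FoodClass,
    Metal,
    METALS,
    default_reference_set,
    load_fish,
    load_vegetables,
)


@pytest.fixture(scope="session")
def veg():
    return load_vegetables()


@pytest.fixture(scope="session")
def fish():
    return load_fish()


@pytest.fixture(scope="session")
def refs():
    return default_reference_set()


@pytest.fixture(scope="session")
def factor_truth_3():
    """Fixed 3-factor ground truth: 100 samples x 6 metals, balanced factors."""
    from metalrisk.synthetic_data import FactorTruth

    rng = np.random.default_rng(2023)
    g = rng.uniform(0.5, 2.0, size=(100, 3))
    f = rng.uniform(0.1, 5.0, size=(3, 6))
    mdl = {m: 0.01 for m in METALS}
    return FactorTruth(g_true=g, f_true=f, noise_cv=0.05, mdl=mdl)


def pick(summaries, species, metal):
    """Fetch a single summary record by species and metal."""
    for s in summaries:
        if s.species == species and s.metal is metal:
            return s
    raise KeyError((species, metal))
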