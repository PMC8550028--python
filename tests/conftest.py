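import numpy as np
import pytest

from visconf.data_model import EXP1_DESIGN, ExperimentDesign
from visconf.models import ModelSpec
from visconf.synthetic import sample_parameters

#: family -> representative spec (constant variance)
ALL_FAMILIES = ("sdt", "noisy_sdt", "wev", "two_channel", "postdecisional", "cnd", "rce", "bayes2d")


def all_specs(include_modes: bool = False):
    """Every family, optionally crossed with the admissible variance modes."""
    specs = [ModelSpec(f) for f in ALL_FAMILIES]
    if include_modes:
        for f in ALL_FAMILIES:
            if f == "bayes2d":
                continue
            specs.append(ModelSpec(f, "identity_dependent"))
            specs.append(ModelSpec(f, "soa_dependent"))
    return specs


@pytest.fixture(scope="session")
def design():
    return EXP1_DESIGN


@pytest.fixture(scope="session")
def tiny_design():
    """Two SOAs, 20 trials each: fast fits for bookkeeping-level tests."""
    return ExperimentDesign(soa_levels_ms=(16.7, 133.3), trials_per_soa=20)


@pytest.fixture()
def rng():
    return np.random.default_rng(20231007)


def draw_params(spec, seed, design=None):
    return sample_parameters(spec, np.random.default_rng(seed), design or EXP1_DESIGN)
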