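import numpy as np
import pytest

from opncircuit import units
from opncircuit.kinetics import (DigestionTimeCourse, MCMCConfig,
                                 run_inference, simulate_digestion)
from opncircuit.synthetic import GeneratorConfig, generate_cohort


@pytest.fixture(scope="session")
def gen_config():
    return GeneratorConfig(seed=101)


@pytest.fixture(scope="session")
def true_kinetics(gen_config):
    return gen_config.true_kinetics()


@pytest.fixture(scope="session")
def true_params(gen_config):
    return gen_config.true_params()


def cohort_in_nm(cfg, seed=None):
    """Generate a cohort and attach the internal nM columns."""
    coh = generate_cohort(cfg, seed=seed)
    coh["opn_nm"] = units.ng_ml_to_nm(coh["opn_ng_ml"], units.OPN_KDA)
    coh["prot_nm"] = units.ng_ml_to_nm(coh["proteasome_ng_ml"],
                                       units.PROTEASOME_KDA)
    return coh


@pytest.fixture(scope="session")
def default_cohort(gen_config):
    return cohort_in_nm(gen_config)


@pytest.fixture(scope="session")
def short_posterior():
    """A quick single-curve inference shared across tests (truth:
    kcut = 1.2, KM = 140 at enzyme 150 nM, substrate 250 nM), using a
    densely sampled low-noise design so the posterior concentrates."""
    times = np.array([0.0, 0.25, 0.5, 1.0, 1.5, 2.0, 3.0, 4.0])
    opn, _ = simulate_digestion(1.2, 140.0, 150.0, 250.0, times)
    rel = opn / 250.0
    rng = np.random.default_rng(42)
    obs = rel[None, :] + rng.normal(0.0, 0.02, (4, times.size))
    data = DigestionTimeCourse("FL", "immuno", 150.0, 250.0, times, obs)
    chains = run_inference(data, MCMCConfig(n_iter=6000, burn_in=1500, seed=3))
    return data, chains
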