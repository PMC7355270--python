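import numpy as np
import pytest

from twinade import published
from twinade import synthetic_twins as st
from twinade.ade_model import ADEParameters, ModelSpec


@pytest.fixture(scope="session")
def hyp_params():
    """Generating parameters for the four hyperactivity phenotypes."""
    return published.cholesky_parameters(
        ("SWAN_HYP", "CPRS_HYP", "TRF_HYP", "CTRS_HYP")
    )


@pytest.fixture(scope="session")
def uni_spec():
    return ModelSpec(phenotypes=("P1",), teacher_rated=(False,), rater=False)


def make_uni_params(a2=0.4, d2=0.2, e2=0.4, beta=0.0, intercept=0.0):
    return ADEParameters(
        delta_a=[[np.sqrt(a2)]],
        delta_d=[[np.sqrt(d2)]],
        delta_e=[[np.sqrt(e2)]],
        intercepts=[intercept],
        beta_sex=[beta],
    )


def simulate_complete(params, spec, n_mz, n_dz, seed, prop_os_dz=0.482):
    design = st.SimulationDesign(
        n_mz_pairs=n_mz,
        n_dz_pairs=n_dz,
        prop_opposite_sex_dz=prop_os_dz,
        missingness=st.MissingnessSpec(0.0, 0.0, 0.0),
        seed=seed,
    )
    return st.simulate_pairs(params, spec, design, np.random.default_rng(seed))
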