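import numpy as np
import pytest

from fermkin import KineticParameters, datasets


@pytest.fixture(scope="session")
def ref_params() -> KineticParameters:
    """The packaged reference kinetic parameter set."""
    return datasets.load_reference_params()


@pytest.fixture(scope="session")
def sim_params(ref_params) -> KineticParameters:
    """Reference parameters with a maintenance coefficient small enough
    that the substrate lasts the whole 264 h run (the reference Ke of
    2.56 exhausts a 55 g/l substrate load within ~74 h)."""
    return KineticParameters(
        x0=ref_params.x0,
        xmax=ref_params.xmax,
        mu_max=ref_params.mu_max,
        y_xs=ref_params.y_xs,
        alpha=ref_params.alpha,
        k_int=ref_params.k_int,
        y_ps=ref_params.alpha * ref_params.y_xs,
        ke=2.56e-3,
        s0=ref_params.s0,
        p0=ref_params.p0,
    )


@pytest.fixture(scope="session")
def ref_design():
    return datasets.load_reference_design()


@pytest.fixture(scope="session")
def ref_factors():
    return datasets.reference_factors()


def random_growth_params(rng: np.random.Generator) -> dict:
    """One random but well-posed parameter set for oracle comparisons."""
    xmax = rng.uniform(1.0, 10.0)
    return dict(
        x0=rng.uniform(0.01, 0.3) * xmax,
        xmax=xmax,
        mu=rng.uniform(0.01, 0.15),
        y_xs=rng.uniform(0.5, 2.0),
        alpha=rng.uniform(0.1, 3.0),
        y_ps=rng.uniform(0.5, 3.0),
        ke=rng.uniform(0.0, 5e-3),
        s0=200.0,
    )
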