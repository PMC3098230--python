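import numpy as np
import pytest

from fatecircuit import GenericParams, Model1Params, Model2Params


@pytest.fixture
def base_params() -> GenericParams:
    """The reference parameter set a = f = 1, d = b = 0.5 (q varied via c)."""
    return GenericParams(a=1.0, f=1.0, b=0.5, c=0.5, d=0.5)


@pytest.fixture
def bistable_params(base_params) -> GenericParams:
    """q = 2: two committed attractors."""
    return base_params.with_q(2.0)


@pytest.fixture
def monostable_params(base_params) -> GenericParams:
    """q = 0.5: single indeterminate attractor."""
    return base_params.with_q(0.5)


@pytest.fixture
def model1_reference() -> Model1Params:
    """Symmetric kinetics mapping to a = f = 1, b = c = 1, d = 0.5."""
    return Model1Params(
        alpha_x=2.0, alpha_y=2.0, delta_x=0.5, delta_y=0.5,
        K_x=1.0, K_y=1.0, K_yx=1.0, K_xy=1.0, x_tot=0.5, y_tot=0.5,
    )


@pytest.fixture
def model2_factorizing(model1_reference) -> Model2Params:
    """Ternary-complex kinetics with K_xxy = K_yx: reduces identically to
    the Model 1 reference."""
    m = model1_reference
    return Model2Params(
        alpha_x=m.alpha_x, alpha_y=m.alpha_y, delta_x=m.delta_x, delta_y=m.delta_y,
        K_x=m.K_x, K_y=m.K_y, K_yx=m.K_yx, K_xy=m.K_xy,
        x_tot=m.x_tot, y_tot=m.y_tot, K_xxy=m.K_yx, K_yyx=m.K_xy,
    )


def random_positive_params(rng: np.random.Generator) -> GenericParams:
    """A random symmetric parameter draw satisfying positivity (a, f > d)."""
    d = rng.uniform(0.1, 1.0)
    return GenericParams(
        a=d + rng.uniform(0.1, 2.0),
        f=d + rng.uniform(0.1, 2.0),
        b=rng.uniform(0.1, 2.0),
        c=rng.uniform(0.1, 2.0),
        d=d,
    )
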