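import numpy as np
import pytest

from dsilt.families import get_family
from dsilt.synth import CoefficientSpec, DesignSpec, simulate_federated


@pytest.fixture(scope="session")
def small_logistic_data():
    """A small 3-study logistic dataset with 5 planted signals."""
    design = DesignSpec(kind="ar1", p=30, rho=0.5)
    coef = CoefficientSpec(M=3, s=5, mu=0.5)
    return simulate_federated(design, coef, "logistic", [150, 150, 150], seed=42)


@pytest.fixture(scope="session")
def tiny_logistic_xy():
    """Hand-sized single-study logistic data (n=40, p=4 incl. intercept)."""
    rng = np.random.default_rng(3)
    X = np.column_stack([np.ones(40), rng.standard_normal((40, 3))])
    beta = np.array([0.2, 1.0, -0.5, 0.0])
    Y = (rng.random(40) < get_family("logistic").phidot(X @ beta)).astype(float)
    return X, Y
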