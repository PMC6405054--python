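import numpy as np
import pytest

from gtpatterns import models, solver


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260101)


@pytest.fixture(scope="session")
def small_periodic_grid():
    return solver.Grid(W=20.0, H=20.0, nx=32, ny=32, bc_y="periodic")


@pytest.fixture(scope="session")
def small_noflux_grid():
    return solver.Grid(W=20.0, H=20.0, nx=32, ny=32, bc_y="noflux")


def random_feasible_point(model, rng, lo=0.05, hi=3.0):
    """A strictly positive random concentration point for a model."""
    return {v: float(rng.uniform(lo, hi)) for v in model.variables}


def numeric_jacobian(model, point, eps=1e-6):
    """Central-difference Jacobian of the reaction terms (test oracle)."""
    n = len(model.variables)
    J = np.zeros((n, n))
    for j, vj in enumerate(model.variables):
        pp, pm = dict(point), dict(point)
        pp[vj] += eps
        pm[vj] -= eps
        rp = models.reaction_rates(model, pp)
        rm = models.reaction_rates(model, pm)
        for i, vi in enumerate(model.variables):
            J[i, j] = (rp[vi] - rm[vi]) / (2 * eps)
    return J
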