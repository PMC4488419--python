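import numpy as np
import pytest

from ipboot.population import (
    generate_population,
    sim1_design,
    sim1_frame,
    sim2_population_spec,
    sim2_stratification,
    stratify_by_response,
)
from ipboot.sampling import ProbabilitySample


def make_sample(y, X=None, p=None, unit_id=None):
    """Build a small ProbabilitySample from plain arrays."""
    y = np.asarray(y, dtype=float)
    n = len(y)
    if X is None:
        X = np.empty((n, 0))
    else:
        X = np.asarray(X, dtype=float).reshape(n, -1)
    names = tuple(f"x{i + 1}" for i in range(X.shape[1]))
    if p is None:
        p = np.full(n, 0.5)
    return ProbabilitySample(
        unit_id=np.arange(1, n + 1) if unit_id is None else np.asarray(unit_id),
        response=y,
        covariates=X,
        covariate_names=names,
        inclusion_prob=np.asarray(p, dtype=float),
    )


@pytest.fixture(scope="session")
def table1_frame():
    return sim1_frame()


@pytest.fixture(scope="session")
def table1_design():
    return sim1_design()


@pytest.fixture(scope="session")
def sim2_frame():
    """One fixed realization of the 1400-row correlated population."""
    return generate_population(sim2_population_spec(seed=20240131))


@pytest.fixture(scope="session")
def sim2_design(sim2_frame):
    return stratify_by_response(sim2_frame, sim2_stratification())
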