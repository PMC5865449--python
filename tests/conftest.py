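import numpy as np
import pytest

from twinoverlap.scales import attach_scales
from twinoverlap.simulate import (GeneratorConfig, SyntheticCohort,
                                  default_solution, generate_cohort,
                                  generate_risk_factors)

# generating truth used across the suite (published decomposition)
SOLUTION = default_solution()
RHO_LIABILITY = 0.42191639887420734  # path-traced implied correlation
CROSS_MZ = 0.26538365469587255       # a_v a_o rA + c_v c_o rC
CROSS_DZ = 0.22060553503905805       # 0.5 a_v a_o rA + c_v c_o rC


@pytest.fixture(scope="session")
def big_cohort():
    """20000-pair cohort for Monte-Carlo checks of the population algebra."""
    cfg = GeneratorConfig(n_pairs=20000, seed=11)
    return generate_risk_factors(generate_cohort(cfg), cfg)


@pytest.fixture(scope="session")
def default_cohort():
    """Study-sized cohort (1116 pairs) with risks and derived scales."""
    cfg = GeneratorConfig(seed=5)
    cohort = generate_risk_factors(generate_cohort(cfg), cfg)
    return SyntheticCohort(attach_scales(cohort.individuals), cfg)


def exact_correlated_vectors(R: np.ndarray, n: int, seed: int = 0) -> np.ndarray:
    """Columns with *sample* correlation matrix exactly R (for formula oracles)."""
    rng = np.random.default_rng(seed)
    k = R.shape[0]
    X = np.column_stack([np.ones(n), rng.standard_normal((n, k))])
    Q, _ = np.linalg.qr(X)          # cols 1..k orthonormal and mean-centered
    L = np.linalg.cholesky(R)
    return Q[:, 1:k + 1] @ L.T
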