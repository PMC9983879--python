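import numpy as np
import pytest
import scipy.linalg

from magreml.grm import compute_grm
from magreml.simulate import scenario_params, simulate_dataset
from magreml.vcmodel import BivariateREMLProblem


def make_random_instance(seed: int, n: int = 12, p_covars: int = 1):
    """A random small GRM + phenotypes + design, plus random PSD Sigma pair.

    Used to compare the canonical-transform likelihood against the dense
    oracle.
    """
    rng = np.random.default_rng(seed)
    B = rng.normal(size=(n, n + 2))
    A = B @ B.T / (n + 2)
    LG = np.tril(rng.normal(size=(2, 2)))
    LE = np.tril(rng.normal(size=(2, 2))) + 2.0 * np.eye(2)
    Sigma_G, Sigma_E = LG @ LG.T, LE @ LE.T
    y_m = rng.normal(size=n)
    y_y = rng.normal(size=n)
    X = np.column_stack([np.ones(n)] + [rng.normal(size=n) for _ in range(p_covars)])
    return A, Sigma_G, Sigma_E, y_m, y_y, X


def problem_from_arrays(A, y_m, y_y, X) -> BivariateREMLProblem:
    d, U = np.linalg.eigh(A)
    return BivariateREMLProblem(d, U.T @ y_m, U.T @ y_y, U.T @ X)


@pytest.fixture(scope="session")
def baseline_small():
    """One Baseline-scenario dataset at n=500, m=600 with its REML problem."""
    params = scenario_params("Baseline")
    geno, phenos = simulate_dataset(params, n=500, m_snps=600, seed=42)
    grm = compute_grm(geno)
    d, U = scipy.linalg.eigh(grm.values, driver="evd")
    problem = BivariateREMLProblem(
        d,
        U.T @ phenos["M"].to_numpy(),
        U.T @ phenos["Y"].to_numpy(),
        U.T @ np.ones((grm.n, 1)),
    )
    return {"params": params, "geno": geno, "phenos": phenos, "grm": grm,
            "problem": problem}


@pytest.fixture(scope="session")
def baseline_small_fit(baseline_small):
    """Unconstrained fit (with VC sampling covariance) of the small Baseline
    dataset."""
    return baseline_small["problem"].fit(constraint="none", seed=0,
                                         compute_vcov=True)
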