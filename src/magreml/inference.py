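"""Significance of the indirect effect.

The indirect effect sigma_G_MM * b^2 is zero iff the mediator has no genetic
variance (null subspace ``Pa``: sigma_G_MM = sigma_G_MY = 0, two
restrictions) or no effect on the outcome (null subspace ``Pb``:
sigma_E_MY = 0, one restriction).  The null parameter space is their union,
which lies partly on the boundary of the VC space, so the headline test is a
likelihood-ratio test whose null optimum is the better of the two
constrained fits and whose degrees of freedom adapt to where that optimum is
found (2 for Pa, 1 for Pb).  A Wald statistic is provided as a secondary
diagnostic only: it is not invariant to reparameterization and misbehaves on
the boundary.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.stats

from .grm import GRM
from .vcmodel import (
    BivariateREMLProblem,
    REMLError,
    VarCompEstimate,
    align_sample_tables,
    grm_pcs,
)

_TIE_TOL = 1e-8
_NEG_TOL = 1e-6


def wald_test(estimate: float, se: float) -> tuple[float, float]:
    """Wald statistic (estimate/se)^2 against chi-square(1).

    Secondary diagnostic only — see the module docstring.
    """
    if not se > 0:
        raise ValueError("se must be positive")
    W = (estimate / se) ** 2
    p = float(scipy.stats.chi2.sf(W, df=1))
    return float(W), p


@dataclasses.dataclass
class LRTResult:
    """Boundary-aware LRT for the indirect effect.

    ``active_space`` records which null subspace attained the null optimum,
    which fixes the degrees of freedom; all three log-likelihoods are kept so
    the df choice can be audited.
    """

    loglik_full: float
    loglik_Pa: float
    loglik_Pb: float
    active_space: str
    df: int
    statistic: float
    p_value: float
    converged: bool = True

    @property
    def loglik_null(self) -> float:
        return max(self.loglik_Pa, self.loglik_Pb)


def lrt_from_logliks(
    loglik_full: float,
    loglik_Pa: float,
    loglik_Pb: float,
    converged: bool = True,
) -> LRTResult:
    """Assemble the LRT from the three fitted log-likelihoods.

    Ties between the two null subspaces (within 1e-8) resolve to Pb (df=1).
    A materially negative statistic indicates an optimizer failure on a
    nested model and raises.
    """
    if loglik_Pa > loglik_Pb + _TIE_TOL:
        active, df, ll_null = "Pa", 2, loglik_Pa
    else:
        active, df, ll_null = "Pb", 1, loglik_Pb
    stat = 2.0 * (loglik_full - ll_null)
    if stat < -10 * _NEG_TOL:
        raise REMLError(
            f"LRT statistic {stat:.3g} < 0: a constrained fit exceeded the "
            "unconstrained likelihood, indicating optimizer failure"
        )
    stat = max(stat, 0.0)
    p = float(scipy.stats.chi2.sf(stat, df=df))
    return LRTResult(
        loglik_full=float(loglik_full),
        loglik_Pa=float(loglik_Pa),
        loglik_Pb=float(loglik_Pb),
        active_space=active,
        df=df,
        statistic=float(stat),
        p_value=p,
        converged=converged,
    )


def lrt_indirect_from_problem(
    problem: BivariateREMLProblem,
    full: VarCompEstimate | None = None,
    n_starts: int = 3,
    seed: int = 0,
) -> tuple[LRTResult, VarCompEstimate]:
    """Run the three fits on a prepared REML problem and form the LRT.

    The unconstrained optimum (fitted here unless supplied) warm-starts both
    constrained fits via projection onto each null subspace, which protects
    the nesting inequality.  Returns (LRT result, unconstrained fit).
    """
    if full is None:
        full = problem.fit(constraint="none", n_starts=n_starts, seed=seed,
                           compute_vcov=True)
    warm = (full.sigma_G, full.sigma_E)
    fit_pa = problem.fit(constraint="Pa", n_starts=n_starts, seed=seed + 1,
                         warm_start=warm, compute_vcov=False)
    fit_pb = problem.fit(constraint="Pb", n_starts=n_starts, seed=seed + 2,
                         warm_start=warm, compute_vcov=False)
    converged = full.converged and fit_pa.converged and fit_pb.converged
    res = lrt_from_logliks(full.loglik, fit_pa.loglik, fit_pb.loglik, converged)
    return res, full


def lrt_indirect(
    grm: GRM,
    phenos: pd.DataFrame,
    traits: tuple[str, str],
    covars: pd.DataFrame | None = None,
    n_pcs: int = 0,
    n_starts: int = 3,
    seed: int = 0,
) -> tuple[LRTResult, VarCompEstimate]:
    """Boundary-aware LRT for the indirect effect on aligned data.

    Complete-case on the two traits; returns the LRT result together with
    the unconstrained VC estimate (with its sampling covariance) so callers
    can derive the mediation point estimates from the same fit.
    """
    tm, ty = traits
    grm2, ph, cv = align_sample_tables(grm, phenos[[tm, ty]], covars)
    y_m = ph[tm].to_numpy(dtype=float)
    y_y = ph[ty].to_numpy(dtype=float)
    complete = ~np.isnan(y_m) & ~np.isnan(y_y)
    sub = np.flatnonzero(complete)
    grm3 = grm2.subset(sub)
    n = grm3.n
    X = [np.ones((n, 1))]
    if cv is not None:
        X.append(cv.to_numpy(dtype=float)[sub])
    if n_pcs > 0:
        X.append(grm_pcs(grm3, n_pcs))
    X = np.hstack(X)
    d, U = scipy.linalg.eigh(grm3.values, driver="evd")
    problem = BivariateREMLProblem(d, U.T @ y_m[sub], U.T @ y_y[sub], U.T @ X,
                                   sample_ids=grm3.sample_ids)
    return lrt_indirect_from_problem(problem, n_starts=n_starts, seed=seed)
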