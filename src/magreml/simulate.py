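"""Synthetic genotypes and phenotypes under the mediation structural model.

The generative model has two latent genetic factors G and G* (polygenic,
built from the same SNP panel with independent effect vectors, so that their
covariance across individuals is the realized GRM) and two latent
environmental factors E and E* (iid standard normal per individual):

    M = a G + g G* + f E*
    Y = c G + b M + e E

G loads on both the mediator and (directly) the outcome; G* reaches the
outcome only through M.  The implied variance components are

    sigma_G_MM = a^2 + g^2            sigma_E_MM = f^2
    sigma_G_YY = (a^2+g^2) b^2 + c^2 + 2abc
                                      sigma_E_YY = f^2 b^2 + e^2
    sigma_G_MY = (a^2+g^2) b + a c    sigma_E_MY = f^2 b

The named verification scenarios fix f = e = 1 and split a^2 + g^2 evenly
between a and g:

=========  =========  =====  =====
scenario   a^2 + g^2    b     c^2
=========  =========  =====  =====
Baseline       2         1     1    (partial mediation)
i              0         1     1    (no mediation: M not heritable)
ii             2         0     1    (no mediation: M has no effect)
iii            0         0     1    (no mediation: neither)
iv             2         1     0    (full mediation)
=========  =========  =====  =====

``run_scenario`` repeats simulate -> GRM -> bivariate REML -> mediation
estimates (optionally the LRT) over independent replicates and tabulates
per-run results.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
import scipy.linalg

from .grm import GRM, GenotypeMatrix, compute_grm
from .inference import lrt_indirect_from_problem
from .mediation import mediation_effects
from .vcmodel import BivariateREMLProblem


@dataclasses.dataclass
class SEMParams:
    """Path coefficients of the generative mediation model."""

    a: float = 1.0
    g: float = 1.0
    f: float = 1.0
    b: float = 1.0
    c: float = 1.0
    e: float = 1.0

    def implied_sigma(self) -> tuple[np.ndarray, np.ndarray]:
        """(Sigma_G, Sigma_E) of the trait pair (M, Y) implied by the paths."""
        a, g, f, b, c, e = (self.a, self.g, self.f, self.b, self.c, self.e)
        ag2 = a * a + g * g
        SG = np.array(
            [[ag2, ag2 * b + a * c],
             [ag2 * b + a * c, ag2 * b * b + c * c + 2 * a * b * c]]
        )
        SE = np.array([[f * f, f * f * b], [f * f * b, f * f * b * b + e * e]])
        return SG, SE

    def implied_vcs(self) -> dict[str, float]:
        SG, SE = self.implied_sigma()
        return {
            "sigma_G_MM": SG[0, 0], "sigma_G_MY": SG[0, 1], "sigma_G_YY": SG[1, 1],
            "sigma_E_MM": SE[0, 0], "sigma_E_MY": SE[0, 1], "sigma_E_YY": SE[1, 1],
        }

    @property
    def indirect(self) -> float:
        return (self.a**2 + self.g**2) * self.b**2

    @property
    def direct(self) -> float:
        return self.c**2


_SCENARIOS: dict[str, tuple[float, float, float]] = {
    # name -> (a^2 + g^2, b, c^2)
    "Baseline": (2.0, 1.0, 1.0),
    "i": (0.0, 1.0, 1.0),
    "ii": (2.0, 0.0, 1.0),
    "iii": (0.0, 0.0, 1.0),
    "iv": (2.0, 1.0, 0.0),
}


def scenario_params(name: str) -> SEMParams:
    """Coefficients of a named verification scenario (a = g = sqrt(ag2/2),
    f = e = 1)."""
    try:
        ag2, b, c2 = _SCENARIOS[name]
    except KeyError:
        raise ValueError(
            f"unknown scenario {name!r}; choose from {sorted(_SCENARIOS)}"
        ) from None
    a = g = float(np.sqrt(ag2 / 2.0))
    return SEMParams(a=a, g=g, f=1.0, b=b, c=float(np.sqrt(c2)), e=1.0)


@dataclasses.dataclass
class ScenarioSpec:
    """A scenario plus the Monte-Carlo design (replicates, sizes, seed)."""

    name: str
    params: SEMParams
    n_individuals: int = 2000
    n_snps: int = 2500
    n_runs: int = 100
    seed: int = 1

    @classmethod
    def named(cls, name: str, n_individuals: int = 2000, n_snps: int = 2500,
              n_runs: int = 100, seed: int = 1) -> "ScenarioSpec":
        return cls(name=name, params=scenario_params(name),
                   n_individuals=n_individuals, n_snps=n_snps,
                   n_runs=n_runs, seed=seed)


def simulate_dataset(
    params: SEMParams,
    n: int,
    m_snps: int,
    seed: int,
    maf_range: tuple[float, float] = (0.05, 0.95),
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Draw one dataset: genotypes plus (M, Y) phenotypes.

    Genotypes are SNP-wise binomial(2, p_i) with p_i ~ Uniform(maf_range);
    G and G* are independent polygenic scores with effects ~ N(0, 1/m) on
    standardized genotypes, so their variance is ~1 and their covariance
    across individuals equals the realized GRM.  Deterministic given ``seed``.
    """
    if n < 2 or m_snps < 1:
        raise ValueError("need n >= 2 individuals and m_snps >= 1 SNPs")
    if params.f < 0:
        raise ValueError("f must be non-negative")
    rng = np.random.default_rng(seed)
    p = rng.uniform(*maf_range, size=m_snps)
    # binomial(2, p) as the sum of two Bernoulli draws (faster than the
    # broadcasting binomial sampler at this shape)
    X = (rng.random((n, m_snps)) < p).astype(float)
    X += rng.random((n, m_snps)) < p
    phat = X.mean(axis=0) / 2.0
    poly = (phat > 0) & (phat < 1)
    Z = (X[:, poly] - 2 * phat[poly]) / np.sqrt(2 * phat[poly] * (1 - phat[poly]))
    m = Z.shape[1]
    G = Z @ (rng.standard_normal(m) / np.sqrt(m))
    Gstar = Z @ (rng.standard_normal(m) / np.sqrt(m))
    E = rng.standard_normal(n)
    Estar = rng.standard_normal(n)
    M = params.a * G + params.g * Gstar + params.f * Estar
    Y = params.c * G + params.b * M + params.e * E
    ids = [(f"F{i}", f"I{i}") for i in range(n)]
    geno = GenotypeMatrix(X, ids, [f"snp{j}" for j in range(m_snps)])
    phenos = pd.DataFrame(
        {"M": M, "Y": Y},
        index=pd.MultiIndex.from_tuples(ids, names=["FID", "IID"]),
    )
    return geno, phenos


def _run_seeds(base_seed: int, n_runs: int) -> np.ndarray:
    state = np.random.SeedSequence(base_seed).generate_state(n_runs, dtype=np.uint32)
    return (state % np.uint32(2**31)).astype(np.int64)


def run_scenario(
    spec: ScenarioSpec,
    do_lrt: bool = True,
    compute_vcov: bool = True,
    n_starts: int = 3,
) -> pd.DataFrame:
    """Monte-Carlo study of one scenario; one row per replicate.

    Columns: the mediation point estimates and SEs, the outcome's genetic
    variance, and (if ``do_lrt``) the LRT statistic, adaptive df and p-value.
    Replicates whose fits fail are recorded with ``converged = False`` and
    NaN estimates.
    """
    seeds = _run_seeds(spec.seed, spec.n_runs)
    rows = []
    for run, run_seed in enumerate(seeds):
        row: dict = {"run": run, "seed": int(run_seed)}
        try:
            geno, phenos = simulate_dataset(
                spec.params, spec.n_individuals, spec.n_snps, int(run_seed)
            )
            grm = compute_grm(geno)
            d, U = scipy.linalg.eigh(grm.values, driver="evd")
            n = grm.n
            problem = BivariateREMLProblem(
                d,
                U.T @ phenos["M"].to_numpy(),
                U.T @ phenos["Y"].to_numpy(),
                U.T @ np.ones((n, 1)),
            )
            full = problem.fit(
                constraint="none", n_starts=n_starts, seed=int(run_seed),
                compute_vcov=compute_vcov or do_lrt,
            )
            med = mediation_effects(full)
            row.update(
                b=med.b, se_b=med.se_b,
                indirect=med.indirect, se_indirect=med.se_indirect,
                direct=med.direct, se_direct=med.se_direct,
                cross_term=med.cross_term,
                prop_mediated=med.prop_mediated,
                sigma_G_YY=full.sigma_G[1, 1],
                converged=full.converged,
            )
            if do_lrt:
                lrt, _ = lrt_indirect_from_problem(
                    problem, full=full, n_starts=n_starts, seed=int(run_seed)
                )
                row.update(
                    lrt_stat=lrt.statistic, df=lrt.df, p=lrt.p_value,
                    active_space=lrt.active_space,
                    converged=row["converged"] and lrt.converged,
                )
        except Exception as e:  # noqa: BLE001 - per-run failures are recorded
            row.update(converged=False, error=str(e))
        rows.append(row)
    return pd.DataFrame(rows)


def summarize_scenario(runs: pd.DataFrame) -> dict[str, float]:
    """Across-run means and mean SEs of the mediation estimands (failed runs
    excluded, with the exclusion count reported)."""
    ok = runs[runs.get("converged", pd.Series(dtype=bool)) == True]  # noqa: E712
    out: dict[str, float] = {
        "n_runs": float(len(runs)),
        "n_used": float(len(ok)),
        "n_failed": float(len(runs) - len(ok)),
    }
    for col in ("b", "indirect", "direct", "se_b", "se_indirect", "se_direct"):
        if col in ok:
            out[f"mean_{col}"] = float(ok[col].mean())
    for col in ("b", "indirect", "direct"):
        if col in ok and len(ok) > 1:
            out[f"mcse_{col}"] = float(ok[col].std(ddof=1) / np.sqrt(len(ok)))
    return out


def qq_data(pvals: np.ndarray) -> pd.DataFrame:
    """Sorted observed p-values against uniform quantiles ((i-0.5)/k), the
    raw material for an LRT calibration QQ plot."""
    p = np.sort(np.asarray(pvals, dtype=float))
    k = len(p)
    expected = (np.arange(1, k + 1) - 0.5) / k
    return pd.DataFrame({"expected": expected, "observed": p})
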