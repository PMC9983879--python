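"""Bivariate (and univariate) genome-based REML.

Model
-----
For traits M and Y measured on n individuals with genomic relatedness matrix
A, the stacked phenotype vector y = (y_M; y_Y) follows

    y ~ N(X beta,  V),   V = Sigma_G (x) A  +  Sigma_E (x) I_n,

where Sigma_G and Sigma_E are the 2x2 genetic and environmental covariance
matrices of the trait pair — six variance components (VCs) in total:
(sigma_G_MM, sigma_G_MY, sigma_G_YY, sigma_E_MM, sigma_E_MY, sigma_E_YY).
Fixed effects (intercept, covariates, GRM principal components) get a
separate coefficient vector per trait and are removed by restricted maximum
likelihood.

Computation
-----------
With the eigendecomposition A = U D U', rotating the phenotypes and the
design matrix of each trait by U' block-diagonalizes V into per-individual
2x2 blocks  V_i = d_i Sigma_G + Sigma_E  (the canonical transformation).
The restricted log-likelihood

    l = -1/2 [ (N - p) log 2*pi + log|V| + log|X' V^-1 X| + y' P y ]

and its analytic gradient with respect to the entries of Sigma_G and Sigma_E
are then sums of cheap 2x2 operations.  Sigma_G and Sigma_E are parameterized
through lower-triangular Cholesky-like factors, which keeps both matrices
positive semi-definite and turns the boundary null spaces of the mediation
likelihood-ratio test into linear restrictions:

* ``Pa`` (mediator has no genetic variance): first row of the genetic factor
  is zero, so sigma_G_MM = sigma_G_MY = 0 — two restrictions.
* ``Pb`` (mediator has no effect on the outcome): the off-diagonal
  environmental loading is zero, so sigma_E_MY = 0 — one restriction.

A dense-matrix likelihood (no canonical transform) is provided both as an
independent cross-check and as the exact path for per-trait missingness at
small n; at larger n, individuals missing one trait are dropped with a
warning (complete-case analysis).
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.optimize

from .grm import GRM, SampleID, grm_pcs

VC_NAMES = (
    "sigma_G_MM",
    "sigma_G_MY",
    "sigma_G_YY",
    "sigma_E_MM",
    "sigma_E_MY",
    "sigma_E_YY",
)

Constraint = Literal["none", "Pa", "Pb"]

_LOG2PI = float(np.log(2.0 * np.pi))


class REMLError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# Phenotype / covariate tables
# ---------------------------------------------------------------------------

def read_table(path: str) -> pd.DataFrame:
    """Read a phenotype or covariate file.

    Whitespace- or comma-delimited text with a header row whose first two
    columns are FID and IID; ``NA`` denotes missing.  Returns a DataFrame
    indexed by (FID, IID).
    """
    sep = "," if open(path).readline().count(",") >= 2 else r"\s+"
    df = pd.read_csv(path, sep=sep, na_values=["NA", "nan", "-9"], dtype={0: str, 1: str})
    if df.shape[1] < 3:
        raise ValueError(f"{path}: expected FID, IID and at least one value column")
    df = df.set_index([df.columns[0], df.columns[1]])
    df.index.names = ["FID", "IID"]
    if df.index.duplicated().any():
        raise ValueError(f"{path}: duplicate (FID, IID) rows")
    return df.astype(float)


def align_sample_tables(
    grm: GRM,
    phenos: pd.DataFrame,
    covars: pd.DataFrame | None = None,
) -> tuple[GRM, pd.DataFrame, pd.DataFrame | None]:
    """Intersect GRM, phenotypes and covariates on (FID, IID); order follows
    the GRM.  Individuals with any missing covariate are dropped."""
    ids = [s for s in grm.sample_ids if s in phenos.index]
    if covars is not None:
        cov_ok = set(covars.dropna().index)
        ids = [s for s in ids if s in cov_ok]
    if not ids:
        raise ValueError("empty analysis sample after aligning GRM and tables")
    grm2 = grm.reorder(ids)
    ph = phenos.loc[ids]
    cv = covars.loc[ids] if covars is not None else None
    return grm2, ph, cv


# ---------------------------------------------------------------------------
# Estimate container
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class VarCompEstimate:
    """Fitted variance components of a trait pair (M, Y).

    ``vcov_vc`` is the 6x6 sampling covariance of the VCs in :data:`VC_NAMES`
    order, from the inverse observed information at the optimum (unconstrained
    fits only).
    """

    sigma_G: np.ndarray
    sigma_E: np.ndarray
    loglik: float
    vcov_vc: np.ndarray | None
    n_used: dict
    converged: bool
    constraint: Constraint = "none"
    n_iter: int = 0
    grad_norm: float = float("nan")

    @property
    def vc(self) -> np.ndarray:
        """The six VCs as a vector in :data:`VC_NAMES` order."""
        G, E = self.sigma_G, self.sigma_E
        return np.array([G[0, 0], G[0, 1], G[1, 1], E[0, 0], E[0, 1], E[1, 1]])

    def __post_init__(self) -> None:
        for S in (self.sigma_G, self.sigma_E):
            ev = np.linalg.eigvalsh(np.asarray(S, dtype=float))
            if ev.min() < -1e-8:
                raise ValueError("variance matrices must be PSD")


def heritability(vc: VarCompEstimate, trait: str = "Y") -> tuple[float, float]:
    """SNP-based heritability sigma_G / (sigma_G + sigma_E) of one trait,
    with a delta-method SE from ``vcov_vc`` (NaN if unavailable)."""
    t = {"M": 0, "Y": 1}[trait]
    g = float(vc.sigma_G[t, t])
    e = float(vc.sigma_E[t, t])
    tot = g + e
    if tot <= 0:
        raise ValueError(f"trait {trait} has zero total variance")
    h2 = g / tot
    J = np.zeros(6)
    J[2 * t] = e / tot**2      # d h2 / d sigma_G
    J[3 + 2 * t] = -g / tot**2  # d h2 / d sigma_E
    se = float("nan")
    if vc.vcov_vc is not None:
        se = float(np.sqrt(max(J @ vc.vcov_vc @ J, 0.0)))
    return h2, se


def genetic_correlation(vc: VarCompEstimate) -> tuple[float, float]:
    """Genetic correlation sigma_G_MY / sqrt(sigma_G_MM * sigma_G_YY) with a
    delta-method SE."""
    gmm, gmy, gyy = vc.sigma_G[0, 0], vc.sigma_G[0, 1], vc.sigma_G[1, 1]
    if gmm <= 0 or gyy <= 0:
        raise ValueError(
            "genetic correlation undefined: a genetic variance is zero "
            "(the genetic factors of that trait are not identified)"
        )
    rho = gmy / np.sqrt(gmm * gyy)
    J = np.zeros(6)
    J[0] = -0.5 * rho / gmm
    J[1] = 1.0 / np.sqrt(gmm * gyy)
    J[2] = -0.5 * rho / gyy
    se = float("nan")
    if vc.vcov_vc is not None:
        se = float(np.sqrt(max(J @ vc.vcov_vc @ J, 0.0)))
    return float(rho), se


# ---------------------------------------------------------------------------
# Canonical-transform likelihood machinery
# ---------------------------------------------------------------------------

def _chol_to_sigma(L: np.ndarray) -> np.ndarray:
    return L @ L.T


def _safe_chol2(S: np.ndarray, jitter: float = 1e-8) -> np.ndarray:
    S = np.asarray(S, dtype=float)
    scale = max(np.trace(S) / 2.0, 1e-12)
    try:
        return np.linalg.cholesky(S + jitter * scale * np.eye(2))
    except np.linalg.LinAlgError:
        ev, Q = np.linalg.eigh(S)
        ev = np.clip(ev, jitter * scale, None)
        return np.linalg.cholesky(Q @ np.diag(ev) @ Q.T)


class BivariateREMLProblem:
    """A bivariate REML problem after the canonical transformation.

    Holds the GRM eigenvalues, rotated phenotypes and rotated per-trait design
    matrix; exposes the restricted log-likelihood, its analytic gradient in
    VC space, constrained fitting, and the observed-information covariance of
    the VC estimates.
    """

    def __init__(
        self,
        eigvals: np.ndarray,
        y_m: np.ndarray,
        y_y: np.ndarray,
        X: np.ndarray,
        sample_ids: list[SampleID] | None = None,
    ):
        self.d = np.asarray(eigvals, dtype=float)
        self.ym = np.asarray(y_m, dtype=float)
        self.yy = np.asarray(y_y, dtype=float)
        self.X = np.asarray(X, dtype=float)
        n = len(self.d)
        if not (len(self.ym) == len(self.yy) == n and self.X.shape[0] == n):
            raise ValueError("eigenvalues, phenotypes and design must share n")
        if np.linalg.matrix_rank(self.X) < self.X.shape[1]:
            raise ValueError("design matrix is rank deficient")
        self.n = n
        self.p = self.X.shape[1]  # per-trait fixed effects
        self.sample_ids = sample_ids

    @classmethod
    def from_data(
        cls,
        grm: GRM,
        y_m: np.ndarray,
        y_y: np.ndarray,
        covars: np.ndarray | None = None,
        n_pcs: int = 0,
    ) -> "BivariateREMLProblem":
        """Eigendecompose the GRM and rotate phenotypes/covariates.

        ``covars`` (n x c, without intercept) and the top ``n_pcs`` GRM
        eigenvectors are combined with an intercept into the per-trait design.
        """
        n = grm.n
        X = [np.ones((n, 1))]
        if covars is not None:
            X.append(np.asarray(covars, dtype=float).reshape(n, -1))
        if n_pcs > 0:
            X.append(grm_pcs(grm, n_pcs))
        X = np.hstack(X)
        d, U = scipy.linalg.eigh(grm.values, driver="evd")
        return cls(
            eigvals=d,
            y_m=U.T @ np.asarray(y_m, dtype=float),
            y_y=U.T @ np.asarray(y_y, dtype=float),
            X=U.T @ X,
            sample_ids=grm.sample_ids,
        )

    # -- likelihood ---------------------------------------------------------

    def _blocks(self, Sigma_G: np.ndarray, Sigma_E: np.ndarray):
        d = self.d
        a = d * Sigma_G[0, 0] + Sigma_E[0, 0]
        b = d * Sigma_G[0, 1] + Sigma_E[0, 1]
        c = d * Sigma_G[1, 1] + Sigma_E[1, 1]
        det = a * c - b * b
        return a, b, c, det

    def loglik(self, Sigma_G: np.ndarray, Sigma_E: np.ndarray) -> float:
        """Restricted log-likelihood at the given covariance matrices."""
        ll, _ = self._ll_grad(Sigma_G, Sigma_E, want_grad=False)
        return ll

    def grad_vc(self, Sigma_G: np.ndarray, Sigma_E: np.ndarray) -> np.ndarray:
        """Analytic gradient of the restricted log-likelihood with respect to
        the six VCs (:data:`VC_NAMES` order)."""
        _, g = self._ll_grad(Sigma_G, Sigma_E, want_grad=True)
        return g

    def _ll_grad(self, Sigma_G, Sigma_E, want_grad: bool):
        Sigma_G = np.asarray(Sigma_G, dtype=float)
        Sigma_E = np.asarray(Sigma_E, dtype=float)
        a, b, c, det = self._blocks(Sigma_G, Sigma_E)
        if (det <= 0).any() or (a <= 0).any():
            i = int(np.argmin(np.where(a <= 0, a, det)))
            raise REMLError(
                f"covariance block for eigenvalue index {i} "
                f"(d={self.d[i]:.6g}) is not positive definite"
            )
        w00 = c / det
        w01 = -b / det
        w11 = a / det
        X, ym, yy = self.X, self.ym, self.yy
        # GLS normal equations: S (2p x 2p), u (2p)
        S00 = X.T @ (w00[:, None] * X)
        S01 = X.T @ (w01[:, None] * X)
        S11 = X.T @ (w11[:, None] * X)
        S = np.block([[S00, S01], [S01.T, S11]])
        u = np.concatenate([X.T @ (w00 * ym + w01 * yy), X.T @ (w01 * ym + w11 * yy)])
        try:
            cho = scipy.linalg.cho_factor(S)
        except np.linalg.LinAlgError as e:  # pragma: no cover
            raise REMLError("X'V^-1X not positive definite") from e
        beta = scipy.linalg.cho_solve(cho, u)
        logdet_S = 2.0 * np.sum(np.log(np.diag(cho[0])))
        p = self.p
        r0 = ym - X @ beta[:p]
        r1 = yy - X @ beta[p:]
        q0 = w00 * r0 + w01 * r1
        q1 = w01 * r0 + w11 * r1
        quad = float(r0 @ q0 + r1 @ q1)
        Nobs = 2 * self.n
        ll = -0.5 * ((Nobs - 2 * p) * _LOG2PI + np.sum(np.log(det)) + logdet_S + quad)
        if not want_grad:
            return float(ll), None
        # tr(S^-1 X'W Delta W X) terms via x_i' (S^-1)_ab x_i quadratics
        Sinv = scipy.linalg.cho_solve(cho, np.eye(2 * p))
        C00, C01, C11 = Sinv[:p, :p], Sinv[:p, p:], Sinv[p:, p:]
        t00 = np.einsum("ij,jk,ik->i", X, C00, X)
        t01 = np.einsum("ij,jk,ik->i", X, C01, X)
        t11 = np.einsum("ij,jk,ik->i", X, C11, X)
        m00 = w00 * w00 * t00 + 2 * w00 * w01 * t01 + w01 * w01 * t11
        m11 = w01 * w01 * t00 + 2 * w01 * w11 * t01 + w11 * w11 * t11
        m01 = 2.0 * (w00 * w01 * t00 + (w00 * w11 + w01 * w01) * t01 + w01 * w11 * t11)
        e00 = w00 - m00 - q0 * q0
        e01 = 2.0 * w01 - m01 - 2.0 * q0 * q1
        e11 = w11 - m11 - q1 * q1
        d = self.d
        g = -0.5 * np.array(
            [
                float(d @ e00),
                float(d @ e01),
                float(d @ e11),
                float(np.sum(e00)),
                float(np.sum(e01)),
                float(np.sum(e11)),
            ]
        )
        return float(ll), g

    # -- parameterization ---------------------------------------------------

    @staticmethod
    def _theta_to_chols(theta: np.ndarray, constraint: Constraint):
        LG = np.zeros((2, 2))
        LE = np.zeros((2, 2))
        if constraint == "none":
            LG[0, 0], LG[1, 0], LG[1, 1] = theta[0:3]
            LE[0, 0], LE[1, 0], LE[1, 1] = theta[3:6]
        elif constraint == "Pa":
            LG[1, 1] = theta[0]
            LE[0, 0], LE[1, 0], LE[1, 1] = theta[1:4]
        elif constraint == "Pb":
            LG[0, 0], LG[1, 0], LG[1, 1] = theta[0:3]
            LE[0, 0], LE[1, 1] = theta[3:5]
        else:
            raise ValueError(f"unknown constraint {constraint!r}")
        return LG, LE

    @staticmethod
    def _chols_to_theta(LG: np.ndarray, LE: np.ndarray, constraint: Constraint):
        if constraint == "none":
            return np.array([LG[0, 0], LG[1, 0], LG[1, 1], LE[0, 0], LE[1, 0], LE[1, 1]])
        if constraint == "Pa":
            # project: drop the mediator's genetic loadings
            gyy = np.sqrt(LG[1, 0] ** 2 + LG[1, 1] ** 2)
            return np.array([gyy, LE[0, 0], LE[1, 0], LE[1, 1]])
        if constraint == "Pb":
            eyy = np.sqrt(LE[1, 0] ** 2 + LE[1, 1] ** 2)
            return np.array([LG[0, 0], LG[1, 0], LG[1, 1], LE[0, 0], eyy])
        raise ValueError(f"unknown constraint {constraint!r}")

    def _grad_theta(self, g_vc: np.ndarray, LG, LE, constraint: Constraint):
        gG00, gG01, gG11, gE00, gE01, gE11 = g_vc

        def chol_grad(l0, l1, l2, g00, g01, g11):
            return (
                2 * l0 * g00 + l1 * g01,
                l0 * g01 + 2 * l1 * g11,
                2 * l2 * g11,
            )

        dG = chol_grad(LG[0, 0], LG[1, 0], LG[1, 1], gG00, gG01, gG11)
        dE = chol_grad(LE[0, 0], LE[1, 0], LE[1, 1], gE00, gE01, gE11)
        if constraint == "none":
            return np.array([*dG, *dE])
        if constraint == "Pa":
            return np.array([dG[2], *dE])
        if constraint == "Pb":
            return np.array([*dG, dE[0], dE[2]])
        raise ValueError(constraint)

    # -- fitting ------------------------------------------------------------

    def _residual_cov(self) -> np.ndarray:
        """Phenotypic covariance of the two traits after removing fixed
        effects (OLS); a method-of-moments anchor for start values."""
        X = self.X
        Q, _ = np.linalg.qr(X)
        r0 = self.ym - Q @ (Q.T @ self.ym)
        r1 = self.yy - Q @ (Q.T @ self.yy)
        dof = max(self.n - self.p, 2)
        C = np.array([[r0 @ r0, r0 @ r1], [r0 @ r1, r1 @ r1]]) / dof
        return C

    def _start_points(self, constraint: Constraint, seed: int, n_starts: int):
        C = self._residual_cov()
        starts = []
        rng = np.random.default_rng(seed)
        fracs = [0.5, 0.25]
        for k in range(n_starts):
            if k < len(fracs):
                hg = fracs[k]
            else:
                hg = float(rng.uniform(0.1, 0.9))
            LG = _safe_chol2(hg * C)
            LE = _safe_chol2((1.0 - hg) * C)
            starts.append(self._chols_to_theta(LG, LE, constraint))
        return starts

    def fit(
        self,
        constraint: Constraint = "none",
        n_starts: int = 3,
        seed: int = 0,
        start: np.ndarray | None = None,
        warm_start: tuple[np.ndarray, np.ndarray] | None = None,
        compute_vcov: bool = True,
        gtol: float = 1e-6,
        maxiter: int = 500,
    ) -> VarCompEstimate:
        """Maximize the restricted likelihood over the (constrained) space.

        ``warm_start`` takes (Sigma_G, Sigma_E) — e.g. an unconstrained
        optimum to be projected onto the constraint — used as an additional
        start.  ``vcov_vc`` is computed only for unconstrained fits.
        """
        bad = (np.inf, None)

        def objective(theta):
            LG, LE = self._theta_to_chols(theta, constraint)
            try:
                ll, g_vc = self._ll_grad(_chol_to_sigma(LG), _chol_to_sigma(LE), True)
            except REMLError:
                return bad[0], np.zeros_like(theta)
            return -ll, -self._grad_theta(g_vc, LG, LE, constraint)

        starts = [] if start is None else [np.asarray(start, dtype=float)]
        if warm_start is not None:
            LG = _safe_chol2(warm_start[0])
            LE = _safe_chol2(warm_start[1])
            starts.append(self._chols_to_theta(LG, LE, constraint))
        starts.extend(self._start_points(constraint, seed, n_starts))

        best = None
        for theta0 in starts:
            res = scipy.optimize.minimize(
                objective,
                theta0,
                jac=True,
                method="L-BFGS-B",
                options={"ftol": 1e-13, "gtol": gtol, "maxiter": maxiter},
            )
            if not np.isfinite(res.fun):
                continue
            if best is None or res.fun < best.fun - 1e-9:
                best = res
        if best is None:
            raise REMLError("all optimizer starts failed")

        LG, LE = self._theta_to_chols(best.x, constraint)
        Sigma_G = _chol_to_sigma(LG)
        Sigma_E = _chol_to_sigma(LE)
        grad_norm = float(np.max(np.abs(best.jac)))
        converged = bool(best.success or grad_norm < 10 * gtol)
        if not converged:
            warnings.warn(
                f"REML fit (constraint={constraint}) did not converge: "
                f"{best.message}", RuntimeWarning,
            )
        vcov = None
        if compute_vcov and constraint == "none":
            vcov = self.vc_covariance(Sigma_G, Sigma_E)
        return VarCompEstimate(
            sigma_G=Sigma_G,
            sigma_E=Sigma_E,
            loglik=float(-best.fun),
            vcov_vc=vcov,
            n_used={"M": self.n, "Y": self.n},
            converged=converged,
            constraint=constraint,
            n_iter=int(best.nit),
            grad_norm=grad_norm,
        )

    def vc_covariance(self, Sigma_G: np.ndarray, Sigma_E: np.ndarray) -> np.ndarray:
        """Sampling covariance of the six VCs: inverse observed information,
        with the information matrix obtained by central finite differences of
        the analytic VC-space gradient at the optimum."""
        vc0 = np.array(
            [Sigma_G[0, 0], Sigma_G[0, 1], Sigma_G[1, 1],
             Sigma_E[0, 0], Sigma_E[0, 1], Sigma_E[1, 1]]
        )
        scale = 0.5 * (vc0[0] + vc0[3] + vc0[2] + vc0[5])

        def grad_at(vc):
            G = np.array([[vc[0], vc[1]], [vc[1], vc[2]]])
            E = np.array([[vc[3], vc[4]], [vc[4], vc[5]]])
            return self.grad_vc(G, E)

        H = np.zeros((6, 6))
        for k in range(6):
            h = 1e-5 * max(abs(vc0[k]), 0.01 * scale, 1e-8)
            vp, vm = vc0.copy(), vc0.copy()
            vp[k] += h
            vm[k] -= h
            try:
                H[:, k] = (grad_at(vp) - grad_at(vm)) / (2.0 * h)
            except REMLError:
                # one-sided fallback at a boundary
                vp2 = vc0.copy()
                vp2[k] += h
                H[:, k] = (grad_at(vp2) - grad_at(vc0)) / h
        H = 0.5 * (H + H.T)
        info = -H
        try:
            vcov = np.linalg.inv(info)
        except np.linalg.LinAlgError:
            warnings.warn("observed information singular; using pseudo-inverse",
                          RuntimeWarning)
            vcov = np.linalg.pinv(info)
        return 0.5 * (vcov + vcov.T)


def reml_loglik(
    Sigma_G: np.ndarray,
    Sigma_E: np.ndarray,
    problem: BivariateREMLProblem,
) -> float:
    """Restricted log-likelihood of a bivariate GREML model (canonical
    transform); see :class:`BivariateREMLProblem`."""
    return problem.loglik(Sigma_G, Sigma_E)


# ---------------------------------------------------------------------------
# Dense-matrix likelihood (oracle / exact missing-data path)
# ---------------------------------------------------------------------------

def dense_reml_loglik(
    A: np.ndarray,
    Sigma_G: np.ndarray,
    Sigma_E: np.ndarray,
    y_m: np.ndarray,
    y_y: np.ndarray,
    X: np.ndarray,
    obs_m: np.ndarray | None = None,
    obs_y: np.ndarray | None = None,
) -> float:
    """Restricted log-likelihood evaluated on the explicit stacked covariance
    matrix, supporting per-trait missingness.

    ``obs_m`` / ``obs_y`` are boolean masks of individuals observed for each
    trait (default: all).  O(N^3) per call — intended for small problems and
    as the independent cross-check of the canonical-transform path.
    """
    A = np.asarray(A, dtype=float)
    n = A.shape[0]
    obs_m = np.ones(n, dtype=bool) if obs_m is None else np.asarray(obs_m, bool)
    obs_y = np.ones(n, dtype=bool) if obs_y is None else np.asarray(obs_y, bool)
    im = np.flatnonzero(obs_m)
    iy = np.flatnonzero(obs_y)
    Vmm = Sigma_G[0, 0] * A[np.ix_(im, im)] + Sigma_E[0, 0] * np.eye(len(im))
    Vyy = Sigma_G[1, 1] * A[np.ix_(iy, iy)] + Sigma_E[1, 1] * np.eye(len(iy))
    cross_eye = (im[:, None] == iy[None, :]).astype(float)
    Vmy = Sigma_G[0, 1] * A[np.ix_(im, iy)] + Sigma_E[0, 1] * cross_eye
    V = np.block([[Vmm, Vmy], [Vmy.T, Vyy]])
    Xs = scipy.linalg.block_diag(X[im], X[iy])
    yv = np.concatenate([np.asarray(y_m, float)[im], np.asarray(y_y, float)[iy]])
    N, p = Xs.shape
    try:
        cV = scipy.linalg.cho_factor(V)
    except np.linalg.LinAlgError as e:
        raise REMLError("stacked covariance matrix not positive definite") from e
    logdet_V = 2.0 * np.sum(np.log(np.diag(cV[0])))
    Vinv_X = scipy.linalg.cho_solve(cV, Xs)
    Vinv_y = scipy.linalg.cho_solve(cV, yv)
    S = Xs.T @ Vinv_X
    u = Xs.T @ Vinv_y
    cS = scipy.linalg.cho_factor(S)
    logdet_S = 2.0 * np.sum(np.log(np.diag(cS[0])))
    beta = scipy.linalg.cho_solve(cS, u)
    quad = float(yv @ Vinv_y - u @ beta)
    return float(-0.5 * ((N - p) * _LOG2PI + logdet_V + logdet_S + quad))


def _dense_fit(A, y_m, y_y, X, obs_m, obs_y, constraint, n_starts, seed):
    """Numerically-differentiated dense REML fit (small-n missing-data path)."""
    dummy = BivariateREMLProblem(np.ones(3), np.zeros(3), np.zeros(3), np.ones((3, 1)))

    def objective(theta):
        LG, LE = BivariateREMLProblem._theta_to_chols(theta, constraint)
        try:
            return -dense_reml_loglik(
                A, _chol_to_sigma(LG), _chol_to_sigma(LE), y_m, y_y, X, obs_m, obs_y
            )
        except REMLError:
            return np.inf

    # start from the complete-case canonical fit
    both = obs_m & obs_y
    sub = np.flatnonzero(both)
    d, U = scipy.linalg.eigh(A[np.ix_(sub, sub)], driver="evd")
    prob = BivariateREMLProblem(d, U.T @ y_m[sub], U.T @ y_y[sub], U.T @ X[sub])
    cc = prob.fit(constraint=constraint, n_starts=n_starts, seed=seed,
                  compute_vcov=False)
    theta0 = BivariateREMLProblem._chols_to_theta(
        _safe_chol2(cc.sigma_G), _safe_chol2(cc.sigma_E), constraint
    )
    res = scipy.optimize.minimize(objective, theta0, method="Nelder-Mead",
                                  options={"xatol": 1e-8, "fatol": 1e-10,
                                           "maxiter": 4000})
    LG, LE = dummy._theta_to_chols(res.x, constraint)
    return VarCompEstimate(
        sigma_G=_chol_to_sigma(LG),
        sigma_E=_chol_to_sigma(LE),
        loglik=float(-res.fun),
        vcov_vc=None,
        n_used={"M": int(obs_m.sum()), "Y": int(obs_y.sum())},
        converged=bool(res.success),
        constraint=constraint,
        n_iter=int(res.nit),
    )


# ---------------------------------------------------------------------------
# High-level fitting
# ---------------------------------------------------------------------------

def reml_fit(
    grm: GRM,
    phenos: pd.DataFrame,
    traits: tuple[str, str],
    covars: pd.DataFrame | None = None,
    constraint: Constraint = "none",
    n_pcs: int = 0,
    n_starts: int = 3,
    seed: int = 0,
    compute_vcov: bool = True,
    dense_max: int = 1000,
    min_n: int = 50,
) -> VarCompEstimate:
    """Fit the bivariate GREML model for ``traits = (mediator, outcome)``.

    Individuals are aligned on (FID, IID) in GRM order.  Per-trait missingness
    is handled exactly through the dense likelihood when the total number of
    observations is at most ``dense_max``; otherwise individuals missing
    either trait are dropped with a warning.
    """
    tm, ty = traits
    if tm == ty:
        raise ValueError("mediator and outcome must be different traits")
    grm2, ph, cv = align_sample_tables(grm, phenos[[tm, ty]], covars)
    y_m = ph[tm].to_numpy(dtype=float)
    y_y = ph[ty].to_numpy(dtype=float)
    obs_m = ~np.isnan(y_m)
    obs_y = ~np.isnan(y_y)
    keep_any = obs_m | obs_y
    if keep_any.sum() < min_n:
        raise ValueError(
            f"analysis sample has {int(keep_any.sum())} individuals; "
            f"minimum is {min_n}"
        )
    n = grm2.n
    X = [np.ones((n, 1))]
    if cv is not None:
        X.append(cv.to_numpy(dtype=float))
    if n_pcs > 0:
        X.append(grm_pcs(grm2, n_pcs))
    X = np.hstack(X)

    complete = obs_m & obs_y
    if complete.all():
        d, U = scipy.linalg.eigh(grm2.values, driver="evd")
        prob = BivariateREMLProblem(d, U.T @ y_m, U.T @ y_y, U.T @ X,
                                    sample_ids=grm2.sample_ids)
        return prob.fit(constraint=constraint, n_starts=n_starts, seed=seed,
                        compute_vcov=compute_vcov)

    n_obs = int(obs_m.sum() + obs_y.sum())
    if n_obs <= dense_max:
        return _dense_fit(grm2.values, np.nan_to_num(y_m), np.nan_to_num(y_y),
                          X, obs_m, obs_y, constraint, n_starts, seed)
    warnings.warn(
        f"per-trait missingness with {n_obs} observations exceeds the exact "
        f"dense path (dense_max={dense_max}); falling back to complete-case "
        f"analysis of {int(complete.sum())} individuals",
        RuntimeWarning,
    )
    sub = np.flatnonzero(complete)
    grm3 = grm2.subset(sub)
    d, U = scipy.linalg.eigh(grm3.values, driver="evd")
    prob = BivariateREMLProblem(d, U.T @ y_m[sub], U.T @ y_y[sub], U.T @ X[sub],
                                sample_ids=grm3.sample_ids)
    return prob.fit(constraint=constraint, n_starts=n_starts, seed=seed,
                    compute_vcov=compute_vcov)


def reml_fit_univariate(
    grm: GRM,
    y: np.ndarray,
    covars: np.ndarray | None = None,
    n_starts: int = 3,
    seed: int = 0,
) -> tuple[float, float, float]:
    """Univariate GREML fit; returns (sigma_G, sigma_E, loglik).

    The univariate model is the 1x1 special case of the bivariate machinery:
    V_i = d_i * sigma_G + sigma_E per rotated observation.
    """
    n = grm.n
    y = np.asarray(y, dtype=float)
    X = np.ones((n, 1)) if covars is None else np.hstack(
        [np.ones((n, 1)), np.asarray(covars, float).reshape(n, -1)]
    )
    d, U = scipy.linalg.eigh(grm.values, driver="evd")
    yr = U.T @ y
    Xr = U.T @ X
    p = X.shape[1]

    def negll(theta):
        sg, se = theta[0] ** 2, theta[1] ** 2
        v = d * sg + se
        if (v <= 0).any():
            return np.inf
        w = 1.0 / v
        S = Xr.T @ (w[:, None] * Xr)
        u = Xr.T @ (w * yr)
        try:
            cS = scipy.linalg.cho_factor(S)
        except np.linalg.LinAlgError:
            return np.inf
        beta = scipy.linalg.cho_solve(cS, u)
        r = yr - Xr @ beta
        quad = float(r @ (w * r))
        logdet_S = 2.0 * np.sum(np.log(np.diag(cS[0])))
        return 0.5 * ((n - p) * _LOG2PI + np.sum(np.log(v)) + logdet_S + quad)

    var_y = float(np.var(y, ddof=1))
    rng = np.random.default_rng(seed)
    best = None
    for k in range(n_starts):
        hg = [0.5, 0.25][k] if k < 2 else float(rng.uniform(0.1, 0.9))
        x0 = np.sqrt([hg * var_y, (1 - hg) * var_y])
        res = scipy.optimize.minimize(negll, x0, method="Nelder-Mead",
                                      options={"xatol": 1e-10, "fatol": 1e-12})
        if best is None or res.fun < best.fun:
            best = res
    return float(best.x[0] ** 2), float(best.x[1] ** 2), float(-best.fun)
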