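"""Variational Bayesian assignment of multi-mapped reads to alleles.

Model: each read pair R_n originates from exactly one allele t
(indicator Z_nt) with probability theta_t; theta has a symmetric
Dirichlet prior with hyperparameter alpha0, P(theta) ∝ prod_t
theta_t^(alpha0 - 1).  The read-given-allele likelihoods P(R_n | t) come
from the alignment module and are fixed.  Mean-field variational
inference with q(Z) q(theta), q(theta) = Dirichlet(alpha_hat), gives the
classic coordinate updates:

  VBE:  resp(n,t) ∝ P(R_n|t) * exp(psi(alpha_hat_t) - psi(sum alpha_hat))
        r_hat_t = sum_n resp(n,t)
  VBM:  alpha_hat_t = alpha0 + r_hat_t ;  E[theta_t] = alpha_hat_t / sum alpha_hat

iterated until the expected read counts r_hat stop moving.  alpha0 is
chosen from a small grid as the maximiser of the final evidence lower
bound (ELBO), a lower bound on the log marginal likelihood of the reads.

The estimator follows the scikit-learn convention (``fit`` on the
likelihood matrix, fitted attributes with trailing underscores) and the
individual updates are also exposed as functions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import sparse
from scipy.special import digamma, gammaln, xlogy
from sklearn.base import BaseEstimator
from sklearn.exceptions import ConvergenceWarning

from .alignment import ReadLikelihoodMatrix

__all__ = [
    "PriorConfig",
    "PosteriorState",
    "DirichletMultinomialVB",
    "vbe_step",
    "vbm_step",
    "elbo",
    "run_vb",
    "select_alpha0",
]

DEFAULT_ALPHA0_GRID = (0.01, 0.1, 0.2, 0.5, 1.0)


@dataclass(frozen=True)
class PriorConfig:
    """Dirichlet prior and convergence settings.

    alpha0: symmetric Dirichlet hyperparameter (> 0), or None to select
        it from ``alpha0_grid`` by maximising the final ELBO.
    tol: convergence tolerance on the max absolute change of the
        expected read counts r_hat (in reads).
    """

    alpha0: float | None = None
    alpha0_grid: tuple[float, ...] = DEFAULT_ALPHA0_GRID
    tol: float = 0.01
    max_iter: int = 1000

    def __post_init__(self) -> None:
        if self.alpha0 is not None and self.alpha0 <= 0:
            raise ValueError(f"alpha0 must be > 0, got {self.alpha0}")
        if self.tol <= 0:
            raise ValueError(f"tol must be > 0, got {self.tol}")
        if not self.alpha0_grid or any(a <= 0 for a in self.alpha0_grid):
            raise ValueError("alpha0_grid must be non-empty and positive")


@dataclass
class PosteriorState:
    """Converged (or final) variational posterior.

    alpha_hat[t] = alpha0 + r_hat[t]; theta_mean is the Dirichlet
    posterior mean E[theta]; responsibilities is the sparse E[Z_nt]
    matrix with the same sparsity pattern as the likelihood matrix.
    """

    alpha0: float
    alpha_hat: np.ndarray
    r_hat: np.ndarray
    theta_mean: np.ndarray
    responsibilities: sparse.csr_matrix
    elbo_trace: list[float]
    n_iter: int
    converged: bool

    @property
    def elbo(self) -> float:
        return self.elbo_trace[-1]

    def theta_sd(self) -> np.ndarray:
        """Posterior standard deviation of theta under Dirichlet(alpha_hat)."""
        a = self.alpha_hat
        s = a.sum()
        return np.sqrt(a * (s - a) / (s * s * (s + 1.0)))


def _as_csr(matrix) -> sparse.csr_matrix:
    if isinstance(matrix, ReadLikelihoodMatrix):
        return matrix.loglik
    m = sparse.csr_matrix(matrix)
    if m.nnz and m.data.max() > 1e-12:
        raise ValueError("log-likelihood entries must be <= 0")
    return m


def _row_index(mat: sparse.csr_matrix) -> np.ndarray:
    return np.repeat(np.arange(mat.shape[0], dtype=np.intp), np.diff(mat.indptr))


def _dirichlet_kl(alpha_hat: np.ndarray, alpha0: float) -> float:
    """KL( Dirichlet(alpha_hat) || Dirichlet(alpha0 * 1) )."""
    T = alpha_hat.size
    dig = digamma(alpha_hat) - digamma(alpha_hat.sum())
    return float(
        gammaln(alpha_hat.sum()) - gammaln(alpha_hat).sum()
        - gammaln(T * alpha0) + T * gammaln(alpha0)
        + ((alpha_hat - alpha0) * dig).sum()
    )


def vbe_step(matrix, alpha_hat: np.ndarray):
    """One VBE update: responsibilities and expected counts given alpha_hat.

    resp(n,t) ∝ P(R_n|t) exp(psi(alpha_hat_t) - psi(sum alpha_hat)),
    normalised over t per read in log space with per-read max
    subtraction; r_hat_t = sum_n resp(n,t).
    """
    mat = _as_csr(matrix)
    alpha_hat = np.asarray(alpha_hat, dtype=float)
    if np.any(alpha_hat <= 0):
        raise ValueError("alpha_hat must be strictly positive")
    rows = _row_index(mat)
    dig = digamma(alpha_hat) - digamma(alpha_hat.sum())
    resp_data, r_hat = _vbe_data(mat.data, mat.indices, mat.indptr, rows, dig,
                                 mat.shape[1])
    resp = sparse.csr_matrix((resp_data, mat.indices.copy(), mat.indptr.copy()),
                             shape=mat.shape)
    return resp, r_hat


def _vbe_data(data, cols, indptr, rows, dig, T):
    w = data + dig[cols]
    m = np.maximum.reduceat(w, indptr[:-1])
    p = np.exp(w - m[rows])
    s = np.add.reduceat(p, indptr[:-1])
    resp = p / s[rows]
    if not np.all(np.isfinite(resp)):
        raise FloatingPointError("non-finite responsibilities in VBE step")
    r_hat = np.bincount(cols, weights=resp, minlength=T)
    return resp, r_hat


def vbm_step(r_hat: np.ndarray, alpha0: float):
    """One VBM update: alpha_hat = alpha0 + r_hat, theta posterior mean."""
    if alpha0 <= 0:
        raise ValueError(f"alpha0 must be > 0, got {alpha0}")
    r_hat = np.asarray(r_hat, dtype=float)
    if np.any(r_hat < 0):
        raise ValueError("r_hat must be elementwise >= 0")
    alpha_hat = alpha0 + r_hat
    theta_mean = alpha_hat / alpha_hat.sum()
    return alpha_hat, theta_mean


def elbo(matrix, responsibilities, alpha_hat: np.ndarray, alpha0: float) -> float:
    """Evidence lower bound E_q[log p(R,Z,theta)] - E_q[log q(Z,theta)]."""
    mat = _as_csr(matrix)
    resp = sparse.csr_matrix(responsibilities)
    alpha_hat = np.asarray(alpha_hat, dtype=float)
    dig = digamma(alpha_hat) - digamma(alpha_hat.sum())
    r_hat = np.bincount(resp.indices, weights=resp.data, minlength=mat.shape[1])
    value = (
        float(resp.data @ mat.data)
        + float(r_hat @ dig)
        - float(xlogy(resp.data, resp.data).sum())
        - _dirichlet_kl(alpha_hat, alpha0)
    )
    if not np.isfinite(value):
        raise FloatingPointError(f"non-finite ELBO: {value}")
    return value


def _fit_single(mat: sparse.csr_matrix, alpha0: float, tol: float,
                max_iter: int) -> PosteriorState:
    N, T = mat.shape
    if N == 0:
        raise ValueError("cannot run inference on an empty likelihood matrix")
    data, cols, indptr = mat.data, mat.indices, mat.indptr
    rows = _row_index(mat)
    per_row = np.diff(indptr)

    # equal split of each read over its hit alleles
    r_hat = np.bincount(cols, weights=1.0 / per_row[rows], minlength=T)
    elbo_trace: list[float] = []
    converged = False
    n_iter = 0
    resp_data = None
    alpha_hat = alpha0 + r_hat
    for n_iter in range(1, max_iter + 1):
        dig = digamma(alpha_hat) - digamma(alpha_hat.sum())
        resp_data, r_new = _vbe_data(data, cols, indptr, rows, dig, T)
        alpha_hat = alpha0 + r_new
        dig_new = digamma(alpha_hat) - digamma(alpha_hat.sum())
        bound = (
            float(resp_data @ data)
            + float(r_new @ dig_new)
            - float(xlogy(resp_data, resp_data).sum())
            - _dirichlet_kl(alpha_hat, alpha0)
        )
        if not np.isfinite(bound):
            raise FloatingPointError("non-finite ELBO during VB iteration")
        elbo_trace.append(bound)
        delta = float(np.max(np.abs(r_new - r_hat)))
        r_hat = r_new
        if delta < tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"VB did not converge in {max_iter} iterations (alpha0={alpha0})",
            ConvergenceWarning,
        )
    theta_mean = alpha_hat / alpha_hat.sum()
    resp = sparse.csr_matrix((resp_data, cols.copy(), indptr.copy()), shape=mat.shape)
    return PosteriorState(alpha0=alpha0, alpha_hat=alpha_hat, r_hat=r_hat,
                          theta_mean=theta_mean, responsibilities=resp,
                          elbo_trace=elbo_trace, n_iter=n_iter, converged=converged)


class DirichletMultinomialVB(BaseEstimator):
    """Scikit-learn style estimator for VB read-to-allele assignment.

    Parameters
    ----------
    alpha0 : float or None
        Symmetric Dirichlet hyperparameter.  ``None`` (default) selects
        it from ``alpha0_grid`` by maximising the final ELBO, ties going
        to the smaller value.
    alpha0_grid : sequence of float
        Candidate hyperparameters for selection.
    tol : float
        Convergence tolerance: max absolute change in expected read
        counts, in reads.
    max_iter : int
        Iteration cap; non-convergence warns rather than raises.

    Attributes
    ----------
    alpha0_ : selected (or given) hyperparameter.
    alpha0_elbos_ : dict mapping each grid value to its final ELBO
        (only when selection ran).
    r_ : expected read counts r_hat per allele.
    alpha_ : Dirichlet posterior parameters alpha0 + r_hat.
    theta_ : posterior mean relative abundances (sums to 1).
    responsibilities_ : sparse E[Z_nt], rows summing to 1.
    elbo_trace_, elbo_, n_iter_, converged_ : fit diagnostics.
    """

    def __init__(self, alpha0: float | None = None,
                 alpha0_grid: Sequence[float] = DEFAULT_ALPHA0_GRID,
                 tol: float = 0.01, max_iter: int = 1000):
        self.alpha0 = alpha0
        self.alpha0_grid = alpha0_grid
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y=None):
        mat = _as_csr(X)
        if np.any(np.diff(mat.indptr) == 0):
            raise ValueError("every read (row) must have at least one hit")
        if self.alpha0 is not None:
            state = _fit_single(mat, float(self.alpha0), self.tol, self.max_iter)
            self.alpha0_elbos_ = {float(self.alpha0): state.elbo}
        else:
            grid = sorted(set(float(a) for a in self.alpha0_grid))
            if not grid:
                raise ValueError("alpha0_grid is empty")
            elbos: dict[float, float] = {}
            best_state = None
            errors: list[Exception] = []
            for a0 in grid:
                try:
                    st = _fit_single(mat, a0, self.tol, self.max_iter)
                except (FloatingPointError, ValueError) as exc:  # pragma: no cover
                    errors.append(exc)
                    continue
                elbos[a0] = st.elbo
                # strict > with ascending grid breaks ties toward smaller alpha0
                if best_state is None or st.elbo > best_state.elbo:
                    best_state = st
            if best_state is None:
                raise RuntimeError(f"all alpha0 grid points failed: {errors}")
            state = best_state
            self.alpha0_elbos_ = elbos
        self.state_ = state
        self.alpha0_ = state.alpha0
        self.r_ = state.r_hat
        self.alpha_ = state.alpha_hat
        self.theta_ = state.theta_mean
        self.responsibilities_ = state.responsibilities
        self.elbo_trace_ = state.elbo_trace
        self.elbo_ = state.elbo
        self.n_iter_ = state.n_iter
        self.converged_ = state.converged
        return self

    def fit_predict(self, X, y=None) -> np.ndarray:
        """Fit, then return the MAP allele index per read."""
        self.fit(X)
        resp = self.responsibilities_
        out = np.empty(resp.shape[0], dtype=np.intp)
        for n in range(resp.shape[0]):
            sl = slice(resp.indptr[n], resp.indptr[n + 1])
            out[n] = resp.indices[sl][np.argmax(resp.data[sl])]
        return out


def run_vb(matrix, config: PriorConfig = PriorConfig(alpha0=1.0)) -> PosteriorState:
    """Run VB to convergence at a fixed alpha0 (see :class:`PriorConfig`)."""
    if config.alpha0 is None:
        raise ValueError("run_vb requires a fixed alpha0; use select_alpha0 for the grid")
    return _fit_single(_as_csr(matrix), config.alpha0, config.tol, config.max_iter)


def select_alpha0(matrix, config: PriorConfig = PriorConfig()):
    """ELBO-maximising alpha0 over the grid; ties to the smaller value.

    Returns ``(best_alpha0, {alpha0: final_elbo})``.
    """
    est = DirichletMultinomialVB(alpha0=None, alpha0_grid=config.alpha0_grid,
                                 tol=config.tol, max_iter=config.max_iter)
    est.fit(matrix)
    return est.alpha0_, est.alpha0_elbos_
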