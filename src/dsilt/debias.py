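"""AC-side debiasing: projection directions, debiased estimates, variances
and the chi-square group statistics.

For each tested covariate j the projection directions u_j^(m) solve the
group Dantzig selector program

    min  max_m ||u^(m)||_1
    s.t. || (H_t^(m) u^(m) - e_j)_l over m ||_2  <=  tau   for every l,

with the second-round Hessians H_t as blocks.  The debiased estimate adds
the one-step correction u' (xi_t - H_t beta_tilde) to the integrative
coefficient, averaged over the K outer folds; its variance uses the
sandwich meat J_t.  The group statistic

    zeta_j = sum_m n_m (breve beta_j^(m) / sigma_hat_j^(m))^2

is asymptotically chi-square with M degrees of freedom under the null.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from ._opt import DantzigInfeasibleError, DantzigSolution, solve_dantzig_pdhg

__all__ = [
    "ProjectionDirections",
    "DebiasResult",
    "solve_group_dantzig",
    "solve_group_dantzig_batch",
    "fold_terms",
    "debias_coefficients",
    "estimate_variance",
    "group_statistic",
    "DantzigInfeasibleError",
]

SIGMA_FLOOR = 1e-12


@dataclass(frozen=True)
class ProjectionDirections:
    """Directions for one target coordinate, with a feasibility certificate.

    ``U`` is M x (p+1); ``max_residual`` is the constraint residual
    recomputed directly from (H, U) after the solve, independent of any
    solver bookkeeping.
    """

    U: np.ndarray
    tau: float
    objective: float
    max_residual: float


@dataclass(frozen=True)
class DebiasResult:
    """Per-(study, target) debiased estimates and the pooled group statistics."""

    beta_breve: np.ndarray  # (M, q)
    sigma_hat: np.ndarray   # (M, q)
    zeta: np.ndarray        # (q,)
    targets: np.ndarray     # tested column indices (q,)


def _certify(H: np.ndarray, U: np.ndarray, j: int) -> float:
    """Residual max_l ||(H^(m)u^(m) - e_j)_l||_2, written out longhand."""
    R = np.stack([H[m] @ U[m] for m in range(H.shape[0])])
    R[:, j] -= 1.0
    return float(np.sqrt((R**2).sum(axis=0)).max())


def solve_group_dantzig(H_blocks, j: int, tau: float, **kwargs) -> ProjectionDirections:
    """Solve the group Dantzig program for a single target coordinate."""
    H = np.stack([np.asarray(h, dtype=float) for h in H_blocks])
    sol = solve_dantzig_pdhg(H, np.array([j]), tau, **kwargs)
    U = sol.U[:, :, 0]
    return ProjectionDirections(
        U=U, tau=float(tau), objective=float(sol.objective[0]),
        max_residual=_certify(H, U, j),
    )


def solve_group_dantzig_batch(
    H_blocks, targets, tau: float, state=None, **kwargs
) -> DantzigSolution:
    """Batched solve over all targets; reuses PDHG state for warm starts."""
    H = np.stack([np.asarray(h, dtype=float) for h in H_blocks])
    return solve_dantzig_pdhg(H, np.asarray(targets), tau, state=state, **kwargs)


def fold_terms(beta_tilde_per_fold, U_per_fold, step2_per_fold, targets) -> np.ndarray:
    """Per-fold debiasing terms T[k, m, j] = beta_tilde_j + u' (xi_t - H_t beta_tilde).

    ``U_per_fold[k]`` has shape (M, P, q); ``step2_per_fold[k]`` is the list
    of per-study second-round summaries for fold k.
    """
    K = len(beta_tilde_per_fold)
    if not (len(U_per_fold) == len(step2_per_fold) == K):
        raise ValueError("fold-wise inputs are misaligned")
    targets = np.asarray(targets, dtype=int)
    M = U_per_fold[0].shape[0]
    T = np.empty((K, M, targets.size))
    for k in range(K):
        Bt = beta_tilde_per_fold[k]
        for m in range(M):
            s2 = step2_per_fold[k][m]
            r = s2.xi_t - s2.H_t @ Bt[m]
            T[k, m] = Bt[m, targets] + U_per_fold[k][m].T @ r
    return T


def debias_coefficients(
    beta_tilde_per_fold, U_per_fold, step2_per_fold, targets
) -> np.ndarray:
    """Cross-fitted debiased estimator: equal-weight average over folds."""
    return fold_terms(beta_tilde_per_fold, U_per_fold, step2_per_fold, targets).mean(axis=0)


def estimate_variance(U_per_fold, step2_per_fold) -> np.ndarray:
    """(sigma_hat^(m))^2 = K^{-1} sum_k u' J_t u, floored at a tiny positive value."""
    K = len(U_per_fold)
    M, _, q = U_per_fold[0].shape
    S = np.zeros((M, q))
    for k in range(K):
        for m in range(M):
            J = step2_per_fold[k][m].J_t
            U = U_per_fold[k][m]
            S[m] += np.einsum("pj,pq,qj->j", U, J, U)
    S /= K
    if np.any(S < SIGMA_FLOOR):
        warnings.warn("variance estimates floored at 1e-12")
        S = np.maximum(S, SIGMA_FLOOR)
    return S


def group_statistic(beta_breve: np.ndarray, sigma2_hat: np.ndarray, n_m) -> np.ndarray:
    """zeta_j = sum_m n_m (beta_breve / sigma_hat)^2 (>= 0, chi2_M under null)."""
    if np.any(sigma2_hat <= 0):
        raise ValueError("sigma_hat must be positive")
    n_m = np.asarray(n_m, dtype=float)[:, None]
    return (n_m * beta_breve**2 / sigma2_hat).sum(axis=0)
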