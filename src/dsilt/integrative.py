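"""AC-side integrative estimation from first-round summaries.

The analysis computer never sees raw rows: the multi-study coefficient
matrix is estimated by minimizing the summary-statistic quadratic

    sum_m w_m (beta^(m)' H_hat^(m) beta^(m) - 2 beta^(m)' xi_hat^(m))
        + lam * sum_{j >= 1} ||beta_j||_2,       w_m = |I^(m)| / |I^(.)|,

whose groups are the M-vectors beta_j of one covariate's coefficients
across studies (the intercept column is unpenalized).  For the linear
family the quadratic is an exact sufficient statistic, so this fit
coincides with the pooled individual-level group LASSO; for other families
it is the one-step quadratic approximation around the local fits.

The penalty level is chosen by a generalized information criterion
GIC = Dev + gamma * DF computed from the same summaries, with the BIC
scaling gamma = log|I| / |I| as default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.linalg import solve as dense_solve

from ._opt import group_lasso_bcd, group_lasso_objective
from .families import adjust, get_family
from .local_site import SummaryStep1

__all__ = [
    "GicReport",
    "fit_group_lasso",
    "gic",
    "select_lambda",
    "fit_group_lasso_individual",
    "select_lambda_individual",
]


def _stack(summaries) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    for s in summaries:
        if not isinstance(s, SummaryStep1):
            raise TypeError(
                "integrative estimation accepts SummaryStep1 payloads only "
                f"(got {type(s).__name__}); raw data never crosses the study boundary"
            )
    ps = {s.xi.shape[0] for s in summaries}
    if len(ps) != 1:
        raise ValueError("summaries disagree on the covariate dimension")
    H = np.ascontiguousarray(np.stack([s.H for s in summaries]))
    xi = np.ascontiguousarray(np.stack([s.xi for s in summaries]))
    n = np.array([s.n_used for s in summaries], dtype=float)
    return H, xi, n / n.sum()


def _check_psd(H: np.ndarray, tol: float = 1e-8) -> None:
    for m in range(H.shape[0]):
        if not np.allclose(H[m], H[m].T, atol=1e-10):
            raise ValueError(f"H block {m} is not symmetric")
        lo = np.linalg.eigvalsh(H[m])[0]
        if lo < -tol * max(1.0, np.abs(H[m]).max()):
            raise ValueError(f"H block {m} is not PSD (min eigenvalue {lo:.3g})")


def fit_group_lasso(
    summaries,
    lam: float,
    init: np.ndarray | None = None,
    tol: float = 1e-7,
    max_sweeps: int = 5000,
    validate: bool = True,
) -> np.ndarray:
    """Group-LASSO integrative estimator from per-study summaries.

    Returns the M x (p+1) coefficient matrix.  Cyclic block coordinate
    descent with exact group prox steps; the objective is monotone
    nonincreasing across sweeps and iteration stops when the largest
    coefficient update falls below ``tol``.
    """
    if lam < 0:
        raise ValueError("lam must be >= 0")
    H, xi, w = _stack(summaries)
    if validate:
        _check_psd(H)
    M, P = xi.shape
    B = np.zeros((M, P)) if init is None else np.array(init, dtype=float)
    penalize = np.ones(P, dtype=np.bool_)
    penalize[0] = False
    sweeps, delta = group_lasso_bcd(H, xi, w, lam, penalize, B, max_sweeps, tol)
    if sweeps >= max_sweeps and delta >= tol:
        warnings.warn(
            f"group LASSO did not converge in {max_sweeps} sweeps "
            f"(last update {delta:.2e}); returning best iterate"
        )
    return B


@dataclass(frozen=True)
class GicReport:
    """Deviance / degrees-of-freedom decomposition of the GIC at one lam."""

    dev: float
    df: float
    gamma: float
    value: float


def _bic_gamma(summaries) -> float:
    n_tot = sum(s.n_used for s in summaries)
    return np.log(n_tot) / n_tot


def gic(summaries, beta: np.ndarray, lam: float, gamma: float | None = None) -> GicReport:
    """Generalized information criterion from summary data only.

    Dev is the summary quadratic at ``beta``; DF is the trace of the matrix
    ratio of the active-set Hessians of the penalized and unpenalized
    objectives (the scalar reading of the displayed degrees-of-freedom
    measure).  ``gamma`` defaults to the BIC scaling log|I|/|I|.
    """
    H, xi, w = _stack(summaries)
    if gamma is None:
        gamma = _bic_gamma(summaries)
    M, P = xi.shape
    dev = group_lasso_objective(H, xi, w, 0.0, np.zeros(P, dtype=bool), beta)
    active = [(m, j) for j in range(P) for m in range(M) if beta[m, j] != 0.0]
    if not active:
        return GicReport(dev=dev, df=0.0, gamma=gamma, value=dev)
    d = len(active)
    A = np.zeros((d, d))
    Pen = np.zeros((d, d))
    gnorm = np.linalg.norm(beta, axis=0)
    for a, (m, j) in enumerate(active):
        for b, (m2, j2) in enumerate(active):
            if m == m2:
                A[a, b] = 2.0 * w[m] * H[m, j, j2]
            if j == j2 and j >= 1:  # group-penalty curvature couples studies
                rho = gnorm[j]
                Pen[a, b] = lam * (
                    (1.0 if m == m2 else 0.0) / rho
                    - beta[m, j] * beta[m2, j] / rho**3
                )
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error")  # treat ill-conditioning as failure
            df = float(np.trace(dense_solve(A + Pen, A, assume_a="sym")))
        if not np.isfinite(df):
            raise np.linalg.LinAlgError
    except (np.linalg.LinAlgError, Warning):
        warnings.warn("singular restricted Hessian in GIC; using ridge-stabilized inverse")
        ridge = 1e-8 * max(np.trace(A + Pen) / d, 1.0)
        df = float(np.trace(np.linalg.solve(A + Pen + ridge * np.eye(d), A)))
    return GicReport(dev=dev, df=df, gamma=gamma, value=dev + gamma * df)


def _default_integrative_grid(summaries, n_points: int = 15, decades: float = 2.5):
    """lam path from the smallest lam nulling every group, log-spaced down."""
    H, xi, w = _stack(summaries)
    M, P = xi.shape
    B = np.zeros((M, P))
    B[:, 0] = np.where(H[:, 0, 0] > 0, xi[:, 0] / np.where(H[:, 0, 0] > 0, H[:, 0, 0], 1.0), 0.0)
    grad = 2.0 * w[:, None] * (H @ B[:, :, None] - xi[:, :, None])[:, :, 0]
    lam_max = np.linalg.norm(grad[:, 1:], axis=0).max() * 1.02
    return lam_max * np.logspace(0.0, -decades, n_points)


def select_lambda(
    summaries,
    grid: np.ndarray | None = None,
    gamma: float | None = None,
) -> tuple[float, np.ndarray, list[GicReport]]:
    """GIC-minimizing penalty for the integrative fit.

    Returns (lam, coefficient matrix, per-grid-point GIC reports); the grid
    is traversed from large to small lam with warm starts, and ties break
    toward the larger lam (sparser model).
    """
    if grid is None:
        grid = _default_integrative_grid(summaries)
    grid = np.sort(np.asarray(grid, dtype=float))[::-1]
    if grid.size == 0:
        raise ValueError("lambda grid must be nonempty")
    if gamma is None:
        gamma = _bic_gamma(summaries)
    _check_psd(_stack(summaries)[0])
    best = None
    reports = []
    B = None
    worse = 0
    for lam in grid:
        B = fit_group_lasso(summaries, lam, init=B, validate=False)
        rep = gic(summaries, B, lam, gamma)
        reports.append(rep)
        if best is None or rep.value < best[2] - 1e-12:
            best = (float(lam), B.copy(), rep.value)
            worse = 0
        else:
            # glmnet-style early exit: once the criterion has moved off its
            # minimum for several consecutive steps the lower (overfitting,
            # increasingly ill-conditioned) end of the path is pointless
            worse += 1
            if worse >= 4:
                break
    return best[0], best[1], reports


# ---------------------------------------------------------------------------
# individual-level counterpart (the ILMA benchmark shares this machinery)


def fit_group_lasso_individual(
    XY_pairs,
    family,
    lam: float,
    init: np.ndarray | None = None,
    max_irls: int = 50,
    tol: float = 1e-8,
):
    """Pooled individual-level group-LASSO GLM fit (prox-Newton).

    ``XY_pairs`` is a list of (X, Y) per study.  Each iteration rebuilds the
    adjusted moments at the current coefficients (exact for the linear
    family, where a single pass suffices) and calls the same group-CD kernel
    as the summary-based fit.  Returns (B, surrogate SummaryStep1 list at
    the solution).
    """
    fam = get_family(family)
    M = len(XY_pairs)
    P = XY_pairs[0][0].shape[1]
    n = np.array([X.shape[0] for X, _ in XY_pairs], dtype=float)
    w = n / n.sum()
    penalize = np.ones(P, dtype=np.bool_)
    penalize[0] = False
    B = np.zeros((M, P)) if init is None else np.array(init, dtype=float)
    summaries = None
    for _ in range(max_irls):
        H = np.empty((M, P, P))
        xi = np.empty((M, P))
        for m, (X, Y) in enumerate(XY_pairs):
            adj = adjust(X, Y, B[m], fam)
            H[m] = adj.Xb.T @ adj.Xb / X.shape[0]
            xi[m] = adj.Xb.T @ adj.Yb / X.shape[0]
        summaries = [
            SummaryStep1(n_used=int(n[m]), xi=xi[m], H=H[m]) for m in range(M)
        ]
        Bold = B.copy()
        group_lasso_bcd(H, xi, w, lam, penalize, B, 5000, 1e-9)
        if fam.name == "linear" or np.max(np.abs(B - Bold)) < tol:
            return B, summaries
    warnings.warn("individual-level group LASSO did not converge; best iterate returned")
    return B, summaries


def select_lambda_individual(
    XY_pairs,
    family,
    grid: np.ndarray | None = None,
    gamma: float | None = None,
):
    """GIC-tuned pooled individual-level fit, mirroring :func:`select_lambda`."""
    fam = get_family(family)
    _, summ0 = fit_group_lasso_individual(XY_pairs, fam, lam=1e12)
    if grid is None:
        grid = _default_integrative_grid(summ0)
    grid = np.sort(np.asarray(grid, dtype=float))[::-1]
    if gamma is None:
        gamma = _bic_gamma(summ0)
    best = None
    B = None
    worse = 0
    for lam in grid:
        B, summ = fit_group_lasso_individual(XY_pairs, fam, lam, init=B)
        rep = gic(summ, B, lam, gamma)
        if best is None or rep.value < best[2] - 1e-12:
            best = (float(lam), B.copy(), rep.value)
            worse = 0
        else:
            worse += 1
            if worse >= 4:
                break
    return best[0], best[1]
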