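"""Everything computed at a data computer (DC).

A DC holds one study's raw rows and never ships them anywhere.  What it
does ship, per outer fold k, are

* first-round summaries (xi_hat, H_hat): inner-cross-fitted adjusted
  cross-moments built around the site's own l1-penalized GLM fit, and
* second-round summaries (xi_t, H_t, J_t): plain held-out-fold moments
  evaluated at the integrative estimate received back from the analysis
  computer.

Both payloads are O(p^2) dense matrices plus a p-vector -- the entire
DataSHIELD message budget of the procedure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from ._opt import group_lasso_bcd
from .families import adjust, get_family, loss
from .synth import StudyData

__all__ = [
    "FoldPlan",
    "SummaryStep1",
    "SummaryStep2",
    "make_folds",
    "fit_l1_glm",
    "select_local_lambda",
    "fit_local_lasso",
    "summary_step1",
    "summary_step2",
    "save_summary",
    "load_summary",
]

PAYLOAD_SCHEMA_VERSION = 1


@dataclass(frozen=True)
class FoldPlan:
    """Outer/inner sample-splitting plan for one study.

    ``outer[i]`` is the outer fold (0..K-1) of observation i; ``inner[k, i]``
    its inner fold (0..Kp-1) within the training complement of outer fold k,
    or -1 when observation i belongs to outer fold k itself.
    """

    K: int
    Kp: int
    outer: np.ndarray
    inner: np.ndarray

    def outer_idx(self, k: int) -> np.ndarray:
        return np.flatnonzero(self.outer == k)

    def train_idx(self, k: int) -> np.ndarray:
        return np.flatnonzero(self.outer != k)

    def inner_idx(self, k: int, kp: int) -> np.ndarray:
        return np.flatnonzero(self.inner[k] == kp)


def make_folds(n: int, K: int, Kp: int, seed) -> FoldPlan:
    """Deterministic near-equal K outer / Kp inner fold assignment.

    K must be even: the null-calibration device used for tau selection
    contrasts the first K/2 folds against the last K/2.
    """
    if K < 2 or K % 2 != 0:
        raise ValueError("K must be an even integer >= 2 (the tau-selection "
                         "null contrast needs two half-samples)")
    if Kp < 2:
        raise ValueError("Kp must be >= 2")
    if n < K * Kp:
        raise ValueError("need n >= K * Kp observations")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    outer_rng, inner_rng = (np.random.default_rng(c) for c in ss.spawn(2))
    outer = np.empty(n, dtype=np.int64)
    perm = outer_rng.permutation(n)
    outer[perm] = np.arange(n) % K
    inner = np.full((K, n), -1, dtype=np.int64)
    for k in range(K):
        tr = np.flatnonzero(outer != k)
        perm = inner_rng.permutation(tr.size)
        inner[k, tr[perm]] = np.arange(tr.size) % Kp
    return FoldPlan(K=K, Kp=Kp, outer=outer, inner=inner)


@dataclass(frozen=True)
class SummaryStep1:
    """First-round DC -> AC payload: {|I_-k|, xi_hat, H_hat}."""

    n_used: int
    xi: np.ndarray
    H: np.ndarray


@dataclass(frozen=True)
class SummaryStep2:
    """Second-round DC -> AC payload: held-out moments at the integrative fit."""

    n_used: int
    xi_t: np.ndarray
    H_t: np.ndarray
    J_t: np.ndarray


# ---------------------------------------------------------------------------
# l1-penalized GLM at a single site (prox-Newton around the group-CD kernel)


def fit_l1_glm(
    X: np.ndarray,
    Y: np.ndarray,
    family,
    lam: float,
    init: np.ndarray | None = None,
    max_irls: int = 50,
    tol: float = 1e-8,
    inner_tol: float = 1e-9,
    max_sweeps: int = 5000,
) -> np.ndarray:
    """LASSO GLM fit with unpenalized intercept at a fixed penalty level.

    Iteratively reweighted quadratic surrogates (whose sufficient statistics
    are exactly the adjusted moments X_b'X_b/n and X_b'Y_b/n) are minimized
    by coordinate descent; at a fixed point the surrogate's KKT conditions
    coincide with those of the penalized GLM loss.
    """
    fam = get_family(family)
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    n, P = X.shape
    beta = np.zeros(P) if init is None else np.array(init, dtype=float)
    penalize = np.ones(P, dtype=np.bool_)
    penalize[0] = False
    w = np.ones(1)
    for _ in range(max_irls):
        adj = adjust(X, Y, beta, fam)
        H = (adj.Xb.T @ adj.Xb / n)[None]
        xi = (adj.Xb.T @ adj.Yb / n)[None]
        B = beta[None].copy()
        # the kernel's quadratic is twice the loss, so the l1 level doubles
        group_lasso_bcd(H, xi, w, 2.0 * lam, penalize, B, max_sweeps, inner_tol)
        delta = np.max(np.abs(B[0] - beta))
        beta = B[0]
        if fam.name == "linear" or delta < tol:
            return beta
    warnings.warn("l1 GLM fit did not converge; returning best iterate")
    return beta


def _default_lam_grid(X, Y, family, n_points=12, decades=2.0) -> np.ndarray:
    """Data-driven penalty path from lam_max (all-zero active set) downward.

    lam_max is the sup-norm of the loss gradient at the intercept-only fit;
    the grid spans 10^-decades below it, log-spaced, which brackets the
    sqrt(log p / n) theoretical rate for the designs of interest.
    """
    fam = get_family(family)
    n = X.shape[0]
    beta0 = fit_l1_glm(X, Y, fam, lam=1e12)  # intercept-only null fit
    grad = X.T @ (fam.phidot(X @ beta0) - Y) / n
    lam_max = np.max(np.abs(grad[1:])) * 1.02
    return lam_max * np.logspace(0.0, -decades, n_points)


def select_local_lambda(
    X: np.ndarray,
    Y: np.ndarray,
    family,
    lam_grid: np.ndarray | None = None,
    cv_folds: int = 5,
    seed=0,
) -> tuple[float, np.ndarray]:
    """Pick the site's l1 penalty by cv_folds-fold CV on held-out deviance.

    Returns (lam_selected, cv_curve); ties break toward the larger lam.
    """
    fam = get_family(family)
    if lam_grid is None:
        lam_grid = _default_lam_grid(X, Y, fam)
    lam_grid = np.sort(np.asarray(lam_grid, dtype=float))[::-1]
    if lam_grid.size == 0:
        raise ValueError("lam_grid must be nonempty")
    n = X.shape[0]
    rng = np.random.default_rng(seed)
    fold = np.empty(n, dtype=int)
    fold[rng.permutation(n)] = np.arange(n) % cv_folds
    cv = np.zeros(lam_grid.size)
    for f in range(cv_folds):
        tr, va = fold != f, fold == f
        beta = None
        for i, lam in enumerate(lam_grid):
            beta = fit_l1_glm(
                X[tr], Y[tr], fam, lam, init=beta,
                max_irls=15, tol=1e-6, inner_tol=1e-8,
            )
            cv[i] += loss(beta, X[va], Y[va], fam) * va.sum()
    cv /= n
    best = int(np.argmin(cv))  # grid sorted descending: first minimum = largest lam
    return float(lam_grid[best]), cv


def fit_local_lasso(
    X: np.ndarray,
    Y: np.ndarray,
    family,
    lam_grid: np.ndarray | None = None,
    cv_folds: int = 5,
    seed=0,
) -> np.ndarray:
    """CV-tuned local LASSO estimator (the site's own sparse GLM fit)."""
    lam, _ = select_local_lambda(X, Y, family, lam_grid, cv_folds, seed)
    return fit_l1_glm(X, Y, family, lam)


# ---------------------------------------------------------------------------
# summary statistics


def summary_step1(
    study: StudyData,
    plan: FoldPlan,
    k: int,
    family,
    lam: float | None = None,
    cv_folds: int = 5,
    seed=0,
) -> SummaryStep1:
    """Inner-cross-fitted first-round summaries on the training complement.

    For each inner fold, the site's l1 GLM is trained on the remaining inner
    folds and the adjusted moments are evaluated on the held-out inner fold;
    xi_hat and H_hat are the equal-weight averages of the per-fold means.
    """
    fam = get_family(family)
    if not 0 <= k < plan.K:
        raise ValueError(f"fold index k={k} outside [0, {plan.K})")
    X, Y = study.X, study.Y
    if lam is None:
        lam, _ = select_local_lambda(X, Y, fam, cv_folds=cv_folds, seed=seed)
    P = X.shape[1]
    xi = np.zeros(P)
    H = np.zeros((P, P))
    beta = None
    for kp in range(plan.Kp):
        ev = plan.inner_idx(k, kp)
        tr = np.flatnonzero((plan.inner[k] >= 0) & (plan.inner[k] != kp))
        beta = fit_l1_glm(X[tr], Y[tr], fam, lam, init=beta)
        adj = adjust(X[ev], Y[ev], beta, fam)
        xi += adj.Xb.T @ adj.Yb / ev.size
        H += adj.Xb.T @ adj.Xb / ev.size
    xi /= plan.Kp
    H /= plan.Kp
    return SummaryStep1(n_used=int(plan.train_idx(k).size), xi=xi, H=H)


def summary_step2(
    study: StudyData,
    plan: FoldPlan,
    k: int,
    beta_tilde: np.ndarray,
    family,
) -> SummaryStep2:
    """Second-round summaries on held-out fold k at the received estimate.

    J_t deliberately uses the raw design and squared raw residuals (not the
    adjusted ones): it estimates the meat of the sandwich variance.
    """
    fam = get_family(family)
    idx = plan.outer_idx(k)
    X, Y = study.X[idx], study.Y[idx]
    n = idx.size
    adj = adjust(X, Y, beta_tilde, fam)
    resid = Y - fam.phidot(adj.theta)
    xi_t = adj.Xb.T @ adj.Yb / n
    H_t = adj.Xb.T @ adj.Xb / n
    J_t = (X * resid[:, None] ** 2).T @ X / n
    return SummaryStep2(n_used=int(n), xi_t=xi_t, H_t=H_t, J_t=J_t)


# ---------------------------------------------------------------------------
# payload (de)serialization -- the emulated DC -> AC wire format


def save_summary(summary, path) -> Path:
    """Write a summary payload as a compressed archive (schema-versioned)."""
    path = Path(path)
    if isinstance(summary, SummaryStep1):
        np.savez_compressed(
            path, kind="step1", schema=PAYLOAD_SCHEMA_VERSION,
            n_used=summary.n_used, xi=summary.xi, H=summary.H,
        )
    elif isinstance(summary, SummaryStep2):
        np.savez_compressed(
            path, kind="step2", schema=PAYLOAD_SCHEMA_VERSION,
            n_used=summary.n_used, xi_t=summary.xi_t, H_t=summary.H_t,
            J_t=summary.J_t,
        )
    else:
        raise TypeError(f"cannot serialize {type(summary).__name__}")
    return path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")


def load_summary(path):
    with np.load(path, allow_pickle=False) as z:
        if int(z["schema"]) != PAYLOAD_SCHEMA_VERSION:
            raise ValueError(f"unsupported payload schema {z['schema']}")
        if str(z["kind"]) == "step1":
            return SummaryStep1(n_used=int(z["n_used"]), xi=z["xi"], H=z["H"])
        return SummaryStep2(
            n_used=int(z["n_used"]), xi_t=z["xi_t"], H_t=z["H_t"], J_t=z["J_t"]
        )
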