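"""Normal-quantile transform, FDR thresholding and tau selection.

The group statistics are mapped to half-normal scale,
N_j = upper-Phi^{-1}( S_chi2_M(zeta_j) / 2 ), and the rejection threshold

    t_hat = inf{ 0 <= t <= t_q : 2 q Phi_bar(t) / (R(t) v 1) <= alpha },
    t_q = (2 log q - 2 log log q)^{1/2},

estimates the number of false positives by 2 q Phi_bar(t).  When no t in
the range qualifies, t_hat = (2 log q)^{1/2}: thresholding at t_q instead
would let through too many false rejections, because beyond t_q the tail
count 2 q Phi_bar(t) no longer estimates R_0(t) consistently.

tau (the Dantzig feasibility radius) is chosen by a null-calibration
device: recomputing the debiased estimates with alternating half-sample
signs cancels the signal, and the tau whose null statistics best match the
theoretical tail count over a fixed grid of upper quantiles wins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.special import gammaln, ndtri_exp

__all__ = [
    "TestOutcome",
    "TauSelectionReport",
    "normal_transform",
    "find_threshold",
    "bh_threshold",
    "error_metrics",
    "null_statistics",
    "select_tau",
]


def normal_transform(zeta: np.ndarray, M: int) -> np.ndarray:
    """N_j = Phi_bar^{-1}(S_chi2_M(zeta_j)/2), stable far into the tail.

    Works on the log scale: the chi-square log survival function stays
    finite where the plain survival probability would underflow.
    """
    zeta = np.asarray(zeta, dtype=float)
    if np.any(zeta < 0):
        raise ValueError("zeta must be nonnegative")
    with np.errstate(divide="ignore"):
        log_sf = stats.chi2.logsf(zeta, df=M)
    # beyond scipy's underflow point, switch to the chi-square tail expansion
    # sf(z) ~ (z/2)^{M/2-1} e^{-z/2} / Gamma(M/2) * (1 + (M-2)/z)
    bad = ~np.isfinite(log_sf)
    if np.any(bad):
        z = zeta[bad]
        log_sf[bad] = (
            (M / 2.0 - 1.0) * np.log(z / 2.0)
            - z / 2.0
            - gammaln(M / 2.0)
            + np.log1p(max(M - 2.0, 0.0) / np.maximum(z, 1.0))
        )
    log_half_sf = log_sf - np.log(2.0)
    return -ndtri_exp(np.minimum(log_half_sf, -np.log(2.0)))


@dataclass(frozen=True)
class TestOutcome:
    """Transformed statistics, threshold, and the rejection set."""

    N: np.ndarray
    t_hat: float
    rejected: np.ndarray  # tested-coordinate labels with N_j >= t_hat
    t_q: float
    alpha: float
    targets: np.ndarray


def _phi_bar(t):
    return stats.norm.sf(t)


def find_threshold(N: np.ndarray, alpha: float, targets=None) -> TestOutcome:
    """Exact infimum of the FDP-estimate inequality over [0, t_q].

    Within a stretch where the rejection count R(t) is constant the
    criterion 2 q Phi_bar(t) / R is continuous and decreasing, so the
    infimum is attained either at the analytic point Phi_bar^{-1}(alpha R /
    (2q)) inside the stretch or at one of the order statistics bounding it;
    all such candidates are scanned.
    """
    N = np.asarray(N, dtype=float)
    q = N.size
    if q < 2:
        raise ValueError("need at least two hypotheses")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    if targets is None:
        targets = np.arange(q)
    targets = np.asarray(targets)
    t_q = np.sqrt(max(2.0 * np.log(q) - 2.0 * np.log(np.log(q)), 0.0))
    t_max = np.sqrt(2.0 * np.log(q))

    counts = np.arange(1, q + 1, dtype=float)
    with np.errstate(over="ignore"):
        analytic = stats.norm.isf(np.minimum(alpha * counts / (2.0 * q), 0.5))
    cand = np.concatenate(([0.0, t_q], N[(N >= 0) & (N <= t_q)], analytic))
    cand = np.unique(np.clip(cand, 0.0, t_q))
    # criterion at each candidate
    Nsorted = np.sort(N)
    R = q - np.searchsorted(Nsorted, cand, side="left")
    crit = 2.0 * q * _phi_bar(cand) / np.maximum(R, 1)
    # the analytic candidates satisfy the inequality with equality: allow for
    # rounding at the boundary
    ok = crit <= alpha * (1.0 + 1e-10) + 1e-15
    t_hat = float(cand[ok][0]) if np.any(ok) else float(t_max)
    rej = targets[N >= t_hat]
    return TestOutcome(
        N=N, t_hat=t_hat, rejected=rej, t_q=float(t_q), alpha=float(alpha),
        targets=targets,
    )


def bh_threshold(N: np.ndarray, alpha: float) -> float:
    """Benjamini-Hochberg-style comparator: same inequality, unbounded range.

    Diagnostic only -- without the [0, t_q] restriction the tail count
    2 q Phi_bar(t) can stop tracking R_0(t) and FDP control may fail.
    """
    N = np.asarray(N, dtype=float)
    q = N.size
    counts = np.arange(1, q + 1, dtype=float)
    with np.errstate(over="ignore"):
        analytic = stats.norm.isf(np.minimum(alpha * counts / (2.0 * q), 0.5))
    cand = np.unique(np.concatenate(([0.0], N[N >= 0], np.maximum(analytic, 0.0))))
    Nsorted = np.sort(N)
    R = q - np.searchsorted(Nsorted, cand, side="left")
    crit = 2.0 * q * _phi_bar(cand) / np.maximum(R, 1)
    ok = crit <= alpha
    return float(cand[ok][0]) if np.any(ok) else float("inf")


def error_metrics(rejected, truth_support, H_index) -> tuple[float, float]:
    """(FDP, power) of a rejection set against the true support within H."""
    rej = set(np.asarray(rejected).tolist())
    truth = set(np.asarray(truth_support).tolist()) & set(np.asarray(H_index).tolist())
    fdp = len(rej - truth) / max(len(rej), 1)
    power = len(rej & truth) / max(len(truth), 1)
    return float(fdp), float(power)


def null_statistics(
    terms: np.ndarray, sigma2_hat: np.ndarray, n_m, K: int | None = None
) -> np.ndarray:
    """Signal-cancelling null statistics from the per-fold debiasing terms.

    ``terms`` has shape (K, M, q) -- the same per-fold quantities averaged
    by the ordinary debiased estimator -- but here the first K/2 folds enter
    with sign +1 and the last K/2 with sign -1, so any common signal
    cancels and the statistic probes pure noise.  K must be even.
    """
    terms = np.asarray(terms, dtype=float)
    K = terms.shape[0] if K is None else K
    if K % 2 != 0:
        raise ValueError("K must be even to form the half-sample null contrast")
    signs = np.where(np.arange(K) < K // 2, 1.0, -1.0)
    beta_null = np.tensordot(signs, terms, axes=(0, 0)) / K
    n_m = np.asarray(n_m, dtype=float)[:, None]
    return (n_m * beta_null**2 / sigma2_hat).sum(axis=0)


@dataclass(frozen=True)
class TauSelectionReport:
    """Calibration distances d_hat(tau) and the selected radius."""

    grid: np.ndarray
    d_hat: np.ndarray
    chosen: float
    H_grid: int
    null_stats: dict


def _calibration_distance(zeta_null: np.ndarray, M: int, q: int, H_grid: int) -> float:
    """d_hat: squared relative error of the null tail count at H upper quantiles.

    Evaluation points x_h = Phi_bar((2 log q)^{1/2}) * h / H, h = 1..H; the
    null tail count is R_0,null(t_h) = #{j : S_chi2_M(zeta_null_j) <= 2 x_h}
    and perfect calibration gives R_0,null = 2 q x_h exactly.
    """
    x = _phi_bar(np.sqrt(2.0 * np.log(q))) * np.arange(1, H_grid + 1) / H_grid
    sf = stats.chi2.sf(zeta_null, df=M)
    R0 = (sf[None, :] <= 2.0 * x[:, None]).sum(axis=1)
    return float(np.mean((R0 / (2.0 * q * x) - 1.0) ** 2))


def select_tau(
    tau_grid, zeta_null_by_tau, M: int, q: int, H_grid: int = 10
) -> TauSelectionReport:
    """Pick tau minimizing the null-calibration distance (ties -> smaller tau)."""
    tau_grid = np.asarray(tau_grid, dtype=float)
    if tau_grid.size == 0:
        raise ValueError("tau grid must be nonempty")
    order = np.argsort(tau_grid)
    d = np.array(
        [_calibration_distance(zeta_null_by_tau[t], M, q, H_grid) for t in tau_grid]
    )
    best = order[int(np.argmin(d[order]))]  # scan ascending: ties -> smaller tau
    return TauSelectionReport(
        grid=tau_grid,
        d_hat=d,
        chosen=float(tau_grid[best]),
        H_grid=H_grid,
        null_stats={float(t): np.asarray(zeta_null_by_tau[t]) for t in tau_grid},
    )
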