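"""Summary-based group-LASSO estimation and GIC tuning."""

import numpy as np
import pytest

from dsilt._opt import group_lasso_objective
from dsilt.integrative import (
    fit_group_lasso,
    fit_group_lasso_individual,
    gic,
    select_lambda,
)
from dsilt.local_site import SummaryStep1


def _random_summaries(seed, M=3, P=6, n=80, cond=None):
    """Exact linear-family summaries from synthetic raw blocks."""
    rng = np.random.default_rng(seed)
    out, raw = [], []
    for m in range(M):
        X = np.column_stack([np.ones(n), rng.standard_normal((n, P - 1))])
        beta = np.zeros(P)
        beta[1:3] = [1.0, -0.7]
        Y = X @ beta + 0.3 * rng.standard_normal(n)
        out.append(SummaryStep1(n_used=n, xi=X.T @ Y / n, H=X.T @ X / n))
        raw.append((X, Y))
    return out, raw


def test_full_shrinkage_intercepts_solve_scalar_quadratics():
    summ, _ = _random_summaries(0)
    B = fit_group_lasso(summ, lam=1e6)
    assert np.all(B[:, 1:] == 0.0)
    for m, s in enumerate(summ):
        assert B[m, 0] == pytest.approx(s.xi[0] / s.H[0, 0], rel=1e-9)


def test_single_study_lam_zero_solves_normal_equations():
    summ, _ = _random_summaries(1, M=1)
    B = fit_group_lasso(summ, lam=0.0, tol=1e-12)
    np.testing.assert_allclose(
        B[0], np.linalg.solve(summ[0].H, summ[0].xi), atol=1e-8
    )


def test_group_kkt_conditions():
    summ, _ = _random_summaries(2)
    lam = 0.08
    B = fit_group_lasso(summ, lam, tol=1e-11)
    n = np.array([s.n_used for s in summ], dtype=float)
    w = n / n.sum()
    grad = np.stack([2.0 * w[m] * (summ[m].H @ B[m] - summ[m].xi) for m in range(3)])
    norms = np.linalg.norm(grad, axis=0)
    active = np.linalg.norm(B, axis=0) > 0
    for j in range(1, B.shape[1]):
        if active[j]:
            # gradient must equal -lam * beta_j / ||beta_j||
            direction = -lam * B[:, j] / np.linalg.norm(B[:, j])
            np.testing.assert_allclose(grad[:, j], direction, atol=1e-6)
        else:
            assert norms[j] <= lam + 1e-6
    assert np.abs(grad[:, 0]).max() < 1e-8  # unpenalized intercept


def test_objective_decreases_and_order_invariant():
    summ, _ = _random_summaries(3)
    lam = 0.05
    B = fit_group_lasso(summ, lam)
    n = np.array([s.n_used for s in summ], dtype=float)
    w = n / n.sum()
    H = np.stack([s.H for s in summ])
    xi = np.stack([s.xi for s in summ])
    pen = np.ones(6, dtype=bool)
    pen[0] = False
    obj_fit = group_lasso_objective(H, xi, w, lam, pen, B)
    obj_zero = group_lasso_objective(H, xi, w, lam, pen, np.zeros_like(B))
    assert obj_fit <= obj_zero
    # permuting study order permutes the solution rows identically
    B_perm = fit_group_lasso(summ[::-1], lam)
    np.testing.assert_allclose(B_perm, B[::-1], atol=1e-7)


def test_rejects_raw_data_and_non_psd():
    with pytest.raises(TypeError, match="SummaryStep1"):
        fit_group_lasso([np.eye(3)], lam=0.1)
    bad = SummaryStep1(n_used=10, xi=np.zeros(3), H=-np.eye(3))
    with pytest.raises(ValueError, match="PSD"):
        fit_group_lasso([bad], lam=0.1)


def test_gic_trivial_cases():
    summ, _ = _random_summaries(4)
    rep0 = gic(summ, np.zeros((3, 6)), lam=0.1)
    assert rep0.dev == 0.0 and rep0.df == 0.0
    # lam=0 with a dense solution: penalty Hessian vanishes, DF = |active|
    B = fit_group_lasso(summ, lam=0.0)
    rep = gic(summ, B, lam=0.0)
    assert rep.df == pytest.approx((B != 0).sum(), rel=1e-6)


def test_gic_df_matches_dense_oracle():
    """DF equals trace([d2(Dev+lam pen)]^{-1} d2 Dev) assembled longhand."""
    summ, _ = _random_summaries(5, M=2, P=4)
    lam = 0.05
    B = fit_group_lasso(summ, lam, tol=1e-11)
    rep = gic(summ, B, lam)
    n = np.array([s.n_used for s in summ], dtype=float)
    w = n / n.sum()
    active = [(m, j) for j in range(4) for m in range(2) if B[m, j] != 0.0]
    d = len(active)
    A = np.zeros((d, d))
    Pen = np.zeros((d, d))
    for a, (m, j) in enumerate(active):
        for b, (m2, j2) in enumerate(active):
            if m == m2:
                A[a, b] = 2.0 * w[m] * summ[m].H[j, j2]
            if j == j2 and j >= 1:
                r = np.linalg.norm(B[:, j])
                Pen[a, b] = lam * ((m == m2) / r - B[m, j] * B[m2, j] / r**3)
    oracle = np.trace(np.linalg.inv(A + Pen) @ A)
    assert rep.df == pytest.approx(oracle, rel=1e-6)


def test_select_lambda_single_point_and_curve():
    summ, _ = _random_summaries(6)
    lam, B, reports = select_lambda(summ, grid=np.array([0.07]))
    assert lam == 0.07 and len(reports) == 1
    grid = np.logspace(-0.5, -2.5, 8)
    lam, B, reports = select_lambda(summ, grid=grid)
    assert lam in grid
    assert len(reports) <= len(grid)  # early exit allowed
    with pytest.raises(ValueError):
        select_lambda(summ, grid=np.array([]))


def test_select_lambda_screens_true_support():
    """Strong signals: GIC-selected support contains the truth."""
    from dsilt.local_site import make_folds, summary_step1
    from dsilt.synth import CoefficientSpec, DesignSpec, simulate_federated

    data = simulate_federated(
        DesignSpec(kind="ar1", p=20, rho=0.0),
        CoefficientSpec(M=3, s=3, mu=1.0),
        "logistic", [400, 400, 400], seed=17,
    )
    hits = 0
    for m_seed in range(2):
        summ = []
        for m, st in enumerate(data.studies):
            plan = make_folds(st.n, 2, 5, seed=10 * m_seed + m)
            summ.append(summary_step1(st, plan, 0, "logistic", lam=0.04))
        _, B, _ = select_lambda(summ)
        sel = set((np.flatnonzero(np.linalg.norm(B[:, 1:], axis=0) > 0) + 1).tolist())
        hits += set(data.support.tolist()) <= sel
    assert hits == 2


def _fista_group_lasso(raw, lam, n_iter=30000):
    """Independent pooled individual-level group-LASSO solver (prox gradient).

    Operates directly on the stacked raw linear-family blocks: objective
    sum_m w_m (b'H b - 2 b'xi) + lam sum_j ||B[:,j]|| with exact Grams.
    """
    M = len(raw)
    P = raw[0][0].shape[1]
    n = np.array([X.shape[0] for X, _ in raw], dtype=float)
    w = n / n.sum()
    H = np.stack([X.T @ X / X.shape[0] for X, _ in raw])
    xi = np.stack([X.T @ Y / X.shape[0] for X, Y in raw])
    L = 2 * max(w[m] * np.linalg.eigvalsh(H[m])[-1] for m in range(M))
    B = np.zeros((M, P))
    Z = B.copy()
    tk = 1.0
    for _ in range(n_iter):
        G = 2.0 * w[:, None] * ((H @ Z[:, :, None])[:, :, 0] - xi)
        V = Z - G / L
        norms = np.linalg.norm(V[:, 1:], axis=0)
        scale = np.maximum(1 - (lam / L) / np.maximum(norms, 1e-300), 0.0)
        Bn = V.copy()
        Bn[:, 1:] *= scale
        tn = (1 + np.sqrt(1 + 4 * tk**2)) / 2
        Z = Bn + ((tk - 1) / tn) * (Bn - B)
        B, tk = Bn, tn
    return B, H, xi, w


def test_linear_family_summary_fit_equals_pooled_fit():
    """Exact sufficiency: the shielded fit equals the pooled-data fit."""
    summ, raw = _random_summaries(8, M=3, P=6, n=50)
    lam = 0.06
    B_summary = fit_group_lasso(summ, lam, tol=1e-12)
    B_pooled, H, xi, w = _fista_group_lasso(raw, lam)
    pen = np.ones(6, dtype=bool)
    pen[0] = False
    o1 = group_lasso_objective(H, xi, w, lam, pen, B_summary)
    o2 = group_lasso_objective(H, xi, w, lam, pen, B_pooled)
    assert abs(o1 - o2) < 1e-8
    # prox-Newton individual-level path agrees too (single Newton step exact)
    B_ind, _ = fit_group_lasso_individual(raw, "linear", lam)
    o3 = group_lasso_objective(H, xi, w, lam, pen, B_ind)
    assert abs(o3 - o2) < 1e-8


def test_estimation_error_shrinks_with_sample_size():
    """Consistency smoke test: the l2/l1 error of the integrative estimator
    decreases as the per-study sample size grows."""
    from dsilt.local_site import make_folds, summary_step1
    from dsilt.synth import CoefficientSpec, DesignSpec, simulate_federated

    errs = []
    for n in (200, 800):
        data = simulate_federated(
            DesignSpec(kind="ar1", p=25, rho=0.5),
            CoefficientSpec(M=3, s=4, mu=0.5),
            "logistic", [n] * 3, seed=23,
        )
        summ = []
        for m, st in enumerate(data.studies):
            plan = make_folds(st.n, 2, 5, seed=m)
            summ.append(summary_step1(st, plan, 0, "logistic", lam=0.05 * np.sqrt(200 / n)))
        _, B, _ = select_lambda(summ)
        errs.append(np.linalg.norm(B - data.truth, axis=0).sum())
    assert errs[1] < errs[0]
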