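"""Fold plans, the site-level l1 GLM, and the two summary payloads."""

import numpy as np
import pytest

from dsilt.families import adjust, get_family
from dsilt.local_site import (
    SummaryStep1,
    SummaryStep2,
    fit_l1_glm,
    load_summary,
    make_folds,
    save_summary,
    select_local_lambda,
    summary_step1,
    summary_step2,
)
from dsilt.synth import StudyData


# ---------------------------------------------------------------- fold plans


def test_make_folds_exact_division():
    plan = make_folds(10, K=2, Kp=5, seed=0)
    assert sorted(plan.outer_idx(k).size for k in range(2)) == [5, 5]
    for k in range(2):
        sizes = [plan.inner_idx(k, kp).size for kp in range(5)]
        assert sizes == [1] * 5


def test_make_folds_remainder_rule():
    plan = make_folds(11, K=2, Kp=2, seed=3)
    assert sorted(plan.outer_idx(k).size for k in range(2)) == [5, 6]


def test_make_folds_partition_property():
    plan = make_folds(37, K=4, Kp=3, seed=1)
    all_idx = np.sort(np.concatenate([plan.outer_idx(k) for k in range(4)]))
    np.testing.assert_array_equal(all_idx, np.arange(37))
    for k in range(4):
        inner_union = np.sort(np.concatenate([plan.inner_idx(k, kp) for kp in range(3)]))
        np.testing.assert_array_equal(inner_union, plan.train_idx(k))


def test_make_folds_rejects_odd_k():
    with pytest.raises(ValueError, match="even"):
        make_folds(20, K=3, Kp=2, seed=0)


def test_make_folds_deterministic():
    a, b = make_folds(40, 2, 5, seed=5), make_folds(40, 2, 5, seed=5)
    np.testing.assert_array_equal(a.outer, b.outer)
    np.testing.assert_array_equal(a.inner, b.inner)


# ------------------------------------------------------------- local l1 GLM


def test_full_shrinkage_gives_null_fit(tiny_logistic_xy):
    X, Y = tiny_logistic_xy
    beta = fit_l1_glm(X, Y, "logistic", lam=10.0)
    assert np.all(beta[1:] == 0.0)
    assert beta[0] == pytest.approx(np.log(Y.mean() / (1 - Y.mean())), abs=1e-6)


def test_lam_zero_linear_equals_least_squares():
    rng = np.random.default_rng(1)
    X = np.column_stack([np.ones(50), rng.standard_normal((50, 4))])
    Y = X @ rng.standard_normal(5) + 0.2 * rng.standard_normal(50)
    beta = fit_l1_glm(X, Y, "linear", lam=0.0, inner_tol=1e-12)
    np.testing.assert_allclose(beta, np.linalg.lstsq(X, Y, rcond=None)[0], atol=1e-9)


def test_l1_glm_kkt_conditions(tiny_logistic_xy):
    """Subgradient optimality of the penalized GLM loss at the solution."""
    X, Y = tiny_logistic_xy
    fam = get_family("logistic")
    lam = 0.02
    beta = fit_l1_glm(X, Y, fam, lam, tol=1e-10, inner_tol=1e-11)
    grad = X.T @ (fam.phidot(X @ beta) - Y) / X.shape[0]
    active = beta[1:] != 0.0
    if active.any():
        assert np.abs(grad[1:][active] + lam * np.sign(beta[1:][active])).max() < 1e-6
    if (~active).any():
        assert np.abs(grad[1:][~active]).max() <= lam + 1e-6
    assert abs(grad[0]) < 1e-6  # intercept unpenalized


def test_select_local_lambda_returns_grid_member(tiny_logistic_xy):
    X, Y = tiny_logistic_xy
    grid = np.array([0.005, 0.05, 0.5])
    lam, curve = select_local_lambda(X, Y, "logistic", lam_grid=grid, seed=1)
    assert lam in grid and curve.shape == (3,)
    with pytest.raises(ValueError):
        select_local_lambda(X, Y, "logistic", lam_grid=np.array([]))


# --------------------------------------------------------- summary payloads


def _study(seed, n=60, p=3, family="logistic", beta=None, noise_sd=1.0):
    rng = np.random.default_rng(seed)
    X = np.column_stack([np.ones(n), rng.standard_normal((n, p))])
    beta = np.zeros(p + 1) if beta is None else beta
    fam = get_family(family)
    if family == "logistic":
        Y = (rng.random(n) < fam.phidot(X @ beta)).astype(float)
    else:
        Y = X @ beta + noise_sd * rng.standard_normal(n)
    return StudyData(X=X, Y=Y)


def test_step1_linear_hessian_is_plain_gram():
    st = _study(0, family="linear", beta=np.array([0.5, 1.0, 0.0, -1.0]))
    plan = make_folds(st.n, 2, 5, seed=2)
    s = summary_step1(st, plan, k=0, family="linear", lam=0.1)
    tr = plan.train_idx(0)
    # phiddot == 1: H is the equal-weight average of per-inner-fold Grams,
    # independent of the fitted coefficients
    H_direct = np.zeros((4, 4))
    for kp in range(5):
        ev = plan.inner_idx(0, kp)
        H_direct += st.X[ev].T @ st.X[ev] / ev.size
    H_direct /= 5
    np.testing.assert_allclose(s.H, H_direct, rtol=1e-10)
    assert s.n_used == tr.size


def test_step1_linear_noiseless_identity():
    beta0 = np.array([0.3, 1.0, -2.0, 0.5])
    st = _study(4, family="linear", beta=beta0, noise_sd=0.0)
    plan = make_folds(st.n, 2, 5, seed=0)
    s = summary_step1(st, plan, 0, "linear", lam=0.05)
    np.testing.assert_allclose(s.xi, s.H @ beta0, atol=1e-10)


def test_step1_matches_bruteforce_double_loop():
    """Tiny logistic instance vs an explicit loop over inner folds and rows."""
    st = _study(7, n=24, p=2)
    plan = make_folds(st.n, 2, 3, seed=5)
    lam = 0.05
    fam = get_family("logistic")
    got = summary_step1(st, plan, 1, fam, lam=lam)
    P = st.X.shape[1]
    xi = np.zeros(P)
    H = np.zeros((P, P))
    for kp in range(3):
        ev = plan.inner_idx(1, kp)
        tr = np.array(
            [i for i in range(st.n) if plan.inner[1, i] >= 0 and plan.inner[1, i] != kp]
        )
        bhat = fit_l1_glm(st.X[tr], st.Y[tr], fam, lam)
        xi_f = np.zeros(P)
        H_f = np.zeros((P, P))
        for i in ev:
            theta = float(st.X[i] @ bhat)
            w = fam.phiddot(np.array([theta]))[0]
            xb = np.sqrt(w) * st.X[i]
            yb = (st.Y[i] - fam.phidot(np.array([theta]))[0] + w * theta) / np.sqrt(w)
            xi_f += xb * yb
            H_f += np.outer(xb, xb)
        xi += xi_f / ev.size
        H += H_f / ev.size
    np.testing.assert_allclose(got.xi, xi / 3, rtol=1e-9)
    np.testing.assert_allclose(got.H, H / 3, rtol=1e-9)


def test_step2_linear_noiseless_correction_vanishes():
    beta0 = np.array([0.0, 1.0, -1.0, 0.4])
    st = _study(9, family="linear", beta=beta0, noise_sd=0.0)
    plan = make_folds(st.n, 2, 5, seed=1)
    s = summary_step2(st, plan, 0, beta0, "linear")
    np.testing.assert_allclose(s.xi_t - s.H_t @ beta0, 0.0, atol=1e-12)
    np.testing.assert_allclose(s.J_t, 0.0, atol=1e-20)


def test_step2_matches_explicit_loop_and_psd(tiny_logistic_xy):
    X, Y = tiny_logistic_xy
    st = StudyData(X=X, Y=Y)
    plan = make_folds(st.n, 2, 2, seed=8)
    beta = np.array([0.1, 0.5, -0.2, 0.0])
    fam = get_family("logistic")
    s = summary_step2(st, plan, 1, beta, fam)
    idx = plan.outer_idx(1)
    adj = adjust(X[idx], Y[idx], beta, fam)
    resid = Y[idx] - fam.phidot(adj.theta)
    J = np.zeros((4, 4))
    xi = np.zeros(4)
    H = np.zeros((4, 4))
    for row, (x, yb, xb, r) in enumerate(zip(X[idx], adj.Yb, adj.Xb, resid)):
        xi += xb * yb
        H += np.outer(xb, xb)
        J += np.outer(x, x) * r**2
    n = idx.size
    np.testing.assert_allclose(s.xi_t, xi / n, rtol=1e-10)
    np.testing.assert_allclose(s.H_t, H / n, rtol=1e-10)
    np.testing.assert_allclose(s.J_t, J / n, rtol=1e-10)
    for Mx in (s.H_t, s.J_t):
        np.testing.assert_allclose(Mx, Mx.T, atol=1e-12)
        assert np.linalg.eigvalsh(Mx)[0] >= -1e-10


def test_summaries_depend_only_on_own_study(small_logistic_data):
    """DataSHIELD contract: another study's rows cannot change this site's message."""
    st0 = small_logistic_data.studies[0]
    plan = make_folds(st0.n, 2, 5, seed=0)
    s_before = summary_step1(st0, plan, 0, "logistic", lam=0.05)
    # "mutate" the other studies by constructing entirely different data
    _ = _study(123, n=st0.n, p=st0.p)
    s_after = summary_step1(st0, plan, 0, "logistic", lam=0.05)
    np.testing.assert_array_equal(s_before.xi, s_after.xi)
    np.testing.assert_array_equal(s_before.H, s_after.H)
    beta = np.zeros(st0.p + 1)
    t_before = summary_step2(st0, plan, 0, beta, "logistic")
    t_after = summary_step2(st0, plan, 0, beta, "logistic")
    np.testing.assert_array_equal(t_before.xi_t, t_after.xi_t)


def test_payload_round_trip(tmp_path, tiny_logistic_xy):
    X, Y = tiny_logistic_xy
    st = StudyData(X=X, Y=Y)
    plan = make_folds(st.n, 2, 2, seed=0)
    s1 = summary_step1(st, plan, 0, "logistic", lam=0.1)
    s2 = summary_step2(st, plan, 0, np.zeros(4), "logistic")
    p1 = save_summary(s1, tmp_path / "s1.npz")
    p2 = save_summary(s2, tmp_path / "s2.npz")
    r1, r2 = load_summary(p1), load_summary(p2)
    assert isinstance(r1, SummaryStep1) and isinstance(r2, SummaryStep2)
    np.testing.assert_array_equal(r1.H, s1.H)
    np.testing.assert_array_equal(r2.J_t, s2.J_t)
    assert r1.n_used == s1.n_used
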