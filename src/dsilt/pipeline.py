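"""End-to-end orchestration of the shielded testing procedure.

``run_dsilt`` executes the three-step algorithm under the data-shielding
contract: raw rows never leave a study; only Summary payloads cross the
emulated DC/AC boundary.  ``run_oneshot`` (each site debiases its own
LASSO, estimates are pooled once) and ``run_ilma`` (the idealized
individual-level meta-analysis) are the two comparators; all three share
the same multiple-testing code path, so differences in rejections are
attributable to the estimation/debiasing stages alone.

``run_experiment`` drives replicated simulation studies and aggregates
empirical FDR (mean FDP) and power per method and setting.
"""

from __future__ import annotations

import logging
import time
import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import debias as db
from . import integrative as intg
from . import multitest as mt
from .families import get_family
from .local_site import (
    fit_l1_glm,
    make_folds,
    select_local_lambda,
    summary_step1,
    summary_step2,
)
from .synth import CoefficientSpec, DesignSpec, FederatedDataset, simulate_federated

logger = logging.getLogger("dsilt")

__all__ = [
    "RunConfig",
    "RunResult",
    "ExperimentResult",
    "run_dsilt",
    "run_oneshot",
    "run_ilma",
    "run_experiment",
    "result_table",
]


@dataclass(frozen=True)
class RunConfig:
    """Configuration shared by the three testing pipelines.

    tau grids default to c * sqrt((M + log p)/n_bar) for c in ``tau_consts``
    (the theoretical radius rate); lambda grids default to data-driven
    log-spaced paths from the smallest fully-sparsifying penalty.
    """

    family: str = "logistic"
    K: int = 2
    Kp: int = 5
    alpha: float = 0.1
    lam_grid: np.ndarray | None = None
    local_lam_grid: np.ndarray | None = None
    gamma: float | None = None  # None -> BIC scaling
    tau_grid: np.ndarray | None = None
    tau_consts: tuple = (1.0, 2.0)
    H_grid: int = 10
    targets: np.ndarray | None = None  # default: all non-intercept columns
    seed: int = 0
    cv_folds: int = 5
    dantzig_max_iter: int = 400
    dantzig_feas_rtol: float = 5e-2

    def __post_init__(self) -> None:
        if self.K < 2 or self.K % 2:
            raise ValueError("K must be an even integer >= 2")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        for g in (self.lam_grid, self.tau_grid):
            if g is not None and len(g) == 0:
                raise ValueError("grids must be nonempty")


@dataclass(frozen=True)
class RunResult:
    """Everything a run produces: the test outcome plus diagnostics."""

    outcome: mt.TestOutcome
    debias: db.DebiasResult
    tau_report: object
    beta_tilde: np.ndarray | None
    meta: dict


def _targets(data: FederatedDataset, cfg: RunConfig) -> np.ndarray:
    if cfg.targets is not None:
        t = np.asarray(cfg.targets, dtype=int)
        if np.any(t < 1) or np.any(t > data.p):
            raise ValueError("targets must be non-intercept column indices")
        return t
    return np.arange(1, data.p + 1)


def _tau_grid(cfg: RunConfig, M: int, p: int, n_bar: float) -> np.ndarray:
    if cfg.tau_grid is not None:
        return np.sort(np.asarray(cfg.tau_grid, dtype=float))
    rate = np.sqrt((M + np.log(p)) / n_bar)
    return np.sort(np.array(cfg.tau_consts, dtype=float) * rate)


def _study_seeds(cfg: RunConfig, M: int):
    ss = np.random.SeedSequence(cfg.seed)
    return [child.spawn(2) for child in ss.spawn(M)]


def _solve_tau_path(H_blocks_per_fold, targets, tau_grid, cfg) -> dict:
    """Solve the Dantzig program per (fold, tau), warm-starting down the grid.

    Returns {tau: [U_k, ...]} for the taus that are feasible; escalates
    through the grid when the smallest radii are infeasible.
    """
    K = len(H_blocks_per_fold)
    U_by_tau: dict[float, list] = {}
    states = [None] * K
    for tau in sorted(tau_grid, reverse=True):  # large tau first: easy -> hard
        Us = []
        try:
            for k in range(K):
                sol = db.solve_group_dantzig_batch(
                    H_blocks_per_fold[k], targets, tau, state=states[k],
                    max_iter=cfg.dantzig_max_iter,
                    feas_rtol=cfg.dantzig_feas_rtol,
                )
                states[k] = sol.state
                Us.append(sol.U)
        except db.DantzigInfeasibleError:
            logger.warning("tau=%.4g infeasible; escalating through the grid", tau)
            continue
        U_by_tau[float(tau)] = Us
    if not U_by_tau:
        raise db.DantzigInfeasibleError("every tau in the grid was infeasible")
    return U_by_tau


def _debias_and_test(
    beta_tilde_per_fold, step2_per_fold, H_blocks_per_fold, targets,
    n_m, tau_grid, cfg, M_stat: int | None = None,
):
    """Shared tail of all pipelines: Dantzig path, tau selection, testing.

    ``M_stat`` is the degrees of freedom of the pooled statistic (differs
    from the number of blocks in the One-shot per-study specialization).
    """
    M = len(n_m)
    q = len(targets)
    U_by_tau = _solve_tau_path(H_blocks_per_fold, targets, tau_grid, cfg)
    terms_by_tau, sigma2_by_tau, zeta_null_by_tau = {}, {}, {}
    for tau, Us in U_by_tau.items():
        terms = db.fold_terms(beta_tilde_per_fold, Us, step2_per_fold, targets)
        sigma2 = db.estimate_variance(Us, step2_per_fold)
        terms_by_tau[tau] = terms
        sigma2_by_tau[tau] = sigma2
        zeta_null_by_tau[tau] = mt.null_statistics(terms, sigma2, n_m)
    report = mt.select_tau(
        np.array(sorted(U_by_tau)), zeta_null_by_tau,
        M_stat or M, q, cfg.H_grid,
    )
    tau = report.chosen
    beta_breve = terms_by_tau[tau].mean(axis=0)
    sigma2 = sigma2_by_tau[tau]
    zeta = db.group_statistic(beta_breve, sigma2, n_m)
    result = db.DebiasResult(
        beta_breve=beta_breve, sigma_hat=np.sqrt(sigma2), zeta=zeta,
        targets=np.asarray(targets),
    )
    N = mt.normal_transform(zeta, M_stat or M)
    outcome = mt.find_threshold(N, cfg.alpha, targets)
    return outcome, result, report


def run_dsilt(data: FederatedDataset, cfg: RunConfig = RunConfig()) -> RunResult:
    """Full shielded pipeline: Steps 1-3 with only summary payloads crossing sites."""
    fam = get_family(data.family)
    M = data.M
    targets = _targets(data, cfg)
    n_m = data.n_m
    seeds = _study_seeds(cfg, M)
    t0 = time.perf_counter()
    plans = [
        make_folds(st.n, cfg.K, cfg.Kp, seeds[m][0]) for m, st in enumerate(data.studies)
    ]
    lam_local = [
        select_local_lambda(
            st.X, st.Y, fam, lam_grid=cfg.local_lam_grid,
            cv_folds=cfg.cv_folds, seed=seeds[m][1],
        )[0]
        for m, st in enumerate(data.studies)
    ]
    step1 = [
        [
            summary_step1(st, plans[m], k, fam, lam=lam_local[m])
            for m, st in enumerate(data.studies)
        ]
        for k in range(cfg.K)
    ]
    t1 = time.perf_counter()
    beta_tilde, lam_int = [], []
    for k in range(cfg.K):
        lam_k, B_k, _ = select_lambda_summaries(step1[k], cfg)
        beta_tilde.append(B_k)
        lam_int.append(lam_k)
    t2 = time.perf_counter()
    step2 = [
        [
            summary_step2(st, plans[m], k, beta_tilde[k][m], fam)
            for m, st in enumerate(data.studies)
        ]
        for k in range(cfg.K)
    ]
    H_blocks = [[s2.H_t for s2 in step2[k]] for k in range(cfg.K)]
    tau_grid = _tau_grid(cfg, M, data.p, float(np.mean(n_m)))
    outcome, result, report = _debias_and_test(
        beta_tilde, step2, H_blocks, targets, n_m, tau_grid, cfg
    )
    t3 = time.perf_counter()
    payload = sum(
        s.xi.nbytes + s.H.nbytes for k in range(cfg.K) for s in step1[k]
    ) + sum(
        s.xi_t.nbytes + s.H_t.nbytes + s.J_t.nbytes
        for k in range(cfg.K)
        for s in step2[k]
    )
    meta = {
        "method": "dsilt",
        "lam_local": lam_local,
        "lam_integrative": lam_int,
        "timings": {"local": t1 - t0, "integrative": t2 - t1, "debias_test": t3 - t2},
        "payload_bytes": payload,
    }
    logger.debug("dsilt run: %s", meta)
    return RunResult(
        outcome=outcome, debias=result, tau_report=report,
        beta_tilde=np.stack(beta_tilde), meta=meta,
    )


def select_lambda_summaries(summaries, cfg: RunConfig):
    return intg.select_lambda(summaries, grid=cfg.lam_grid, gamma=cfg.gamma)


def run_ilma(data: FederatedDataset, cfg: RunConfig = RunConfig()) -> RunResult:
    """Idealized benchmark: integrative fit on pooled individual-level rows.

    Only Step 1 differs from the shielded pipeline -- the coefficient
    matrix is fit by the pooled-data prox-Newton group LASSO instead of the
    summary quadratic; debiasing and testing reuse the identical code.
    """
    fam = get_family(data.family)
    M = data.M
    targets = _targets(data, cfg)
    n_m = data.n_m
    seeds = _study_seeds(cfg, M)
    plans = [
        make_folds(st.n, cfg.K, cfg.Kp, seeds[m][0]) for m, st in enumerate(data.studies)
    ]
    beta_tilde = []
    for k in range(cfg.K):
        pairs = [
            (st.X[plans[m].train_idx(k)], st.Y[plans[m].train_idx(k)])
            for m, st in enumerate(data.studies)
        ]
        _, B_k = intg.select_lambda_individual(
            pairs, fam, grid=cfg.lam_grid, gamma=cfg.gamma
        )
        beta_tilde.append(B_k)
    step2 = [
        [
            summary_step2(st, plans[m], k, beta_tilde[k][m], fam)
            for m, st in enumerate(data.studies)
        ]
        for k in range(cfg.K)
    ]
    H_blocks = [[s2.H_t for s2 in step2[k]] for k in range(cfg.K)]
    tau_grid = _tau_grid(cfg, M, data.p, float(np.mean(n_m)))
    outcome, result, report = _debias_and_test(
        beta_tilde, step2, H_blocks, targets, n_m, tau_grid, cfg
    )
    return RunResult(
        outcome=outcome, debias=result, tau_report=report,
        beta_tilde=np.stack(beta_tilde),
        meta={"method": "ilma"},
    )


def run_oneshot(data: FederatedDataset, cfg: RunConfig = RunConfig()) -> RunResult:
    """One-shot comparator: each site debiases its own LASSO locally.

    Per study, the projection directions solve the M=1 specialization of
    the group Dantzig program at the site's cross-fitted LASSO estimates,
    with the site's own tau chosen by the M=1 null-calibration analogue;
    debiased estimates and variances travel to the AC exactly once, where
    the pooled group statistic and the shared testing step are applied.
    """
    fam = get_family(data.family)
    M = data.M
    targets = _targets(data, cfg)
    q = len(targets)
    n_m = data.n_m
    seeds = _study_seeds(cfg, M)
    plans = [
        make_folds(st.n, cfg.K, cfg.Kp, seeds[m][0]) for m, st in enumerate(data.studies)
    ]
    lam_local = [
        select_local_lambda(
            st.X, st.Y, fam, lam_grid=cfg.local_lam_grid,
            cv_folds=cfg.cv_folds, seed=seeds[m][1],
        )[0]
        for m, st in enumerate(data.studies)
    ]
    beta_breve = np.empty((M, q))
    sigma2 = np.empty((M, q))
    tau_reports = []
    for m, st in enumerate(data.studies):
        beta_hat = []
        b = None
        for k in range(cfg.K):
            tr = plans[m].train_idx(k)
            b = fit_l1_glm(st.X[tr], st.Y[tr], fam, lam_local[m], init=b)
            beta_hat.append(b[None, :])  # (1, P) block
        step2_m = [
            [summary_step2(st, plans[m], k, beta_hat[k][0], fam)] for k in range(cfg.K)
        ]
        H_blocks = [[step2_m[k][0].H_t] for k in range(cfg.K)]
        tau_grid = _tau_grid(cfg, 1, data.p, float(st.n))
        U_by_tau = _solve_tau_path(H_blocks, targets, tau_grid, cfg)
        terms_by_tau, s2_by_tau, znull = {}, {}, {}
        for tau, Us in U_by_tau.items():
            terms = db.fold_terms(beta_hat, Us, step2_m, targets)
            s2 = db.estimate_variance(Us, step2_m)
            terms_by_tau[tau], s2_by_tau[tau] = terms, s2
            znull[tau] = mt.null_statistics(terms, s2, [st.n])
        report = mt.select_tau(np.array(sorted(U_by_tau)), znull, 1, q, cfg.H_grid)
        tau_reports.append(report)
        beta_breve[m] = terms_by_tau[report.chosen].mean(axis=0)[0]
        sigma2[m] = s2_by_tau[report.chosen][0]
    zeta = db.group_statistic(beta_breve, sigma2, n_m)
    result = db.DebiasResult(
        beta_breve=beta_breve, sigma_hat=np.sqrt(sigma2), zeta=zeta,
        targets=np.asarray(targets),
    )
    N = mt.normal_transform(zeta, M)
    outcome = mt.find_threshold(N, cfg.alpha, targets)
    return RunResult(
        outcome=outcome, debias=result, tau_report=tau_reports,
        beta_tilde=None, meta={"method": "oneshot", "lam_local": lam_local},
    )


_RUNNERS = {"dsilt": run_dsilt, "oneshot": run_oneshot, "ilma": run_ilma}


def result_table(result: RunResult) -> pd.DataFrame:
    """Tidy per-covariate results: estimates, statistics and rejection flags."""
    d = result.debias
    rows = {"j": d.targets}
    for m in range(d.beta_breve.shape[0]):
        rows[f"beta_breve_{m}"] = d.beta_breve[m]
        rows[f"sigma_hat_{m}"] = d.sigma_hat[m]
    rows["zeta"] = d.zeta
    rows["N"] = result.outcome.N
    rows["rejected"] = np.isin(d.targets, result.outcome.rejected)
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ExperimentResult:
    """Per-replication metrics and their per-(method, setting) aggregates."""

    table: pd.DataFrame
    summary: pd.DataFrame


def _one_replication(setting: dict, methods, cfg: RunConfig, rep: int, child):
    data_seed, run_seed = child.spawn(2)
    design = DesignSpec(
        kind=setting.get("design", "ar1"), p=setting["p"],
        rho=setting.get("rho", 0.5), trans=setting.get("trans", 0.2),
        emit=setting.get("emit", 0.2),
    )
    coef = CoefficientSpec(
        M=setting["M"], s=setting["s"], mu=setting["mu"],
        nu_sd_factor=setting.get("nu_sd_factor", 0.5),
    )
    data = simulate_federated(
        design, coef, setting.get("family", cfg.family), setting["n_m"], data_seed
    )
    run_cfg = replace(cfg, seed=int(run_seed.generate_state(1)[0] & 0x7FFFFFFF))
    rows = []
    for method in methods:
        try:
            res = _RUNNERS[method](data, run_cfg)
            fdp, power = mt.error_metrics(
                res.outcome.rejected, data.support, res.outcome.targets
            )
            rows.append(
                dict(setting, method=method, rep=rep, fdp=fdp, power=power,
                     rejections=len(res.outcome.rejected), failed=False)
            )
        except Exception as exc:  # partial failure: record and move on
            warnings.warn(f"replication {rep} / {method} failed: {exc}")
            rows.append(
                dict(setting, method=method, rep=rep, fdp=np.nan, power=np.nan,
                     rejections=-1, failed=True)
            )
    return rows


def run_experiment(
    settings,
    n_reps: int,
    seed: int = 0,
    methods=("dsilt", "oneshot", "ilma"),
    cfg: RunConfig = RunConfig(),
    out_dir=None,
    n_jobs: int = 1,
) -> ExperimentResult:
    """Replicated simulation study over a grid of settings.

    ``settings`` is an iterable of dicts with keys M, n_m, p, s, mu and
    optionally design/rho/trans/emit/family.  Per-replication seeds are
    spawned deterministically from ``seed``; parallelism (if requested) is
    across replications only.
    """
    settings = list(settings)
    jobs = []
    children = np.random.SeedSequence(seed).spawn(len(settings) * n_reps)
    idx = 0
    for setting in settings:
        for rep in range(n_reps):
            jobs.append((setting, rep, children[idx]))
            idx += 1
    if n_jobs != 1:
        from joblib import Parallel, delayed

        out = Parallel(n_jobs=n_jobs)(
            delayed(_one_replication)(s, methods, cfg, rep, ch) for s, rep, ch in jobs
        )
    else:
        out = [_one_replication(s, methods, cfg, rep, ch) for s, rep, ch in jobs]
    table = pd.DataFrame([row for rows in out for row in rows])
    keys = ["method"] + [k for k in ("design", "p", "s", "mu", "M", "n_m") if k in table]
    summary = (
        table[~table["failed"]]
        .groupby(keys, as_index=False)
        .agg(fdr=("fdp", "mean"), power=("power", "mean"), reps=("fdp", "size"))
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        table.to_csv(out_dir / "replications.csv", index=False)
        summary.to_csv(out_dir / "summary.csv", index=False)
        _plot_summary(summary, out_dir / "fdr_power.png")
    return ExperimentResult(table=table, summary=summary)


def _plot_summary(summary: pd.DataFrame, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(9, 3.5), sharex=True)
    for method, grp in summary.groupby("method"):
        g = grp.sort_values("mu")
        axes[0].plot(g["mu"], g["fdr"], marker="o", label=method)
        axes[1].plot(g["mu"], g["power"], marker="o", label=method)
    axes[0].axhline(0.1, ls="--", c="gray", lw=0.8)
    axes[0].set_xlabel("mu"), axes[0].set_ylabel("empirical FDR")
    axes[1].set_xlabel("mu"), axes[1].set_ylabel("empirical power")
    axes[1].legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
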