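"""Synthetic federated datasets with the structure of the simulation study.

Designs
-------
* ``ar1``  : rows i.i.d. Gaussian with AR(1) covariance rho^|j-k| (default
  rho = 0.5), the classic correlated-SNP-score surrogate.
* ``hmm``  : binary hidden Markov design; each row is an observed binary
  chain over the p positions with symmetric transition flip probability
  ``trans`` and emission flip probability ``emit`` (both default 0.2),
  mimicking correlated binary genotype calls.

Coefficients are heterogeneous in magnitude but share a common support of
size s: study m has beta_j^(m) = mu * (1 + nu_j^(m)) * psi_j for j in the
support, where psi_j is a Rademacher sign shared across studies and
nu_j^(m) ~ N(0, (mu * nu_sd_factor)^2) varies independently per (j, m).
The intercept's true coefficient is 0 everywhere.

Seeding: a single master seed fans out through ``numpy.random.SeedSequence``
children in a fixed order (signs, heterogeneity, then per-study design and
outcome streams), so studies are mutually independent yet every artifact is
bitwise reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .families import get_family

__all__ = [
    "DesignSpec",
    "CoefficientSpec",
    "StudyData",
    "FederatedDataset",
    "make_ar1_design",
    "make_hmm_design",
    "make_coefficients",
    "simulate_federated",
    "save_studies",
    "load_studies",
    "save_truth",
    "load_truth",
]


@dataclass(frozen=True)
class DesignSpec:
    """Covariate design: ``kind`` is 'ar1' (uses rho) or 'hmm' (uses trans/emit)."""

    kind: str = "ar1"
    p: int = 120
    rho: float = 0.5
    trans: float = 0.2
    emit: float = 0.2

    def __post_init__(self) -> None:
        if self.kind not in ("ar1", "hmm"):
            raise ValueError(f"unknown design kind {self.kind!r}")
        if self.p < 2:
            raise ValueError("p must be >= 2")
        if self.kind == "ar1" and not (0.0 <= self.rho < 1.0):
            raise ValueError("rho must lie in [0, 1)")
        if self.kind == "hmm" and not (0.0 < self.trans < 1.0 and 0.0 < self.emit < 1.0):
            raise ValueError("trans and emit must lie in (0, 1)")


@dataclass(frozen=True)
class CoefficientSpec:
    """Shared-support heterogeneous coefficients across M studies."""

    M: int = 3
    s: int = 10
    mu: float = 0.35
    nu_sd_factor: float = 0.5  # sd(nu) = mu * nu_sd_factor

    def __post_init__(self) -> None:
        if self.M < 1 or self.s < 0 or self.mu < 0:
            raise ValueError("require M >= 1, s >= 0, mu >= 0")


@dataclass(frozen=True)
class StudyData:
    """One site's raw data: X is n x (p+1) with an all-ones first column."""

    X: np.ndarray
    Y: np.ndarray

    def __post_init__(self) -> None:
        if self.X.ndim != 2 or self.Y.ndim != 1 or self.X.shape[0] != self.Y.shape[0]:
            raise ValueError("X must be n x (p+1) and Y length n")
        if not np.allclose(self.X[:, 0], 1.0):
            raise ValueError("first column of X must be the intercept (all ones)")
        if not (np.isfinite(self.X).all() and np.isfinite(self.Y).all()):
            raise ValueError("missing or non-finite values are not supported")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:  # covariate count excluding intercept
        return self.X.shape[1] - 1


@dataclass(frozen=True)
class FederatedDataset:
    """Ordered collection of study blocks, never pooled by the shielded code paths.

    ``truth`` (optional) is the M x (p+1) true coefficient matrix;
    ``support`` the true active set S_0 (column indices >= 1).
    """

    studies: tuple[StudyData, ...]
    truth: np.ndarray | None = None
    support: np.ndarray | None = None
    family: str = "logistic"

    def __post_init__(self) -> None:
        ps = {s.p for s in self.studies}
        if len(ps) != 1:
            raise ValueError("all studies must share the same covariate dimension")

    @property
    def M(self) -> int:
        return len(self.studies)

    @property
    def p(self) -> int:
        return self.studies[0].p

    @property
    def n_m(self) -> np.ndarray:
        return np.array([s.n for s in self.studies])

    @property
    def N(self) -> int:
        return int(self.n_m.sum())


def make_ar1_design(n: int, p: int, rho: float, seed) -> np.ndarray:
    """n x p matrix, rows i.i.d. N(0, Sigma) with Sigma_jk = rho^|j-k|.

    Generated by the exact AR(1) recursion x_{j+1} = rho x_j + sqrt(1-rho^2) e.
    """
    if not (0.0 <= rho < 1.0):
        raise ValueError("rho must lie in [0, 1)")
    if n < 1 or p < 1:
        raise ValueError("n and p must be >= 1")
    rng = np.random.default_rng(seed)
    Z = rng.standard_normal((n, p))
    X = np.empty((n, p))
    X[:, 0] = Z[:, 0]
    c = np.sqrt(1.0 - rho * rho)
    for j in range(1, p):
        X[:, j] = rho * X[:, j - 1] + c * Z[:, j]
    return X


def make_hmm_design(n: int, p: int, trans: float, emit: float, seed) -> np.ndarray:
    """n x p binary matrix; each row an emitted hidden-Markov chain.

    The hidden chain starts from its stationary law Bernoulli(1/2), flips
    with probability ``trans`` at each step, and the observed bit flips the
    hidden bit with probability ``emit``.
    """
    if not (0.0 < trans < 1.0 and 0.0 < emit < 1.0):
        raise ValueError("trans and emit must lie in (0, 1)")
    if n < 1 or p < 1:
        raise ValueError("n and p must be >= 1")
    rng = np.random.default_rng(seed)
    H = np.empty((n, p), dtype=np.int64)
    H[:, 0] = rng.random(n) < 0.5
    flips = rng.random((n, p - 1)) < trans
    for j in range(1, p):
        H[:, j] = H[:, j - 1] ^ flips[:, j - 1]
    E = rng.random((n, p)) < emit
    return (H ^ E).astype(float)


def make_coefficients(spec: CoefficientSpec, p: int, seed) -> np.ndarray:
    """M x (p+1) true coefficient matrix (column 0 = intercept = 0).

    Columns 1..s carry mu*(1+nu_j^(m))*psi_j; the sign pattern psi and hence
    the support are identical across the M rows.
    """
    if spec.s > p:
        raise ValueError("support size s cannot exceed p")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    sign_rng, nu_rng = (np.random.default_rng(c) for c in ss.spawn(2))
    B = np.zeros((spec.M, p + 1))
    if spec.s == 0 or spec.mu == 0.0:
        return B
    psi = sign_rng.choice([-1.0, 1.0], size=spec.s)
    nu = nu_rng.normal(0.0, spec.mu * spec.nu_sd_factor, size=(spec.M, spec.s))
    B[:, 1 : spec.s + 1] = spec.mu * (1.0 + nu) * psi
    return B


def _draw_design(design: DesignSpec, n: int, seed) -> np.ndarray:
    if design.kind == "ar1":
        return make_ar1_design(n, design.p, design.rho, seed)
    return make_hmm_design(n, design.p, design.trans, design.emit, seed)


def simulate_federated(
    design: DesignSpec,
    coef: CoefficientSpec,
    family: str,
    n_m,
    seed,
    noise_sd: float = 1.0,
) -> FederatedDataset:
    """Generate an M-study federated dataset with known truth.

    Outcomes follow the family's conditional law at the true coefficients:
    Bernoulli(expit(theta)) for 'logistic', theta + noise_sd*N(0,1) for
    'linear', Poisson(exp(theta)) for 'poisson_log'.
    """
    fam = get_family(family)
    n_m = [int(n) for n in np.atleast_1d(n_m)]
    if len(n_m) not in (1, coef.M):
        raise ValueError("n_m must be scalar or of length M")
    if len(n_m) == 1:
        n_m = n_m * coef.M
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    coef_child, *study_children = ss.spawn(1 + coef.M)
    B = make_coefficients(coef, design.p, coef_child)
    studies = []
    for m, (n, child) in enumerate(zip(n_m, study_children)):
        x_child, y_child = child.spawn(2)
        Xraw = _draw_design(design, n, x_child)
        X = np.column_stack([np.ones(n), Xraw])
        theta = X @ B[m]
        rng = np.random.default_rng(y_child)
        if fam.name == "logistic":
            Y = (rng.random(n) < fam.phidot(theta)).astype(float)
        elif fam.name == "linear":
            Y = theta + noise_sd * rng.standard_normal(n)
        elif fam.name == "poisson_log":
            Y = rng.poisson(fam.phidot(theta)).astype(float)
        else:  # pragma: no cover - get_family already validates
            raise ValueError(f"unsupported family {fam.name!r}")
        studies.append(StudyData(X=X, Y=Y))
    support = np.flatnonzero(np.any(B[:, 1:] != 0.0, axis=0)) + 1
    return FederatedDataset(
        studies=tuple(studies), truth=B, support=support, family=fam.name
    )


# ---------------------------------------------------------------------------
# plain-text round trips (one headered CSV per study: y, x0, x1, ..., xp)

def save_studies(data: FederatedDataset, out_dir) -> list[Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for m, st in enumerate(data.studies):
        cols = {"y": st.Y}
        for j in range(st.X.shape[1]):
            cols[f"x{j}"] = st.X[:, j]
        path = out_dir / f"study_{m}.csv"
        pd.DataFrame(cols).to_csv(path, index=False)
        paths.append(path)
    return paths


def load_studies(paths, family: str = "logistic") -> FederatedDataset:
    studies = []
    for path in paths:
        df = pd.read_csv(path)
        xcols = sorted(
            (c for c in df.columns if c.startswith("x")), key=lambda c: int(c[1:])
        )
        studies.append(
            StudyData(X=df[xcols].to_numpy(float), Y=df["y"].to_numpy(float))
        )
    return FederatedDataset(studies=tuple(studies), family=family)


def save_truth(data: FederatedDataset, path) -> Path:
    if data.truth is None:
        raise ValueError("dataset carries no ground truth")
    B = data.truth
    df = pd.DataFrame(
        B, columns=[f"beta_{j}" for j in range(B.shape[1])]
    )
    df.insert(0, "study", np.arange(B.shape[0]))
    sup = np.zeros(B.shape[1], dtype=int)
    sup[np.asarray(data.support, dtype=int)] = 1
    df.loc[len(df)] = ["support", *sup]
    path = Path(path)
    df.to_csv(path, index=False)
    return path


def load_truth(path) -> tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path)
    sup_row = df[df["study"] == "support"]
    B = df[df["study"] != "support"].drop(columns="study").to_numpy(float)
    support = np.flatnonzero(sup_row.drop(columns="study").to_numpy(float)[0])
    return B, support
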