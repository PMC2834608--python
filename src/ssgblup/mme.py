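"""Sparse mixed-model equations, REML, and the profile likelihood over w.

Model: y = X beta + Z gbar + e with gbar ~ N(0, sigma2_g H_w) and
e ~ N(0, sigma2_e I).  With lambda = sigma2_e / sigma2_g the MME are

    [ X'X      X'Z              ] [beta]   [X'y]
    [ Z'X  Z'Z + lambda H_w^-1  ] [gbar] = [Z'y]

whose solution gives BLUEs and (G)EBVs; the REML log-likelihood is

    -2 l = (n-p-q) log sigma2_e + q log sigma2_g + log det H_w
           + log det C_lambda + (y'y - sol'rhs) / sigma2_e

up to a constant, where C_lambda is the MME coefficient matrix above.
Because there are exactly two variance components, the residual variance
profiles out analytically (sigma2_e-hat = (y'y - sol'rhs)/(n - p) at fixed
lambda) and REML reduces to an exact one-dimensional search over lambda;
this replaces the usual average-information iteration while satisfying the
same contract (maximise the REML likelihood).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg as la
import scipy.sparse as sp
from scipy.optimize import minimize_scalar
from scipy.sparse.linalg import splu

from .grm import GwBlock, HwInverse, blend_Gw, combined_inverse
from .pedigree import PedigreeProjection, RelationshipMatrix

__all__ = [
    "ModelFrame",
    "VarianceComponents",
    "MMESolution",
    "ProfileResult",
    "DensePrecision",
    "pedigree_precision",
    "assemble_mme",
    "solve_mme",
    "reml_loglik",
    "estimate_vc",
    "profile_w",
]

log = logging.getLogger("ssgblup.reml")


class MMEError(ValueError):
    pass


@dataclass
class VarianceComponents:
    """Total genetic variance sigma2_g (genomic + polygenic), residual
    variance sigma2_e, and the polygenic weight w in [0, 1]; the polygenic
    share of the genetic variance is w * sigma2_g."""

    sigma2_g: float
    sigma2_e: float
    w: float

    def __post_init__(self):
        if self.sigma2_g < 0 or self.sigma2_e <= 0:
            raise MMEError("variance components out of range")
        if not 0.0 <= self.w <= 1.0:
            raise MMEError("w must lie in [0, 1]")

    @property
    def lam(self) -> float:
        if self.sigma2_g == 0:
            return np.inf
        return self.sigma2_e / self.sigma2_g


@dataclass
class ModelFrame:
    """Phenotypes with their fixed-effect design and animal incidence.

    ``animal_idx`` maps each record to a position in the covariance
    operator's animal order (genotyped block first, then non-genotyped).
    """

    y: np.ndarray
    X: np.ndarray
    animal_idx: np.ndarray
    ids: list  # animal order of the genetic effect (covariance order)

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=float)
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        if self.X.shape[0] != self.y.size:
            self.X = self.X.T
        self.animal_idx = np.asarray(self.animal_idx, dtype=np.int64)
        if not (self.y.size == self.X.shape[0] == self.animal_idx.size):
            raise MMEError("y, X and animal_idx must have equal record counts")
        if self.animal_idx.min(initial=0) < 0 or (
            self.animal_idx.size and self.animal_idx.max() >= len(self.ids)
        ):
            raise MMEError("record maps to an animal outside the pedigree")

    @property
    def n(self) -> int:
        return self.y.size

    @property
    def Z(self) -> sp.csr_matrix:
        n, q = self.n, len(self.ids)
        return sp.csr_matrix(
            (np.ones(n), (np.arange(n), self.animal_idx)), shape=(n, q)
        )


@dataclass
class MMESolution:
    ids: list
    beta: np.ndarray
    gebv: np.ndarray
    pev: np.ndarray | None
    logL: float
    vc: VarianceComponents

    def gebv_of(self, animals) -> np.ndarray:
        idx = {a: i for i, a in enumerate(self.ids)}
        return np.array([self.gebv[idx[a]] for a in animals])


@dataclass
class ProfileResult:
    grid: np.ndarray
    logL: np.ndarray
    w_hat: float
    ci: tuple
    vc_at_w_hat: VarianceComponents
    solutions: dict = field(default_factory=dict)


class DensePrecision:
    """Adapter exposing a dense covariance H through the same interface as
    the sparse-plus-block H_w^-1 (used by the two-step comparator)."""

    def __init__(self, ids, H):
        self.ids = list(ids)
        H = np.asarray(H, dtype=float)
        cf = la.cho_factor(H, lower=True)
        self.logdet = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
        self._Q = la.cho_solve(cf, np.eye(H.shape[0]))

    def sparse(self) -> sp.csc_matrix:
        return sp.csc_matrix(self._Q)


def _reparameterise_X(X: np.ndarray):
    """Drop linearly dependent columns of X (pivoted QR), with a warning."""
    if X.ndim == 1:
        X = X[:, None]
    q, r, piv = la.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = max(X.shape) * np.finfo(float).eps * (diag[0] if diag.size else 0.0)
    rank = int(np.sum(diag > tol))
    if rank < X.shape[1]:
        warnings.warn(
            f"fixed-effect design is rank deficient (rank {rank} of {X.shape[1]}); "
            "dependent columns dropped"
        )
        keep = np.sort(piv[:rank])
        return X[:, keep], keep
    return X, np.arange(X.shape[1])


@dataclass
class MMESystem:
    C: sp.csc_matrix
    rhs: np.ndarray
    frame: ModelFrame
    p: int
    q: int
    lam: float
    Hlogdet: float
    kept_cols: np.ndarray


def assemble_mme(frame: ModelFrame, hw_inv, vc: VarianceComponents) -> MMESystem:
    """Sparse MME coefficient matrix and right-hand side at lambda =
    sigma2_e / sigma2_g."""
    lam = vc.lam
    if not np.isfinite(lam):
        raise MMEError("sigma2_g = 0: use the shrinkage limit analytically")
    X, kept = _reparameterise_X(frame.X)
    Z = frame.Z
    Q = hw_inv.sparse()
    XtX = sp.csc_matrix(X.T @ X)
    XtZ = sp.csc_matrix(X.T @ Z)
    C = sp.bmat(
        [[XtX, XtZ], [XtZ.T, (Z.T @ Z + lam * Q).tocsc()]], format="csc"
    )
    rhs = np.concatenate([X.T @ frame.y, Z.T @ frame.y])
    return MMESystem(C, rhs, frame, X.shape[1], Q.shape[0], lam, hw_inv.logdet, kept)


def _splu_logdet(lu) -> float:
    return float(np.sum(np.log(np.abs(lu.U.diagonal()))))


def _neg2_reml(system: MMESystem, lu, sol) -> tuple:
    """Pieces shared by solve/logL: (SSR, logdetC)."""
    ssr = float(system.frame.y @ system.frame.y - sol @ system.rhs)
    return max(ssr, 1e-300), _splu_logdet(lu)


def _loglik_from_pieces(system: MMESystem, ssr, logdetC, vc: VarianceComponents) -> float:
    n, p, q = system.frame.n, system.p, system.q
    m2l = (
        (n - p - q) * np.log(vc.sigma2_e)
        + q * np.log(vc.sigma2_g)
        + system.Hlogdet
        + logdetC
        + ssr / vc.sigma2_e
    )
    return -0.5 * m2l


def solve_mme(system: MMESystem, vc: VarianceComponents | None = None,
              pev_for=None) -> MMESolution:
    """Solve the assembled system by a sparse symmetric factorisation.

    PEV_i = sigma2_e * (C_lambda^-1)_{ii} over the genetic block; computed
    for all animals by default, for ``pev_for`` (id list) only, or skipped
    with ``pev_for=False``.
    """
    if vc is None:
        raise MMEError("variance components required to scale PEV and logL")
    try:
        lu = splu(system.C, permc_spec="MMD_AT_PLUS_A")
    except RuntimeError as e:
        raise MMEError(f"MME coefficient matrix is singular: {e}") from e
    sol = lu.solve(system.rhs)
    if not np.all(np.isfinite(sol)):
        raise MMEError("MME solve produced non-finite values (singular genetic block?)")
    ssr, logdetC = _neg2_reml(system, lu, sol)
    logL = _loglik_from_pieces(system, ssr, logdetC, vc)
    p = system.p
    ids = system.frame.ids
    beta = np.full(system.frame.X.shape[1], np.nan)
    beta[system.kept_cols] = sol[:p]
    pev = None
    if pev_for is not False:
        if pev_for is None:
            cols = np.arange(len(ids))
        else:
            idx = {a: i for i, a in enumerate(ids)}
            cols = np.array([idx[a] for a in pev_for], dtype=np.int64)
        pev = np.full(len(ids), np.nan)
        e = np.zeros(system.C.shape[0])
        for c in cols:
            e[p + c] = 1.0
            pev[c] = vc.sigma2_e * lu.solve(e)[p + c]
            e[p + c] = 0.0
    return MMESolution(list(ids), beta, sol[p:], pev, logL, vc)


def reml_loglik(frame: ModelFrame, hw_inv, vc: VarianceComponents) -> float:
    """REML log-likelihood (up to an additive constant) via the sparse MME.

    Equals the dense expression -1/2 [log det V + log det(X'V^-1 X) +
    (y - X beta)' V^-1 (y - X beta)] with V = sigma2_g Z H_w Z' +
    sigma2_e I, by the standard determinant identities.
    """
    system = assemble_mme(frame, hw_inv, vc)
    lu = splu(system.C, permc_spec="MMD_AT_PLUS_A")
    sol = lu.solve(system.rhs)
    ssr, logdetC = _neg2_reml(system, lu, sol)
    return _loglik_from_pieces(system, ssr, logdetC, vc)


def estimate_vc(frame: ModelFrame, hw_inv, w: float, lam_bounds=(1e-6, 1e6),
                max_iter=100, tol=1e-10) -> tuple[VarianceComponents, float]:
    """REML estimates of (sigma2_g, sigma2_e) at fixed polygenic weight w.

    The residual variance is profiled out in closed form and the remaining
    one-dimensional likelihood in log(lambda) is maximised by Brent search;
    see the module docstring.  Returns (VarianceComponents, logL).
    """
    X, _ = _reparameterise_X(frame.X)
    n, p = frame.n, X.shape[1]
    if n <= p:
        raise MMEError("no residual degrees of freedom: n <= p")
    yty = float(frame.y @ frame.y)
    q = len(frame.ids)
    Hlogdet = hw_inv.logdet
    Q = hw_inv.sparse()
    Z = frame.Z
    ZtZ = (Z.T @ Z).tocsc()
    XtX = sp.csc_matrix(X.T @ X)
    XtZ = sp.csc_matrix(X.T @ Z)
    rhs = np.concatenate([X.T @ frame.y, Z.T @ frame.y])

    trace = []

    def neg2_profile(t: float) -> float:
        lam = float(np.exp(t))
        C = sp.bmat([[XtX, XtZ], [XtZ.T, ZtZ + lam * Q]], format="csc")
        lu = splu(C, permc_spec="MMD_AT_PLUS_A")
        sol = lu.solve(rhs)
        ssr = max(yty - sol @ rhs, 1e-300)
        phi = ssr / (n - p)
        m2l = (n - p) * np.log(phi) - q * t + Hlogdet + _splu_logdet(lu) + (n - p)
        trace.append((lam, -0.5 * m2l))
        log.debug("reml lambda=%.6g logL=%.6f", lam, -0.5 * m2l)
        return m2l

    res = minimize_scalar(
        neg2_profile,
        bounds=(np.log(lam_bounds[0]), np.log(lam_bounds[1])),
        method="bounded",
        options={"xatol": tol ** 0.5, "maxiter": max_iter},
    )
    if not res.success and res.status != 1:
        raise MMEError(f"REML did not converge: {res.message}; trace={trace[-5:]}")
    lam = float(np.exp(res.x))
    # recompute the profiled residual variance at the optimum
    C = sp.bmat([[XtX, XtZ], [XtZ.T, ZtZ + lam * Q]], format="csc")
    lu = splu(C, permc_spec="MMD_AT_PLUS_A")
    sol = lu.solve(rhs)
    ssr = max(yty - sol @ rhs, 1e-300)
    sigma2_e = ssr / (n - p)
    vc = VarianceComponents(sigma2_e / lam, sigma2_e, w)
    logL = _loglik_from_pieces(
        MMESystem(C, rhs, frame, p, q, lam, Hlogdet, np.arange(p)),
        ssr,
        _splu_logdet(lu),
        vc,
    )
    return vc, logL


def pedigree_precision(ped) -> HwInverse:
    """Classical animal-model precision: H = A, so H^-1 is just the sparse
    pedigree inverse (the no-genotype / w = 1 limit of the single step)."""
    from .pedigree import build_A_inverse

    Ainv = build_A_inverse(ped).tocsc()
    lu = splu(Ainv, permc_spec="MMD_AT_PLUS_A")
    return HwInverse(list(ped.ids), Ainv, np.zeros((0, 0)), -_splu_logdet(lu), 1.0)


DEFAULT_W_GRID = np.round(np.arange(0.01, 0.20, 0.02), 2)  # 0.01, 0.03, ..., 0.19


def profile_w(frame: ModelFrame, proj: PedigreeProjection, G: RelationshipMatrix,
              grid=None, ci_drop=3.84, w_bounds=(0.0, 1.0),
              keep_solutions=False) -> ProfileResult:
    """Profile REML log-likelihood over a grid of polygenic weights w.

    For each w the two variance components are estimated by REML and the
    maximised log-likelihood recorded.  The confidence set is
    {w : logL(w) > logL(w_hat) - ci_drop}, reported as the [min, max] of
    qualifying grid points and extended to the stated bounds when a grid
    boundary qualifies; ci_drop defaults to 3.84, the 95% quantile of a
    chi-square(1) distribution used as a direct log-likelihood drop.
    Ties at the maximum resolve to the smallest w.
    """
    grid = DEFAULT_W_GRID if grid is None else np.asarray(grid, dtype=float)
    if grid.size == 0 or np.any(np.diff(grid) <= 0):
        raise MMEError("w grid must be nonempty and strictly increasing")
    if np.any(grid <= 0) or np.any(grid > 1):
        raise MMEError("w grid values must lie in (0, 1]")
    logLs = np.full(grid.size, np.nan)
    vcs: list = [None] * grid.size
    sols = {}
    failures = []
    for k, w in enumerate(grid):
        try:
            Gw = blend_Gw(G, proj.A11, w)
            hw_inv = combined_inverse(proj, Gw)
            vcs[k], logLs[k] = estimate_vc(frame, hw_inv, w)
            if keep_solutions:
                system = assemble_mme(frame, hw_inv, vcs[k])
                sols[float(w)] = solve_mme(system, vcs[k], pev_for=False)
        except (MMEError, np.linalg.LinAlgError) as e:  # pragma: no cover
            failures.append((w, str(e)))
    if np.all(np.isnan(logLs)):
        raise MMEError(f"REML failed at every grid point: {failures}")
    k_hat = int(np.nanargmax(logLs))
    w_hat = float(grid[k_hat])
    ok = np.where(logLs > logLs[k_hat] - ci_drop)[0]
    lo, hi = float(grid[ok[0]]), float(grid[ok[-1]])
    if ok[0] == 0:
        lo = float(w_bounds[0])
    if ok[-1] == grid.size - 1:
        hi = float(w_bounds[1])
    return ProfileResult(grid, logLs, w_hat, (lo, hi), vcs[k_hat], sols)
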