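"""Restricted maximum-likelihood variance-component estimation.

Fits ``y = X b + sum_k g_k + e`` with ``Var(g_k) = A_k sigma2_k`` by REML:
one EM warm-up step followed by average-information (AI) updates with
step-halving, so the restricted log-likelihood never decreases on an
accepted step. Case-control phenotypes are analysed as 0/1 on the observed
scale (linear mixed model); conversion to the liability scale is a
post-hoc multiplication by the ascertainment-corrected factor.

Two equivalent computational paths are provided: a generic dense path for
any number of relationship matrices, and a fast single-matrix path that
rotates the problem through one eigendecomposition.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

from liabkit.grm import GRM
from liabkit.liability import LiabilityContext

logger = logging.getLogger(__name__)

__all__ = [
    "RemlSettings",
    "VarianceComponentFit",
    "LiabilityEstimates",
    "reml_fit",
    "h2_liability_from_fit",
    "covariate_difference_h2",
]


@dataclass(frozen=True)
class RemlSettings:
    max_iter: int = 100
    tol: float = 1e-4  # absolute log-likelihood change at convergence
    var_floor_frac: float = 1e-6  # floor = frac * phenotypic variance
    use_eigen_single: bool = True  # one-GRM fast path via eigendecomposition
    allow_negative: bool = False  # unconstrained genetic components (residual stays floored)

    def __post_init__(self) -> None:
        if self.tol <= 0:
            raise ValueError("tolerance must be positive")


@dataclass
class VarianceComponentFit:
    """Estimates and diagnostics of a (multi-component) REML fit.

    ``sigma`` holds the k genetic variances followed by the residual variance.
    """

    sigma: np.ndarray
    se_sigma: np.ndarray
    sigma_cov: np.ndarray  # covariance of sigma from the inverse AI matrix
    h2_obs: np.ndarray  # per-GRM observed-scale fractions
    se_h2_obs: np.ndarray
    h2_obs_total: float
    se_h2_obs_total: float
    fixed_effects: np.ndarray
    loglik: float
    n_iter: int
    converged: bool
    identifiable: bool
    at_floor: np.ndarray
    trace: list = field(default_factory=list)

    @property
    def n_components(self) -> int:
        return len(self.sigma) - 1


@dataclass(frozen=True)
class LiabilityEstimates:
    components: np.ndarray
    se_components: np.ndarray
    total: float
    se_total: float


class _State:
    __slots__ = ("ll", "score", "ai", "beta", "quads", "traces")

    def __init__(self, ll, score, ai, beta, quads, traces):
        self.ll, self.score, self.ai, self.beta = ll, score, ai, beta
        self.quads, self.traces = quads, traces


class _DenseBackend:
    """Explicit V / P evaluation; cost O(n^3) per likelihood evaluation."""

    def __init__(self, As: list[np.ndarray], y: np.ndarray, X: np.ndarray):
        self.As, self.y, self.X = As, y, X
        self.n = len(y)
        self.k = len(As)

    def evaluate(self, sigma: np.ndarray) -> _State | None:
        n, k = self.n, self.k
        V = sigma[k] * np.eye(n)
        for s, A in zip(sigma[:k], self.As):
            V += s * A
        try:
            c, low = linalg.cho_factor(V, check_finite=False)
        except linalg.LinAlgError:
            return None
        logdet_v = 2.0 * np.sum(np.log(np.diag(c)))
        Vinv = linalg.cho_solve((c, low), np.eye(n), check_finite=False)
        VinvX = Vinv @ self.X
        XtVX = self.X.T @ VinvX
        sign, logdet_x = np.linalg.slogdet(XtVX)
        if sign <= 0:
            return None
        beta = np.linalg.solve(XtVX, VinvX.T @ self.y)
        P = Vinv - VinvX @ np.linalg.solve(XtVX, VinvX.T)
        Py = P @ self.y
        ypy = float(self.y @ Py)
        ll = -0.5 * (logdet_v + logdet_x + ypy)

        traces = np.empty(k + 1)
        quads = np.empty(k + 1)
        u = np.empty((k + 1, n))  # A_k P y (residual: P y itself times I)
        for i, A in enumerate(self.As):
            traces[i] = np.sum(P * A)
            u[i] = A @ Py
            quads[i] = float(Py @ u[i])
        traces[k] = np.trace(P)
        u[k] = Py
        quads[k] = float(Py @ Py)
        score = -0.5 * (traces - quads)
        Pu = P @ u.T
        ai = 0.5 * (u @ Pu)
        return _State(ll, score, ai, beta, quads, traces)


class _EigenBackend:
    """Single-GRM path: rotate by the GRM's eigenvectors so V is diagonal."""

    def __init__(self, A: np.ndarray, y: np.ndarray, X: np.ndarray):
        d, U = np.linalg.eigh(A)
        self.d = d
        self.y = U.T @ y
        self.X = U.T @ X
        self.n = len(y)
        self.k = 1

    def _apply_p(self, winv: np.ndarray, bw: np.ndarray, xtwx: np.ndarray, v: np.ndarray) -> np.ndarray:
        return winv * v - bw @ np.linalg.solve(xtwx, bw.T @ v)

    def evaluate(self, sigma: np.ndarray) -> _State | None:
        w = sigma[0] * self.d + sigma[1]
        if (w <= 0).any():
            return None
        winv = 1.0 / w
        bw = self.X * winv[:, None]  # W^-1 X
        xtwx = self.X.T @ bw
        sign, logdet_x = np.linalg.slogdet(xtwx)
        if sign <= 0:
            return None
        beta = np.linalg.solve(xtwx, bw.T @ self.y)
        resid = self.y - self.X @ beta
        Py = winv * resid
        ypy = float(self.y @ Py)
        ll = -0.5 * (float(np.sum(np.log(w))) + logdet_x + ypy)

        # tr(P M) = tr(W^-1 M) - tr((X'W^-1X)^-1 X' W^-1 M W^-1 X) for diag M
        def tr_p(m_diag: np.ndarray) -> float:
            t1 = float(np.sum(m_diag * winv))
            inner = bw.T @ (m_diag[:, None] * bw)
            t2 = float(np.trace(np.linalg.solve(xtwx, inner)))
            return t1 - t2

        traces = np.array([tr_p(self.d), tr_p(np.ones(self.n))])
        u = np.vstack([self.d * Py, Py])
        quads = np.array([float(Py @ u[0]), float(Py @ u[1])])
        score = -0.5 * (traces - quads)
        Pu = np.column_stack([self._apply_p(winv, bw, xtwx, u[i]) for i in range(2)])
        ai = 0.5 * (u @ Pu)
        return _State(ll, score, ai, beta, quads, traces)


def _optimize(backend, settings: RemlSettings, var_p: float, initial_sigma=None):
    n, k = backend.n, backend.k
    floor = np.full(k + 1, settings.var_floor_frac * var_p)
    if settings.allow_negative:
        floor[:k] = -10.0 * var_p  # effectively unconstrained; V must stay PD
    if initial_sigma is not None:
        sigma = np.maximum(np.asarray(initial_sigma, dtype=float).copy(), floor)
        if len(sigma) != k + 1:
            raise ValueError("initial_sigma has wrong length")
    else:
        sigma = np.full(k + 1, var_p / (k + 1))
    state = backend.evaluate(sigma)
    if state is None:
        raise RuntimeError("restricted likelihood undefined at the starting point")
    trace = [(0, state.ll, sigma.copy())]
    converged = False
    n_iter = 0
    for it in range(1, settings.max_iter + 1):
        n_iter = it
        if it == 1:
            # EM warm-up: monotone and robust far from the optimum
            cand = sigma + sigma**2 * (state.quads - state.traces) / n
            cand = np.maximum(cand, floor)
            cand_state = backend.evaluate(cand)
            if cand_state is None or cand_state.ll < state.ll - 1e-8:
                cand, cand_state = sigma, state  # keep start if EM misbehaves numerically
        else:
            held = (sigma <= floor + 1e-12 + 1e-8 * np.abs(floor)) & (state.score < 0)
            free = ~held
            if not free.any():
                converged = True
                break
            try:
                delta = np.linalg.solve(
                    state.ai[np.ix_(free, free)], state.score[free]
                )
            except np.linalg.LinAlgError:
                delta = state.score[free] / np.maximum(np.diag(state.ai)[free], 1e-12)
            step = 1.0
            cand_state = None
            for _ in range(30):
                cand = sigma.copy()
                cand[free] = sigma[free] + step * delta
                cand = np.maximum(cand, floor)
                cand_state = backend.evaluate(cand)
                if cand_state is not None and cand_state.ll >= state.ll - 1e-10:
                    break
                step *= 0.5
            else:
                converged = True  # no improving direction left
                break
        if abs(cand_state.ll - state.ll) < settings.tol and it >= 2:
            converged = True
        sigma, state = cand, cand_state
        trace.append((it, state.ll, sigma.copy()))
        if converged:
            break
    return sigma, state, trace, converged, n_iter, floor


def _grm_values(g) -> np.ndarray:
    return g.values if isinstance(g, GRM) else np.asarray(g, dtype=float)


def reml_fit(
    grms,
    phenotype: np.ndarray,
    covariates: np.ndarray | None = None,
    settings: RemlSettings = RemlSettings(),
    initial_sigma: np.ndarray | None = None,
) -> VarianceComponentFit:
    """AI-REML fit of one or more GRM variance components.

    Parameters
    ----------
    grms
        A single :class:`~liabkit.grm.GRM` (or array) or a list of them, all
        on the same sample set.
    phenotype
        Observed phenotype vector; a 0/1 case-control status is analysed
        directly on the observed scale.
    covariates
        Fixed-effect design matrix. An intercept column is prepended when no
        constant column is present; ``None`` means intercept only.
    initial_sigma
        Optional warm start of length ``n_grms + 1`` (residual last).
    """
    if isinstance(grms, (GRM, np.ndarray)):
        grms = [grms]
    As = [_grm_values(g) for g in grms]
    ids = [g.sample_ids for g in grms if isinstance(g, GRM)]
    if ids and any(i != ids[0] for i in ids[1:]):
        raise ValueError("all GRMs must share the same sample set")
    y = np.asarray(phenotype, dtype=float)
    n = len(y)
    for A in As:
        if A.shape != (n, n):
            raise ValueError("GRM dimensions do not match phenotype length")

    if covariates is None:
        X = np.ones((n, 1))
    else:
        X = np.atleast_2d(np.asarray(covariates, dtype=float))
        if X.shape[0] != n:
            X = X.T
        has_const = np.any(np.ptp(X, axis=0) == 0)
        if not has_const:
            X = np.column_stack([np.ones(n), X])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("fixed-effect design matrix is singular")
    if n <= X.shape[1]:
        raise ValueError("more fixed effects than samples")

    var_p = float(y.var(ddof=1))
    if var_p == 0:
        raise ValueError("phenotype has zero variance")

    if len(As) == 1 and settings.use_eigen_single:
        backend = _EigenBackend(As[0], y, X)
    else:
        backend = _DenseBackend(As, y, X)

    sigma, state, trace, converged, n_iter, floor = _optimize(
        backend, settings, var_p, initial_sigma
    )
    if not converged:
        warnings.warn(
            f"REML did not converge in {n_iter} iterations; returning partial results",
            stacklevel=2,
        )

    k = len(As)
    at_floor = sigma <= floor + 1e-12 + 1e-8 * np.abs(floor)
    free = ~at_floor
    cov = np.zeros((k + 1, k + 1))
    identifiable = True
    if free.any():
        ai_free = state.ai[np.ix_(free, free)]
        cond = np.linalg.cond(ai_free)
        if cond > 1e8:
            identifiable = False
            warnings.warn(
                "AI matrix is near-singular: individual components are not "
                "separately identifiable (their sum remains estimable)",
                stacklevel=2,
            )
        cov[np.ix_(free, free)] = np.linalg.pinv(ai_free)
    se_sigma = np.sqrt(np.maximum(np.diag(cov), 0.0))

    total = float(sigma.sum())
    h2_obs = sigma[:k] / total
    se_h2 = np.empty(k)
    for j in range(k):
        g = np.full(k + 1, -sigma[j] / total**2)
        g[j] += 1.0 / total
        se_h2[j] = np.sqrt(max(float(g @ cov @ g), 0.0))
    genetic = float(sigma[:k].sum())
    g_tot = np.full(k + 1, sigma[k] / total**2)
    g_tot[k] = -genetic / total**2
    se_tot = np.sqrt(max(float(g_tot @ cov @ g_tot), 0.0))

    return VarianceComponentFit(
        sigma=sigma,
        se_sigma=se_sigma,
        sigma_cov=cov,
        h2_obs=h2_obs,
        se_h2_obs=se_h2,
        h2_obs_total=genetic / total,
        se_h2_obs_total=float(se_tot),
        fixed_effects=np.asarray(state.beta),
        loglik=float(state.ll),
        n_iter=n_iter,
        converged=converged,
        identifiable=identifiable,
        at_floor=at_floor,
        trace=trace,
    )


def h2_liability_from_fit(fit: VarianceComponentFit, context: LiabilityContext) -> LiabilityEstimates:
    """Convert a fit's observed-scale fractions to the liability scale; SEs
    scale by the same factor (delta method)."""
    f = context.factor
    return LiabilityEstimates(
        components=fit.h2_obs * f,
        se_components=fit.se_h2_obs * f,
        total=fit.h2_obs_total * f,
        se_total=fit.se_h2_obs_total * f,
    )


def _standardized_dosage(gm, snp_index: int) -> np.ndarray:
    from liabkit.io_formats import MISSING

    x = gm.dosages[:, snp_index].astype(float)
    ok = gm.dosages[:, snp_index] != MISSING
    mean = x[ok].mean()
    x = np.where(ok, x, mean)
    sd = x.std()
    if sd == 0:
        return np.zeros(len(x))
    return (x - mean) / sd


def covariate_difference_h2(
    gm,
    phenotype: np.ndarray,
    risk_snp_id: str,
    context: LiabilityContext,
    covariates: np.ndarray | None = None,
    chrom_grms: dict[int, GRM] | None = None,
    base_fit: VarianceComponentFit | None = None,
    settings: RemlSettings = RemlSettings(),
) -> tuple[float, float]:
    """Per-SNP heritability by the covariate-difference procedure.

    Runs the joint all-chromosome REML fit with and without the risk SNP's
    standardized dosage appended to the fixed effects, and returns the
    decrease in the host chromosome's liability-scale component, with SE by
    quadrature over the two fits.
    """
    from liabkit.grm import compute_grm

    try:
        snp_index = gm.snp_ids.index(risk_snp_id)
    except ValueError:
        raise ValueError(f"risk SNP {risk_snp_id} not present") from None
    host = gm.snps[snp_index].chromosome

    if chrom_grms is None:
        chrom_grms = {}
        chroms = gm.chromosomes
        for c in np.unique(chroms):
            ids = [s.id for s in gm.snps if s.chromosome == c]
            chrom_grms[int(c)] = compute_grm(gm, ids)
    chrom_order = sorted(chrom_grms)
    host_idx = chrom_order.index(host)
    grm_list = [chrom_grms[c] for c in chrom_order]

    x = _standardized_dosage(gm, snp_index)
    if np.all(x == 0):
        warnings.warn(f"risk SNP {risk_snp_id} is monomorphic: difference is 0", stacklevel=2)
        return 0.0, 0.0

    n = gm.n_samples
    X0 = np.ones((n, 1)) if covariates is None else covariates
    if base_fit is None:
        base_fit = reml_fit(grm_list, phenotype, X0, settings)
    X1 = np.column_stack([X0, x])
    fit_cov = reml_fit(
        grm_list, phenotype, X1, settings, initial_sigma=base_fit.sigma
    )

    base_l = h2_liability_from_fit(base_fit, context)
    cov_l = h2_liability_from_fit(fit_cov, context)
    diff = float(base_l.components[host_idx] - cov_l.components[host_idx])
    se = float(np.hypot(base_l.se_components[host_idx], cov_l.se_components[host_idx]))
    return diff, se
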