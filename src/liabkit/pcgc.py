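"""Phenotype-correlation genotype-correlation (PCGC) regression.

Ascertainment-robust liability-scale heritability for case-control data:
regress pairwise products of the P-standardized phenotype on GRM
off-diagonal entries (no intercept; the theoretical value at zero
relatedness is zero) and rescale the slope by the ascertainment-corrected
conversion factor ``K^2 (1-K)^2 / (z^2 P (1-P))``. Standard errors come
from a leave-one-block-out jackknife over samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from liabkit.grm import GRM
from liabkit.liability import liability_context

__all__ = ["PcgcFit", "pcgc_fit"]


@dataclass(frozen=True)
class PcgcFit:
    h2_l: float
    se: float
    slope: float
    intercept_diagnostic: float  # intercept of an auxiliary with-intercept fit
    n_blocks: int


def pcgc_fit(
    grm: GRM | np.ndarray,
    phenotype: np.ndarray,
    K: float,
    P: float | None = None,
    covariates: np.ndarray | None = None,
    n_blocks: int = 200,
) -> PcgcFit:
    """PCGC regression of one GRM against a binary phenotype.

    Parameters
    ----------
    grm
        Relationship matrix on the analysis samples.
    phenotype
        0/1 case-control status.
    K
        Population lifetime risk.
    P
        Sample case fraction; defaults to the observed fraction.
    covariates
        Optional fixed effects, residualized out of the standardized
        phenotype before forming pairwise products (extension; the plain
        no-covariate form is the default estimator).
    n_blocks
        Jackknife block count over samples.
    """
    A = grm.values if isinstance(grm, GRM) else np.asarray(grm, dtype=float)
    y = np.asarray(phenotype, dtype=float)
    n = len(y)
    if A.shape != (n, n):
        raise ValueError("GRM does not match phenotype length")
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("PCGC requires a binary 0/1 phenotype")
    if P is None:
        P = float(y.mean())
    if P < K:
        warnings.warn(
            f"sample case fraction P={P:.4g} below K={K:.4g}: "
            "inconsistent with positive ascertainment", stacklevel=2,
        )
    ctx = liability_context(K, P)

    ystar = (y - P) / np.sqrt(P * (1 - P))
    if covariates is not None:
        X = np.atleast_2d(np.asarray(covariates, dtype=float))
        if X.shape[0] != n:
            X = X.T
        X = np.column_stack([np.ones(n), X])
        ystar = ystar - X @ np.linalg.lstsq(X, ystar, rcond=None)[0]

    # pairwise sums over the off-diagonal, via whole-matrix contractions
    G = A.copy()
    np.fill_diagonal(G, 0.0)
    yy_g = ystar @ G @ ystar  # 2 * sum_{j<k} y*_j y*_k G_jk
    gg = float(np.sum(G * G))  # 2 * sum_{j<k} G_jk^2
    if gg == 0:
        raise ValueError("GRM off-diagonal is identically zero")
    slope = float(yy_g / gg)
    h2 = slope * ctx.factor

    # auxiliary with-intercept fit as a QC diagnostic
    n_pairs = n * (n - 1) / 2
    sum_g = float(G.sum()) / 2
    sum_p = float((ystar.sum() ** 2 - (ystar**2).sum()) / 2)
    sxx = gg / 2 - sum_g**2 / n_pairs
    sxy = yy_g / 2 - sum_g * sum_p / n_pairs
    slope_aux = sxy / sxx if sxx > 0 else np.nan
    intercept = sum_p / n_pairs - slope_aux * sum_g / n_pairs

    # block jackknife over samples: remove each block's pair contributions
    blocks = np.array_split(np.arange(n), min(n_blocks, n))
    row_num = ystar * (G @ ystar)  # per-sample sum of y*y*G over partners
    row_den = (G * G).sum(axis=1)
    estimates = []
    for b in blocks:
        sub = G[np.ix_(b, b)]
        ys = ystar[b]
        within_num = float(ys @ sub @ ys)
        within_den = float(np.sum(sub * sub))
        num_b = yy_g - 2 * row_num[b].sum() + within_num
        den_b = gg - 2 * row_den[b].sum() + within_den
        if den_b > 0:
            estimates.append(num_b / den_b * ctx.factor)
    estimates = np.asarray(estimates)
    B = len(estimates)
    se = float(np.sqrt((B - 1) / B * np.sum((estimates - estimates.mean()) ** 2)))

    return PcgcFit(
        h2_l=h2, se=se, slope=slope,
        intercept_diagnostic=float(intercept), n_blocks=B,
    )
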