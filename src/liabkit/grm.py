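"""Realized genetic relationship matrices and the LD-incompleteness adjustment.

Off-diagonal estimator (pairwise-complete over SNPs non-missing in both
samples)::

    A_jk = (1 / m_jk) * sum_i (x_ij - 2 p_i)(x_ik - 2 p_i) / (2 p_i (1 - p_i))

Diagonal uses the companion sample-specific estimator
``A_jj = 1 + (1/m_j) * sum_i [x_ij^2 - (1 + 2 p_i) x_ij + 2 p_i^2] / (2 p_i (1 - p_i))``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from liabkit.io_formats import MISSING, GenotypeMatrix

__all__ = ["GRM", "LdAdjustment", "allele_freqs", "compute_grm", "region_snp_subset", "ld_adjustment"]


@dataclass
class GRM:
    """Symmetric relationship matrix with per-pair SNP counts and sample ids."""

    values: np.ndarray  # (n, n) float64
    pair_counts: np.ndarray  # (n, n) int
    sample_ids: list[tuple[str, str]]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.sample_ids)
        if self.values.shape != (n, n):
            raise ValueError("GRM shape does not match sample ids")
        if not np.allclose(self.values, self.values.T, atol=1e-8):
            raise ValueError("GRM must be symmetric")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def offdiag(self) -> np.ndarray:
        """Lower-triangle off-diagonal entries as a flat vector."""
        i, j = np.tril_indices(self.n_samples, k=-1)
        return self.values[i, j]

    def subset(self, index: np.ndarray) -> "GRM":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GRM(
            values=self.values[np.ix_(index, index)],
            pair_counts=self.pair_counts[np.ix_(index, index)],
            sample_ids=[self.sample_ids[i] for i in index],
        )


@dataclass(frozen=True)
class LdAdjustment:
    maf_threshold: float
    beta: float
    h2_unadjusted: float
    h2_adjusted: float
    se_adjusted: float


def allele_freqs(gm: GenotypeMatrix) -> np.ndarray:
    """Frequency of the counted allele (allele1) per SNP, over non-missing calls."""
    ok = gm.dosages != MISSING
    counts = ok.sum(axis=0)
    if (counts == 0).any():
        j = int(np.flatnonzero(counts == 0)[0])
        raise ValueError(f"SNP {gm.snps[j].id}: all genotypes missing")
    return np.where(ok, gm.dosages, 0).sum(axis=0) / (2.0 * counts)


def compute_grm(gm: GenotypeMatrix, snp_subset: Sequence[str] | np.ndarray | None = None) -> GRM:
    """Compute the realized relationship matrix from (a subset of) SNPs.

    Monomorphic SNPs are excluded with a warning. Missing genotypes are
    handled pairwise-complete; per-pair SNP counts are recorded.
    """
    if snp_subset is not None:
        subset = set(snp_subset) if not isinstance(snp_subset, np.ndarray) else set(snp_subset.tolist())
        idx = [i for i, s in enumerate(gm.snps) if s.id in subset]
        if not idx:
            raise ValueError("empty SNP subset")
        gm = gm.subset_snps(np.asarray(idx))
    if gm.n_snps == 0:
        raise ValueError("no SNPs to compute GRM from")

    p = allele_freqs(gm)
    poly = (p > 0) & (p < 1)
    if not poly.all():
        warnings.warn(f"excluding {int((~poly).sum())} monomorphic SNPs from GRM", stacklevel=2)
        gm = gm.subset_snps(poly)
        p = p[poly]
    if gm.n_snps == 0:
        raise ValueError("all SNPs in subset are monomorphic")

    X = gm.dosages.astype(float)
    ok = gm.dosages != MISSING
    denom = 2.0 * p * (1.0 - p)

    # off-diagonal: standardized dosages with missing set to 0 contribute
    # exactly the pairwise-complete sum; counts via the indicator product
    Z = np.where(ok, (X - 2.0 * p) / np.sqrt(denom), 0.0)
    num = Z @ Z.T
    okf = ok.astype(float)
    counts = okf @ okf.T
    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.where(counts > 0, num / np.maximum(counts, 1), 0.0)

    # diagonal: 1 + (1/m_j) sum [x^2 - (1+2p)x + 2p^2] / (2p(1-p))
    diag_terms = np.where(ok, (X * X - (1.0 + 2.0 * p) * X + 2.0 * p * p) / denom, 0.0)
    m_j = ok.sum(axis=1)
    np.fill_diagonal(values, 1.0 + diag_terms.sum(axis=1) / np.maximum(m_j, 1))
    np.fill_diagonal(counts, m_j)

    return GRM(values=values, pair_counts=counts.astype(np.int64), sample_ids=list(gm.samples))


def region_snp_subset(
    gm: GenotypeMatrix,
    loci: Iterable[tuple[int, int]],
    window_bp: int = 500_000,
) -> list[str]:
    """SNP ids within ``window_bp`` (inclusive) of any locus, union over loci."""
    chroms = gm.chromosomes
    positions = gm.positions
    mask = np.zeros(gm.n_snps, dtype=bool)
    for chrom, pos in loci:
        on_chrom = chroms == chrom
        if not on_chrom.any():
            warnings.warn(f"locus chr{chrom}:{pos}: chromosome absent from data", stacklevel=2)
            continue
        mask |= on_chrom & (np.abs(positions - pos) <= window_bp)
    return [gm.snps[i].id for i in np.flatnonzero(mask)]


def ld_adjustment(
    grm_array: GRM,
    grm_causal_proxy: GRM,
    h2: float = np.nan,
    se: float = np.nan,
    maf_threshold: float = np.nan,
) -> LdAdjustment:
    """Incomplete-LD adjustment: regress centered array-GRM off-diagonals on
    centered causal-proxy off-diagonals through the origin; the adjusted
    heritability is ``h2 / beta`` with SE scaled by ``1 / beta``.
    """
    if grm_array.sample_ids != grm_causal_proxy.sample_ids:
        raise ValueError("GRMs must be computed on the same sample set")
    x = grm_causal_proxy.offdiag()
    y = grm_array.offdiag()
    x = x - x.mean()
    y = y - y.mean()
    beta = float(x @ y / (x @ x))
    if beta <= 0:
        raise ValueError(f"degenerate proxy SNP set: regression slope {beta:.4g} <= 0")
    return LdAdjustment(
        maf_threshold=maf_threshold,
        beta=beta,
        h2_unadjusted=h2,
        h2_adjusted=h2 / beta,
        se_adjusted=se / beta,
    )
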