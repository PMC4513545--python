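"""SNP- and sample-level quality control filters and the genomic inflation factor.

Filter order is fixed and logged: SNP call rate, then minor allele frequency,
then Hardy-Weinberg exact test computed in controls only.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import chi2

from liabkit.io_formats import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)

#: Median of the 1-df chi-squared distribution.
CHI2_1DF_MEDIAN = float(chi2.median(1))


@dataclass(frozen=True)
class QcThresholds:
    hwe_p_min: float = 1.0e-6
    snp_call_rate_min: float = 0.95
    maf_min: float = 0.01
    sample_call_rate_min: float = 0.95
    ibs_max: float = 0.80

    def __post_init__(self) -> None:
        for name in ("hwe_p_min", "snp_call_rate_min", "maf_min", "sample_call_rate_min", "ibs_max"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name}={v} must be in (0, 1)")


@dataclass
class QcReport:
    n_input: int
    removed: dict[str, int] = field(default_factory=dict)
    surviving_ids: list = field(default_factory=list)

    @property
    def n_removed(self) -> int:
        return sum(self.removed.values())

    @property
    def n_surviving(self) -> int:
        return len(self.surviving_ids)


def hwe_exact_p(n_hom1: int, n_het: int, n_hom2: int) -> float:
    """Two-sided Hardy-Weinberg exact test p-value.

    Sums the probabilities of all heterozygote counts (conditional on the
    observed allele counts) that are no more probable than the observed one.
    """
    counts = (n_hom1, n_het, n_hom2)
    if any(c < 0 or c != int(c) for c in counts):
        raise ValueError("genotype counts must be non-negative integers")
    n = sum(counts)
    if n == 0:
        raise ValueError("all genotype counts are zero")
    n_a = 2 * n_hom1 + n_het  # rarity side does not matter: distribution is symmetric
    # heterozygote count parity is fixed by the allele count
    hets = np.arange(n_a % 2, min(n_a, 2 * n - n_a) + 1, 2)
    # log-probability up to a constant: P(het) ∝ 2^het / (hom1! het! hom2!)
    from scipy.special import gammaln

    hom1 = (n_a - hets) // 2
    hom2 = n - hom1 - hets
    logp = hets * np.log(2.0) - gammaln(hom1 + 1) - gammaln(hets + 1) - gammaln(hom2 + 1)
    p = np.exp(logp - logp.max())
    p /= p.sum()
    p_obs = p[hets == n_het][0]
    return float(p[p <= p_obs * (1 + 1e-12)].sum())


def _genotype_counts(dosages: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-SNP (hom-allele1, het, hom-allele2) counts over non-missing samples."""
    n_hom1 = (dosages == 2).sum(axis=0)
    n_het = (dosages == 1).sum(axis=0)
    n_hom2 = (dosages == 0).sum(axis=0)
    return n_hom1, n_het, n_hom2


def snp_call_rates(gm: GenotypeMatrix) -> np.ndarray:
    return (gm.dosages != MISSING).mean(axis=0)


def sample_call_rates(gm: GenotypeMatrix) -> np.ndarray:
    return (gm.dosages != MISSING).mean(axis=1)


def minor_allele_freqs(gm: GenotypeMatrix) -> np.ndarray:
    ok = gm.dosages != MISSING
    with np.errstate(invalid="ignore"):
        freq = np.where(ok, gm.dosages, 0).sum(axis=0) / (2 * ok.sum(axis=0))
    return np.minimum(freq, 1 - freq)


def filter_snps(
    gm: GenotypeMatrix,
    controls_mask: np.ndarray,
    thresholds: QcThresholds = QcThresholds(),
) -> tuple[GenotypeMatrix, QcReport]:
    """Apply the SNP filters in fixed order: call rate, MAF, HWE-in-controls."""
    controls_mask = np.asarray(controls_mask, dtype=bool)
    if controls_mask.shape != (gm.n_samples,):
        raise ValueError("controls_mask must align with samples")
    report = QcReport(n_input=gm.n_snps)
    keep = np.ones(gm.n_snps, dtype=bool)

    call = snp_call_rates(gm)
    fail_call = call < thresholds.snp_call_rate_min
    report.removed["call_rate"] = int(fail_call.sum())
    keep &= ~fail_call

    maf = minor_allele_freqs(gm)
    fail_maf = keep & (maf < thresholds.maf_min)
    report.removed["maf"] = int(fail_maf.sum())
    keep &= ~fail_maf

    if controls_mask.sum() == 0:
        warnings.warn("no controls present: HWE filter skipped", stacklevel=2)
        report.removed["hwe"] = 0
    else:
        ctl = gm.dosages[controls_mask]
        n_hom1, n_het, n_hom2 = _genotype_counts(ctl)
        fail_hwe = np.zeros(gm.n_snps, dtype=bool)
        for j in np.flatnonzero(keep):
            total = n_hom1[j] + n_het[j] + n_hom2[j]
            if total == 0:
                continue  # SNP entirely missing in controls: HWE not evaluable
            if hwe_exact_p(n_hom1[j], n_het[j], n_hom2[j]) < thresholds.hwe_p_min:
                fail_hwe[j] = True
        report.removed["hwe"] = int(fail_hwe.sum())
        keep &= ~fail_hwe

    logger.info(
        "SNP QC: %d -> %d (call_rate %d, maf %d, hwe %d)",
        gm.n_snps, int(keep.sum()), report.removed["call_rate"],
        report.removed["maf"], report.removed["hwe"],
    )
    out = gm.subset_snps(keep)
    report.surviving_ids = out.snp_ids
    return out, report


def filter_samples(
    gm: GenotypeMatrix,
    thresholds: QcThresholds = QcThresholds(),
    pairwise_ibs: np.ndarray | None = None,
) -> tuple[GenotypeMatrix, QcReport]:
    """Remove low-call-rate samples, then one member of each pair with
    IBS above the threshold (the lower-call-rate member; ties drop the
    later sample)."""
    report = QcReport(n_input=gm.n_samples)
    call = sample_call_rates(gm)
    keep = call >= thresholds.sample_call_rate_min
    report.removed["call_rate"] = int((~keep).sum())

    n_rel = 0
    if pairwise_ibs is not None:
        ibs = np.asarray(pairwise_ibs, dtype=float)
        if ibs.shape != (gm.n_samples, gm.n_samples):
            raise ValueError("pairwise_ibs must be n x n")
        if not np.allclose(ibs, ibs.T):
            raise ValueError("pairwise_ibs must be symmetric")
        # greedy: repeatedly break the surviving pair with highest IBS
        while True:
            idx = np.flatnonzero(keep)
            sub = ibs[np.ix_(idx, idx)].copy()
            np.fill_diagonal(sub, -np.inf)
            i, j = np.unravel_index(np.argmax(sub), sub.shape)
            if sub[i, j] <= thresholds.ibs_max:
                break
            a, b = idx[i], idx[j]
            if call[a] < call[b]:
                drop = a
            elif call[b] < call[a]:
                drop = b
            else:
                drop = max(a, b)
            keep[drop] = False
            n_rel += 1
    report.removed["relatedness"] = n_rel

    out = gm.subset_samples(keep)
    report.surviving_ids = out.samples
    return out, report


def genomic_inflation(chi2_stats: np.ndarray) -> float:
    """Genomic inflation factor: median 1-df association chi-squared over the
    null median 0.4549364."""
    stats = np.asarray(chi2_stats, dtype=float)
    if stats.size == 0:
        raise ValueError("no association statistics supplied")
    return float(np.median(stats) / CHI2_1DF_MEDIAN)


def trend_test_chi2(gm: GenotypeMatrix, status: np.ndarray) -> np.ndarray:
    """Cochran-Armitage trend statistics (1 df), one per SNP.

    Missing genotypes are dropped per SNP. Monomorphic SNPs get statistic 0.
    """
    y = np.asarray(status, dtype=float)
    stats = np.zeros(gm.n_snps)
    X = gm.dosages
    for j in range(gm.n_snps):
        ok = X[:, j] != MISSING
        x = X[ok, j].astype(float)
        yy = y[ok]
        n = x.size
        vx = x.var()
        vy = yy.var()
        if n == 0 or vx == 0 or vy == 0:
            continue
        r = np.corrcoef(x, yy)[0, 1]
        stats[j] = n * r * r
    return stats
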