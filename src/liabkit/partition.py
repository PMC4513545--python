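"""Genome-partitioned heritability.

Per-chromosome joint fits with the chromosome-length regression, the
risk-locus two-GRM split, the annotation (e.g. transcript / non-transcript)
two-GRM split, and subtype-stratified all-SNP fits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from liabkit.grm import compute_grm, region_snp_subset
from liabkit.greml import RemlSettings, h2_liability_from_fit, reml_fit
from liabkit.io_formats import AnnotationSet, GenotypeMatrix, PhenotypeTable
from liabkit.liability import LiabilityContext, liability_context

__all__ = [
    "PartitionResult",
    "per_chromosome_partition",
    "risk_loci_partition",
    "annotation_partition",
    "stratified_heritability",
]


@dataclass
class PartitionResult:
    labels: list[str]
    estimates: np.ndarray  # liability-scale variance fractions per part
    ses: np.ndarray
    snp_counts: list[int]
    total: float
    se_total: float
    converged: bool
    regression: dict = field(default_factory=dict)  # slope/intercept/r2 when applicable
    extras: dict = field(default_factory=dict)


def _chrom_lengths(gm: GenotypeMatrix, mode: str = "span") -> dict[int, float]:
    """Chromosome 'length': bp span of analyzed SNPs (default) or SNP count."""
    out: dict[int, float] = {}
    chroms = gm.chromosomes
    positions = gm.positions
    for c in np.unique(chroms):
        mask = chroms == c
        if mode == "span":
            out[int(c)] = float(positions[mask].max() - positions[mask].min() + 1)
        elif mode == "count":
            out[int(c)] = float(mask.sum())
        else:
            raise ValueError(f"unknown length mode {mode!r}")
    return out


def per_chromosome_partition(
    gm: GenotypeMatrix,
    phenotype: np.ndarray,
    context: LiabilityContext,
    covariates: np.ndarray | None = None,
    settings: RemlSettings = RemlSettings(),
    length_mode: str = "span",
) -> PartitionResult:
    """One GRM per chromosome, fitted jointly; estimates regressed on
    chromosome length."""
    chroms = np.unique(gm.chromosomes)
    if len(chroms) < 2:
        raise ValueError("need at least two chromosomes to partition")
    grms = []
    counts = []
    for c in chroms:
        ids = [s.id for s in gm.snps if s.chromosome == c]
        counts.append(len(ids))
        grms.append(compute_grm(gm, ids))
    fit = reml_fit(grms, phenotype, covariates, settings)
    liab = h2_liability_from_fit(fit, context)

    lengths = _chrom_lengths(gm, length_mode)
    x = np.array([lengths[int(c)] for c in chroms])
    if np.ptp(x) == 0:  # equal-length chromosomes: regression undefined
        regression = {"slope": float("nan"), "intercept": float("nan"), "r2": 0.0}
    else:
        reg = stats.linregress(x, liab.components)
        regression = {
            "slope": float(reg.slope),
            "intercept": float(reg.intercept),
            "r2": float(reg.rvalue**2),
        }
    return PartitionResult(
        labels=[f"chr{int(c)}" for c in chroms],
        estimates=liab.components,
        ses=liab.se_components,
        snp_counts=counts,
        total=liab.total,
        se_total=liab.se_total,
        converged=fit.converged,
        regression=regression,
        extras={"fit": fit, "chromosome_lengths": x.tolist()},
    )


def risk_loci_partition(
    gm: GenotypeMatrix,
    phenotype: np.ndarray,
    loci: list[tuple[int, int]],
    context: LiabilityContext,
    window_bp: int = 500_000,
    covariates: np.ndarray | None = None,
    settings: RemlSettings = RemlSettings(),
) -> PartitionResult:
    """Two-GRM joint fit: SNPs within ``window_bp`` of the risk loci versus
    all remaining SNPs."""
    locus_ids = region_snp_subset(gm, loci, window_bp)
    if not locus_ids:
        raise ValueError("no SNPs fall within the risk-locus windows")
    locus_set = set(locus_ids)
    rest_ids = [s.id for s in gm.snps if s.id not in locus_set]
    if not rest_ids:
        raise ValueError("risk-locus windows cover every SNP; nothing to contrast")
    grm_loci = compute_grm(gm, locus_ids)
    grm_rest = compute_grm(gm, rest_ids)
    fit = reml_fit([grm_loci, grm_rest], phenotype, covariates, settings)
    liab = h2_liability_from_fit(fit, context)
    return PartitionResult(
        labels=["risk_loci", "remainder"],
        estimates=liab.components,
        ses=liab.se_components,
        snp_counts=[len(locus_ids), len(rest_ids)],
        total=liab.total,
        se_total=liab.se_total,
        converged=fit.converged,
        extras={"fit": fit, "locus_snp_ids": locus_ids},
    )


def annotation_partition(
    gm: GenotypeMatrix,
    phenotype: np.ndarray,
    annotation: AnnotationSet,
    context: LiabilityContext,
    covariates: np.ndarray | None = None,
    settings: RemlSettings = RemlSettings(),
    labels: tuple[str, str] = ("transcript", "non_transcript"),
) -> PartitionResult:
    """Two-GRM joint fit over an annotation split (e.g. transcript vs not)."""
    inside = annotation.contains_many(gm.chromosomes, gm.positions)
    ids_in = [s.id for s, flag in zip(gm.snps, inside) if flag]
    ids_out = [s.id for s, flag in zip(gm.snps, inside) if not flag]
    for name, ids in zip(labels, (ids_in, ids_out)):
        if not ids:
            raise ValueError(f"annotation class {name!r} contains no SNPs")
    grm_in = compute_grm(gm, ids_in)
    grm_out = compute_grm(gm, ids_out)
    fit = reml_fit([grm_in, grm_out], phenotype, covariates, settings)
    liab = h2_liability_from_fit(fit, context)
    return PartitionResult(
        labels=list(labels),
        estimates=liab.components,
        ses=liab.se_components,
        snp_counts=[len(ids_in), len(ids_out)],
        total=liab.total,
        se_total=liab.se_total,
        converged=fit.converged,
        extras={"fit": fit, "fraction_in_class": len(ids_in) / gm.n_snps},
    )


def stratified_heritability(
    gm: GenotypeMatrix,
    phenotypes: PhenotypeTable,
    K: float,
    covariates: np.ndarray | None = None,
    settings: RemlSettings = RemlSettings(),
    min_cases: int = 50,
    grm=None,
) -> dict[str, tuple[float, float]]:
    """Independent all-SNP fit per case subtype (subtype cases + all controls),
    each with its own case fraction in the liability transform.

    Returns ``{subtype: (h2_l, se)}``; undersized strata are skipped.
    """
    if phenotypes.subtype is None:
        raise ValueError("phenotypes carry no subtype labels")
    if grm is None:
        grm = compute_grm(gm)
    status = phenotypes.status
    controls = np.flatnonzero(status == 0)
    labels = sorted({s for s in phenotypes.subtype if s is not None})
    out: dict[str, tuple[float, float]] = {}
    for label in labels:
        cases = np.flatnonzero(
            [s == label and y == 1 for s, y in zip(phenotypes.subtype, status)]
        )
        if cases.size < min_cases:
            warnings.warn(
                f"subtype {label!r}: {cases.size} cases < {min_cases}, skipped",
                stacklevel=2,
            )
            continue
        idx = np.concatenate([cases, controls])
        sub_grm = grm.subset(idx)
        y = status[idx].astype(float)
        P = float(y.mean())
        ctx = liability_context(K, P)
        X = None if covariates is None else covariates[idx]
        fit = reml_fit(sub_grm, y, X, settings)
        liab = h2_liability_from_fit(fit, ctx)
        out[label] = (liab.total, liab.se_total)
    return out
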