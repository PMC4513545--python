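"""Reproducible synthetic case-control cohorts under the liability threshold model.

Genotypes are Hardy-Weinberg draws at MAFs from a configurable law, with
optional within-block LD through a latent Gaussian copula on haplotypes.
Liability is a weighted sum of standardized causal dosages plus a normal
residual; disease status is liability above the threshold implied by the
lifetime risk ``K``. Ascertained cohorts are produced by exact rejection
sampling from the population model (non-causal genotypes, which are
independent of phenotype, are drawn only for the retained individuals).

All randomness flows from a single integer seed through spawned streams of
the counter-based Philox generator, one stream per operation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.stats import norm

from liabkit.io_formats import GenotypeMatrix, PhenotypeTable, SnpRecord

__all__ = [
    "RiskSnpSpec",
    "SimulationConfig",
    "SimulatedCohort",
    "simulate_genotypes",
    "simulate_liability_phenotype",
    "ascertain_cohort",
    "simulate_ascertained_cohort",
    "assign_subtypes",
]

_POSITION_STEP = 20_000  # bp between adjacent simulated SNPs


@dataclass(frozen=True)
class RiskSnpSpec:
    """A designated risk SNP: its MAF, its share of liability variance, and
    (optionally) the chromosome that hosts it."""

    maf: float
    share: float
    chromosome: int | None = None


@dataclass(frozen=True)
class SimulationConfig:
    n_cases: int
    n_controls: int
    m: int
    h2_l: float
    K: float
    seed: int
    maf_law: tuple[str, float, float] = ("uniform", 0.05, 0.5)
    causal_fraction: float = 0.1
    causal_snps: Sequence[int] | None = None  # explicit causal indices
    risk_snps: tuple[RiskSnpSpec, ...] = ()
    n_chromosomes: int = 2
    chrom_snp_counts: Sequence[int] | None = None
    ld_block_size: int = 1
    ld_rho: float = 0.0
    subtype_proportions: Sequence[float] | None = None
    subtype_names: Sequence[str] | None = None
    max_batches: int = 200

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if not 0 < self.K < 1:
            raise ValueError("K must be in (0, 1)")
        share_sum = sum(r.share for r in self.risk_snps)
        if not share_sum <= self.h2_l <= 1:
            raise ValueError(
                f"need sum(risk shares)={share_sum} <= h2_l={self.h2_l} <= 1"
            )
        if not 0 <= self.ld_rho < 1:
            raise ValueError("ld_rho must be in [0, 1)")
        if self.chrom_snp_counts is not None and sum(self.chrom_snp_counts) != self.m:
            raise ValueError("chrom_snp_counts must sum to m")

    @property
    def n_samples(self) -> int:
        return self.n_cases + self.n_controls

    @property
    def case_fraction(self) -> float:
        return self.n_cases / self.n_samples

    def snp_layout(self) -> tuple[np.ndarray, np.ndarray]:
        """(chromosome, position) arrays for the m simulated SNPs."""
        if self.chrom_snp_counts is not None:
            counts = list(self.chrom_snp_counts)
        else:
            base = self.m // self.n_chromosomes
            counts = [base] * self.n_chromosomes
            for i in range(self.m - base * self.n_chromosomes):
                counts[i] += 1
        chroms = np.repeat(np.arange(1, len(counts) + 1), counts)
        positions = np.concatenate(
            [np.arange(1, c + 1) * _POSITION_STEP for c in counts]
        )
        return chroms.astype(int), positions.astype(np.int64)

    def risk_snp_indices(self) -> list[int]:
        """Deterministic placement: the middle SNP of the host chromosome
        (round-robin hosts when unspecified), shifted to keep indices unique."""
        chroms, _ = self.snp_layout()
        taken: set[int] = set()
        out = []
        for i, spec in enumerate(self.risk_snps):
            host = spec.chromosome or (i % self.n_chromosomes) + 1
            on = np.flatnonzero(chroms == host)
            if on.size == 0:
                raise ValueError(f"risk SNP {i}: chromosome {host} not in layout")
            j = int(on[len(on) // 2])
            while j in taken:
                j += 1
            taken.add(j)
            out.append(j)
        return out


@dataclass
class SimulatedCohort:
    genotypes: GenotypeMatrix
    phenotypes: PhenotypeTable
    truth: dict = field(default_factory=dict)
    config: SimulationConfig | None = None


def _rng_streams(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.Generator(np.random.Philox(s)) for s in np.random.SeedSequence(seed).spawn(n)]


def _draw_mafs(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    law, a, b = config.maf_law
    if law == "uniform":
        p = rng.uniform(a, b, size=config.m)
    elif law == "beta":
        p = np.minimum(rng.beta(a, b, size=config.m), 0.5)
        p = np.maximum(p, 0.01)
    else:
        raise ValueError(f"unknown MAF law {law!r}")
    for j, spec in zip(config.risk_snp_indices(), config.risk_snps):
        p[j] = spec.maf
    return p


def _draw_genotype_block(
    p: np.ndarray, n: int, rng: np.random.Generator, block: int, rho: float
) -> np.ndarray:
    """HWE genotypes at frequencies ``p``; optional equicorrelated latent
    Gaussian within blocks of ``block`` adjacent SNPs (applied per haplotype)."""
    m = len(p)
    if block <= 1 or rho == 0.0:
        g = (rng.random((n, m)) < p).astype(np.int8)
        g += (rng.random((n, m)) < p).astype(np.int8)
        return g
    thr = norm.ppf(p)
    g = np.zeros((n, m), dtype=np.int8)
    for _hap in range(2):
        eps = rng.standard_normal((n, m))
        z = np.empty((n, m))
        for start in range(0, m, block):
            stop = min(start + block, m)
            shared = rng.standard_normal(n)[:, None]
            z[:, start:stop] = np.sqrt(rho) * shared + np.sqrt(1 - rho) * eps[:, start:stop]
        g += (z < thr).astype(np.int8)
    return g


def _make_snp_records(config: SimulationConfig) -> list[SnpRecord]:
    chroms, positions = config.snp_layout()
    return [
        SnpRecord(id=f"snp{j + 1}", chromosome=int(chroms[j]), position=int(positions[j]),
                  allele1="A", allele2="G")
        for j in range(config.m)
    ]


def _sample_keys(n: int, prefix: str = "S") -> list[tuple[str, str]]:
    return [(f"{prefix}{i + 1}", f"{prefix}{i + 1}") for i in range(n)]


def simulate_genotypes(config: SimulationConfig, n: int | None = None) -> GenotypeMatrix:
    """Draw a population genotype matrix (no phenotype, no ascertainment)."""
    rng_maf, rng_geno = _rng_streams(config.seed, 2)
    p = _draw_mafs(config, rng_maf)
    n = config.n_samples if n is None else n
    g = _draw_genotype_block(p, n, rng_geno, config.ld_block_size, config.ld_rho)
    return GenotypeMatrix(_sample_keys(n), _make_snp_records(config), g)


def build_effects(
    config: SimulationConfig, rng: np.random.Generator, class_masks: dict | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Per-SNP effects on the standardized-dosage scale, so the population
    genetic variance is exactly ``h2_l``.

    Designated risk SNPs get fixed effects ``sqrt(share)``; the polygenic
    remainder is spread equally (random signs) over the causal set. When
    ``class_masks`` maps labels to (mask, variance) pairs, each class carries
    its own variance budget instead.
    """
    beta = np.zeros(config.m)
    risk_idx = config.risk_snp_indices()
    for j, spec in zip(risk_idx, config.risk_snps):
        beta[j] = np.sqrt(spec.share) * rng.choice([-1.0, 1.0])

    if class_masks:
        for mask, variance in class_masks.values():
            idx = np.flatnonzero(mask)
            n_causal = max(1, int(round(config.causal_fraction * idx.size)))
            causal = rng.choice(idx, size=n_causal, replace=False)
            b = np.sqrt(variance / n_causal)
            beta[causal] += b * rng.choice([-1.0, 1.0], size=n_causal)
        return beta, np.flatnonzero(beta)

    background = config.h2_l - sum(r.share for r in config.risk_snps)
    if config.causal_snps is not None:
        causal = np.asarray([j for j in config.causal_snps if j not in risk_idx])
    else:
        pool = np.setdiff1d(np.arange(config.m), risk_idx)
        n_causal = max(1, int(round(config.causal_fraction * config.m)))
        causal = rng.choice(pool, size=min(n_causal, pool.size), replace=False)
    if background > 0:
        if causal.size == 0:
            raise ValueError("positive background heritability but no causal SNPs")
        b = np.sqrt(background / causal.size)
        beta[causal] = b * rng.choice([-1.0, 1.0], size=causal.size)
    return beta, np.flatnonzero(beta)


def simulate_liability_phenotype(
    gm: GenotypeMatrix, config: SimulationConfig, exact_h2: bool = True
) -> tuple[PhenotypeTable, dict]:
    """Assign case/control status to an existing genotype matrix by the
    liability threshold model.

    With ``exact_h2`` the realized genetic scores are rescaled so their sample
    variance equals ``h2_l`` exactly.
    """
    rng_eff, rng_resid = _rng_streams(config.seed ^ 0x5EED, 2)
    beta, causal = build_effects(config, rng_eff)
    X = gm.dosages.astype(float)
    p = X.mean(axis=0) / 2
    sd = np.sqrt(2 * p * (1 - p))
    use = beta != 0
    Z = (X[:, use] - 2 * p[use]) / np.where(sd[use] > 0, sd[use], 1.0)
    g = Z @ beta[use]
    if exact_h2 and config.h2_l > 0 and g.std() > 0:
        g = g * np.sqrt(config.h2_l) / g.std()
    resid = rng_resid.standard_normal(gm.n_samples) * np.sqrt(max(1 - config.h2_l, 0))
    liability = g + resid
    t = norm.isf(config.K)
    status = (liability > t).astype(int)
    truth = {
        "causal_snps": causal.tolist(),
        "beta": beta,
        "realized_genetic_variance": float(g.var()),
        "realized_case_rate": float(status.mean()),
        "threshold": float(t),
    }
    return PhenotypeTable(samples=list(gm.samples), status=status), truth


def ascertain_cohort(
    mafs: np.ndarray,
    beta: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> SimulatedCohort:
    """Rejection-sample an ascertained cohort from the population model.

    Individuals stream from the population until the case and control quotas
    are met. Causal genotypes, liability and status are generated for every
    candidate; genotypes at non-causal SNPs (independent of phenotype) are
    drawn only for retained individuals — distributionally identical to
    generating everything up front, at a fraction of the cost.
    """
    t = norm.isf(config.K)
    causal = np.flatnonzero(beta)
    p_causal = mafs[causal]
    sd_causal = np.sqrt(2 * p_causal * (1 - p_causal))
    resid_sd = np.sqrt(max(1 - config.h2_l, 0))

    need_cases, need_controls = config.n_cases, config.n_controls
    batch = int(8 * need_cases / config.K / config.max_batches)
    batch = max(1000, min(batch, 200_000))  # memory cap; quota check handles shortfalls
    case_rows: list[np.ndarray] = []
    control_rows: list[np.ndarray] = []
    n_generated = 0
    for _ in range(config.max_batches):
        if need_cases <= 0 and need_controls <= 0:
            break
        gc = _draw_genotype_block(p_causal, batch, rng, config.ld_block_size, config.ld_rho)
        z = (gc.astype(float) - 2 * p_causal) / sd_causal
        liability = z @ beta[causal] + rng.standard_normal(batch) * resid_sd
        is_case = liability > t
        n_generated += batch
        if need_cases > 0:
            take = np.flatnonzero(is_case)[:need_cases]
            case_rows.extend(gc[take])
            need_cases -= take.size
        if need_controls > 0:
            take = np.flatnonzero(~is_case)[:need_controls]
            control_rows.extend(gc[take])
            need_controls -= take.size
    if need_cases > 0 or need_controls > 0:
        raise RuntimeError(
            f"quotas unmet after {config.max_batches} batches "
            f"({need_cases} cases / {need_controls} controls short); raise max_batches"
        )

    n = config.n_samples
    dosages = np.empty((n, config.m), dtype=np.int8)
    causal_block = np.vstack(case_rows + control_rows)
    dosages[:, causal] = causal_block
    noncausal = np.setdiff1d(np.arange(config.m), causal)
    if noncausal.size:
        dosages[:, noncausal] = _draw_genotype_block(
            mafs[noncausal], n, rng, config.ld_block_size, config.ld_rho
        )
    status = np.concatenate([np.ones(config.n_cases, dtype=int), np.zeros(config.n_controls, dtype=int)])
    gm = GenotypeMatrix(_sample_keys(n), _make_snp_records(config), dosages)
    pheno = PhenotypeTable(samples=list(gm.samples), status=status)
    truth = {
        "causal_snps": causal.tolist(),
        "beta": beta,
        "risk_snp_indices": config.risk_snp_indices(),
        "n_generated": n_generated,
        "threshold": float(t),
        "case_fraction": config.case_fraction,
    }
    return SimulatedCohort(genotypes=gm, phenotypes=pheno, truth=truth, config=config)


def simulate_ascertained_cohort(config: SimulationConfig) -> SimulatedCohort:
    """End-to-end cohort generation: MAFs, effects, rejection-sampled
    ascertainment to the configured case/control quotas, optional subtypes."""
    rng_maf, rng_eff, rng_asc, rng_sub = _rng_streams(config.seed, 4)
    mafs = _draw_mafs(config, rng_maf)
    beta, _ = build_effects(config, rng_eff)
    cohort = ascertain_cohort(mafs, beta, config, rng_asc)
    cohort.truth["mafs"] = mafs
    if config.subtype_proportions is not None:
        assign_subtypes(cohort, config.subtype_proportions, config.subtype_names, rng_sub)
    return cohort


def assign_subtypes(
    cohort: SimulatedCohort,
    proportions: Sequence[float],
    names: Sequence[str] | None = None,
    rng: np.random.Generator | None = None,
) -> SimulatedCohort:
    """Multinomially label cases with subtypes; controls stay unlabeled."""
    props = np.asarray(proportions, dtype=float)
    if not np.isclose(props.sum(), 1.0):
        raise ValueError("subtype proportions must sum to 1")
    if names is None:
        names = [f"subtype{i + 1}" for i in range(len(props))]
    if rng is None:
        seed = cohort.config.seed if cohort.config else 0
        rng = _rng_streams(seed ^ 0x5B, 1)[0]
    status = cohort.phenotypes.status
    labels: list[str | None] = [None] * len(status)
    cases = np.flatnonzero(status == 1)
    draws = rng.choice(len(props), size=cases.size, p=props)
    for i, d in zip(cases, draws):
        labels[i] = names[d]
    cohort.phenotypes.subtype = labels
    return cohort
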