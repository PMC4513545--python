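"""Readers and writers for the standard GWAS file formats.

Supported formats:

* PLINK binary genotypes (``.bed``/``.bim``/``.fam``), SNP-major dialect only;
* GCTA binary GRM triplets (``.grm.bin``/``.grm.N.bin``/``.grm.id``);
* BED genomic intervals (0-based half-open) for annotation classes;
* whitespace-delimited phenotype/covariate tables keyed by ``FID IID``.

Dosages count copies of BIM allele1 (the PLINK convention); missing genotypes
are stored as ``-1`` in an ``int8`` matrix.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING = -1

_BED_MAGIC = bytes([0x6C, 0x1B])
_SNP_MAJOR = 0x01

# PLINK 2-bit genotype codes -> allele1 dosage
# 00 = hom allele1 (dosage 2), 01 = missing, 10 = het, 11 = hom allele2
_CODE_TO_DOSAGE = np.array([2, MISSING, 1, 0], dtype=np.int8)
_DOSAGE_TO_CODE = {2: 0b00, MISSING: 0b01, 1: 0b10, 0: 0b11}


class PlinkFormatError(ValueError):
    """Raised for malformed PLINK or GRM binary payloads."""


@dataclass(frozen=True)
class SnpRecord:
    """A single variant: identifier, locus and allele pair (counted = allele1)."""

    id: str
    chromosome: int
    position: int
    allele1: str
    allele2: str

    def __post_init__(self) -> None:
        if self.position <= 0:
            raise ValueError(f"SNP {self.id}: position must be positive (1-based)")
        if self.allele1 == self.allele2:
            raise ValueError(f"SNP {self.id}: alleles must differ")


@dataclass
class GenotypeMatrix:
    """``n`` samples x ``m`` SNPs of allele1-dosages in {0, 1, 2, -1(missing)}."""

    samples: list[tuple[str, str]]
    snps: list[SnpRecord]
    dosages: np.ndarray  # (n, m) int8

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        n, m = len(self.samples), len(self.snps)
        if self.dosages.shape != (n, m):
            raise ValueError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{n} samples x {m} SNPs"
            )
        ids = [s.id for s in self.snps]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate SNP identifiers")
        bad = self.dosages[(self.dosages < MISSING) | (self.dosages > 2)]
        if bad.size:
            raise ValueError(f"invalid dosage values: {np.unique(bad)}")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def snp_ids(self) -> list[str]:
        return [s.id for s in self.snps]

    @property
    def chromosomes(self) -> np.ndarray:
        return np.array([s.chromosome for s in self.snps], dtype=int)

    @property
    def positions(self) -> np.ndarray:
        return np.array([s.position for s in self.snps], dtype=np.int64)

    def subset_snps(self, index: Sequence[int] | np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeMatrix(
            samples=list(self.samples),
            snps=[self.snps[i] for i in index],
            dosages=self.dosages[:, index],
        )

    def subset_samples(self, index: Sequence[int] | np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeMatrix(
            samples=[self.samples[i] for i in index],
            snps=list(self.snps),
            dosages=self.dosages[index, :],
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.samples == other.samples
            and self.snps == other.snps
            and np.array_equal(self.dosages, other.dosages)
        )


@dataclass
class PhenotypeTable:
    """Binary disease status plus optional covariates/subtype, keyed by (FID, IID)."""

    samples: list[tuple[str, str]]
    status: np.ndarray  # (n,) int, 0 = control, 1 = case
    covariates: np.ndarray | None = None  # (n, c) float
    covariate_names: list[str] = field(default_factory=list)
    subtype: list[str | None] | None = None

    def __post_init__(self) -> None:
        self.status = np.asarray(self.status, dtype=int)
        if self.status.shape != (len(self.samples),):
            raise ValueError("status length does not match samples")
        if not np.isin(self.status, [0, 1]).all():
            raise ValueError("status must be coded 0/1")
        if self.covariates is not None:
            self.covariates = np.atleast_2d(np.asarray(self.covariates, dtype=float))
            if self.covariates.shape[0] != len(self.samples):
                raise ValueError("covariate rows do not match samples")

    @property
    def case_fraction(self) -> float:
        return float(self.status.mean())

    def aligned_to(self, samples: list[tuple[str, str]]) -> "PhenotypeTable":
        """Reorder/subset to the given sample keys; error on unresolvable keys."""
        pos = {key: i for i, key in enumerate(self.samples)}
        try:
            idx = [pos[key] for key in samples]
        except KeyError as exc:  # pragma: no cover - defensive
            raise KeyError(f"sample {exc.args[0]} not phenotyped") from None
        return PhenotypeTable(
            samples=list(samples),
            status=self.status[idx],
            covariates=None if self.covariates is None else self.covariates[idx],
            covariate_names=list(self.covariate_names),
            subtype=None if self.subtype is None else [self.subtype[i] for i in idx],
        )


class AnnotationSet:
    """Genomic intervals (0-based half-open) with point-membership queries."""

    def __init__(self, intervals: Sequence[tuple[int, int, int]]) -> None:
        # merge overlapping intervals per chromosome so searchsorted parity works
        by_chrom: dict[int, list[tuple[int, int]]] = {}
        for chrom, start, end in intervals:
            if start >= end:
                warnings.warn(
                    f"rejecting interval chr{chrom}:{start}-{end} (start >= end)",
                    stacklevel=2,
                )
                continue
            by_chrom.setdefault(int(chrom), []).append((int(start), int(end)))
        self._bounds: dict[int, np.ndarray] = {}
        self._n = 0
        for chrom, ivals in by_chrom.items():
            merged: list[list[int]] = []
            for start, end in sorted(ivals):
                if merged and start <= merged[-1][1]:
                    merged[-1][1] = max(merged[-1][1], end)
                else:
                    merged.append([start, end])
            self._n += len(merged)
            self._bounds[chrom] = np.array(merged, dtype=np.int64).ravel()

    def __len__(self) -> int:
        return self._n

    def contains(self, chromosome: int, position: int) -> bool:
        """Membership of a 1-based SNP position in any interval."""
        bounds = self._bounds.get(int(chromosome))
        if bounds is None:
            return False
        # convert 1-based position to 0-based coordinate
        return bool(np.searchsorted(bounds, position - 1, side="right") % 2)

    def contains_many(self, chromosomes: np.ndarray, positions: np.ndarray) -> np.ndarray:
        out = np.zeros(len(positions), dtype=bool)
        for chrom, bounds in self._bounds.items():
            mask = chromosomes == chrom
            if mask.any():
                out[mask] = np.searchsorted(bounds, positions[mask] - 1, side="right") % 2 == 1
        return out


# ---------------------------------------------------------------------------
# PLINK BED/BIM/FAM
# ---------------------------------------------------------------------------

def read_plink(prefix: str | Path, *, bed_path=None, bim_path=None, fam_path=None) -> GenotypeMatrix:
    """Read a SNP-major PLINK binary fileset into a :class:`GenotypeMatrix`.

    Parameters
    ----------
    prefix
        Path prefix; ``.bed``/``.bim``/``.fam`` are appended unless the three
        explicit paths are given.
    """
    prefix = Path(prefix)
    bed_path = Path(bed_path) if bed_path else prefix.with_suffix(".bed")
    bim_path = Path(bim_path) if bim_path else prefix.with_suffix(".bim")
    fam_path = Path(fam_path) if fam_path else prefix.with_suffix(".fam")

    fam = pd.read_csv(fam_path, sep=r"\s+", header=None, dtype=str)
    samples = list(zip(fam[0], fam[1]))
    if Path(bim_path).stat().st_size == 0:
        snps: list[SnpRecord] = []
    else:
        bim = pd.read_csv(bim_path, sep=r"\s+", header=None, dtype=str)
        snps = [
            SnpRecord(
                id=row[1],
                chromosome=int(row[0]),
                position=int(row[3]),
                allele1=row[4],
                allele2=row[5],
            )
            for row in bim.itertuples(index=False)
        ]

    n, m = len(samples), len(snps)
    raw = Path(bed_path).read_bytes()
    if len(raw) < 3 or raw[:2] != _BED_MAGIC:
        raise PlinkFormatError(f"{bed_path}: bad BED magic bytes")
    if raw[2] != _SNP_MAJOR:
        raise PlinkFormatError(f"{bed_path}: only SNP-major BED files are supported")
    bytes_per_snp = (n + 3) // 4
    payload = np.frombuffer(raw, dtype=np.uint8, offset=3)
    if payload.size != bytes_per_snp * m:
        raise PlinkFormatError(
            f"{bed_path}: payload is {payload.size} bytes, expected "
            f"{bytes_per_snp * m} for {n} samples x {m} SNPs"
        )
    if m == 0:
        return GenotypeMatrix(samples, snps, np.zeros((n, 0), dtype=np.int8))
    blocks = payload.reshape(m, bytes_per_snp)
    # unpack 2-bit codes, sample index runs from the low bits of each byte
    codes = np.empty((m, bytes_per_snp * 4), dtype=np.uint8)
    for shift in range(4):
        codes[:, shift::4] = (blocks >> (2 * shift)) & 0b11
    dosages = _CODE_TO_DOSAGE[codes[:, :n]].T.copy()
    return GenotypeMatrix(samples, snps, dosages)


def write_plink(gm: GenotypeMatrix, prefix: str | Path) -> None:
    """Write a SNP-major PLINK binary fileset; inverse of :func:`read_plink`."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    n, m = gm.n_samples, gm.n_snps

    with open(prefix.with_suffix(".fam"), "w") as fh:
        for fid, iid in gm.samples:
            fh.write(f"{fid} {iid} 0 0 0 -9\n")
    with open(prefix.with_suffix(".bim"), "w") as fh:
        for s in gm.snps:
            fh.write(f"{s.chromosome} {s.id} 0 {s.position} {s.allele1} {s.allele2}\n")

    dosage_idx = gm.dosages.T.astype(np.int64)  # (m, n), values -1..2
    code_map = np.empty(4, dtype=np.uint8)
    code_map[0] = _DOSAGE_TO_CODE[0]
    code_map[1] = _DOSAGE_TO_CODE[1]
    code_map[2] = _DOSAGE_TO_CODE[2]
    code_map[3] = _DOSAGE_TO_CODE[MISSING]
    codes = code_map[np.where(dosage_idx == MISSING, 3, dosage_idx)]

    bytes_per_snp = (n + 3) // 4
    padded = np.zeros((m, bytes_per_snp * 4), dtype=np.uint8)
    padded[:, :n] = codes
    packed = np.zeros((m, bytes_per_snp), dtype=np.uint8)
    for shift in range(4):
        packed |= padded[:, shift::4] << (2 * shift)
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC + bytes([_SNP_MAJOR]))
        fh.write(packed.tobytes())


# ---------------------------------------------------------------------------
# GCTA GRM binary triplet
# ---------------------------------------------------------------------------

def write_grm_gcta(grm, prefix: str | Path) -> None:
    """Write a GRM as GCTA's binary triplet (float32 lower triangle)."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    n = grm.n_samples
    tril = np.tril_indices(n)
    grm.values[tril].astype("<f4").tofile(f"{prefix}.grm.bin")
    grm.pair_counts[tril].astype("<f4").tofile(f"{prefix}.grm.N.bin")
    with open(f"{prefix}.grm.id", "w") as fh:
        for fid, iid in grm.sample_ids:
            fh.write(f"{fid}\t{iid}\n")


def read_grm_gcta(prefix: str | Path):
    """Read a GCTA binary GRM triplet; inverse of :func:`write_grm_gcta`."""
    from liabkit.grm import GRM  # local import to avoid a cycle

    prefix = Path(prefix)
    ids = []
    with open(f"{prefix}.grm.id") as fh:
        for line in fh:
            parts = line.split()
            if parts:
                ids.append((parts[0], parts[1]))
    n = len(ids)
    n_pairs = n * (n + 1) // 2
    vals = np.fromfile(f"{prefix}.grm.bin", dtype="<f4")
    counts = np.fromfile(f"{prefix}.grm.N.bin", dtype="<f4")
    if vals.size != n_pairs or counts.size != n_pairs:
        raise PlinkFormatError(
            f"{prefix}: {n} sample ids imply {n_pairs} stored values, "
            f"found {vals.size} relationships / {counts.size} counts"
        )
    values = np.zeros((n, n))
    pair_counts = np.zeros((n, n))
    tril = np.tril_indices(n)
    values[tril] = vals
    pair_counts[tril] = counts
    values = values + np.tril(values, -1).T
    pair_counts = pair_counts + np.tril(pair_counts, -1).T
    return GRM(values=values, pair_counts=pair_counts.astype(np.int64), sample_ids=ids)


# ---------------------------------------------------------------------------
# BED intervals and phenotype tables
# ---------------------------------------------------------------------------

def _parse_chrom(token: str) -> int:
    token = token.lower().removeprefix("chr")
    return int(token)


def read_intervals(bed_path: str | Path) -> AnnotationSet:
    """Read a 3+ column BED file of intervals (0-based half-open)."""
    intervals: list[tuple[int, int, int]] = []
    with open(bed_path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 3:
                warnings.warn(f"skipping short BED line: {line!r}", stacklevel=2)
                continue
            intervals.append((_parse_chrom(parts[0]), int(parts[1]), int(parts[2])))
    return AnnotationSet(intervals)


def read_phenotypes(path: str | Path, *, covariate_path: str | Path | None = None) -> PhenotypeTable:
    """Read a whitespace-delimited ``FID IID status`` file (status 0/1 or 1/2).

    An optional covariate file with ``FID IID cov1 cov2 ...`` columns is joined
    on the sample key.
    """
    df = pd.read_csv(path, sep=r"\s+", header=None, dtype=str)
    samples = list(zip(df[0], df[1]))
    status = df[2].astype(float).to_numpy()
    if set(np.unique(status)) <= {1.0, 2.0}:  # PLINK 1/2 coding
        status = status - 1
    covariates = None
    names: list[str] = []
    if covariate_path is not None:
        cov = pd.read_csv(covariate_path, sep=r"\s+", header=None, dtype=str)
        cov_map = {
            (row[0], row[1]): [float(v) for v in row[2:]]
            for row in cov.itertuples(index=False)
        }
        covariates = np.array([cov_map[key] for key in samples], dtype=float)
        names = [f"cov{i + 1}" for i in range(covariates.shape[1])]
    return PhenotypeTable(
        samples=samples, status=status.astype(int), covariates=covariates, covariate_names=names
    )


def write_phenotypes(pheno: PhenotypeTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        for (fid, iid), y in zip(pheno.samples, pheno.status):
            fh.write(f"{fid} {iid} {y}\n")
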