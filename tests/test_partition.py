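import numpy as np
import pytest

from liabkit.io_formats import AnnotationSet
from liabkit.liability import LiabilityContext, liability_context
from liabkit.partition import (
    annotation_partition,
    per_chromosome_partition,
    risk_loci_partition,
    stratified_heritability,
)
from liabkit.synthetic_data import (
    RiskSnpSpec,
    SimulationConfig,
    assign_subtypes,
    simulate_ascertained_cohort,
    simulate_genotypes,
)

IDENTITY_CTX = LiabilityContext(K=0.5, P=0.5, t=0.0, z=1.0, factor=1.0)


def quantitative_cohort(seed, m=600, n=400, n_chrom=3, causal_chrom=None, h2=0.3,
                        chrom_snp_counts=None):
    """Genotypes plus a quantitative phenotype with causal SNPs either spread
    uniformly or confined to one chromosome."""
    cfg = SimulationConfig(
        n_cases=1, n_controls=n - 1, m=m, h2_l=h2, K=0.5, seed=seed,
        n_chromosomes=n_chrom, chrom_snp_counts=chrom_snp_counts,
    )
    gm = simulate_genotypes(cfg, n=n)
    rng = np.random.default_rng(seed + 77)
    if causal_chrom is None:
        causal = rng.choice(m, size=m // 5, replace=False)
    else:
        pool = np.flatnonzero(gm.chromosomes == causal_chrom)
        causal = rng.choice(pool, size=max(2, len(pool) // 3), replace=False)
    beta = np.zeros(m)
    beta[causal] = rng.choice([-1, 1], size=len(causal)) * np.sqrt(h2 / len(causal))
    X = gm.dosages.astype(float)
    p = X.mean(axis=0) / 2
    Z = (X - 2 * p) / np.sqrt(2 * p * (1 - p))
    y = Z @ beta + rng.standard_normal(n) * np.sqrt(1 - h2)
    return gm, y


class TestPerChromosome:
    def test_concentrated_architecture(self):
        ests = []
        for seed in range(4):
            gm, y = quantitative_cohort(seed, causal_chrom=2)
            res = per_chromosome_partition(gm, y, IDENTITY_CTX)
            ests.append(res.estimates)
        mean = np.mean(ests, axis=0)
        assert mean[1] > 0.15
        assert mean[1] > 3 * max(mean[0], mean[2], 0.01)

    def test_regression_fields_present(self):
        gm, y = quantitative_cohort(11)
        res = per_chromosome_partition(gm, y, IDENTITY_CTX)
        assert set(res.regression) == {"slope", "intercept", "r2"}
        assert 0 <= res.regression["r2"] <= 1

    def test_length_proportional_beats_scattered(self):
        # chromosome lengths 3:2:1; causal variance uniform over SNPs tracks
        # length, causal on the smallest chromosome does not
        counts = [300, 200, 100]
        r2_prop, r2_scat = [], []
        for seed in range(5):
            gm, y = quantitative_cohort(seed, m=600, chrom_snp_counts=counts)
            r2_prop.append(per_chromosome_partition(gm, y, IDENTITY_CTX).regression["r2"])
            gm, y = quantitative_cohort(seed + 50, m=600, chrom_snp_counts=counts, causal_chrom=3)
            r2_scat.append(per_chromosome_partition(gm, y, IDENTITY_CTX).regression["r2"])
        assert np.mean(r2_prop) > np.mean(r2_scat)

    def test_single_chromosome_rejected(self):
        gm, y = quantitative_cohort(1, n_chrom=1)
        with pytest.raises(ValueError, match="two chromosomes"):
            per_chromosome_partition(gm, y, IDENTITY_CTX)

    def test_length_mode_count(self):
        gm, y = quantitative_cohort(2)
        res = per_chromosome_partition(gm, y, IDENTITY_CTX, length_mode="count")
        assert res.extras["chromosome_lengths"] == [200.0, 200.0, 200.0]


class TestRiskLoci:
    def test_null_loci_component_small(self):
        gm, y = quantitative_cohort(21)
        loci = [(1, int(gm.positions[10]))]
        res = risk_loci_partition(gm, y, loci, IDENTITY_CTX, window_bp=100_000)
        assert res.labels == ["risk_loci", "remainder"]
        assert res.estimates[0] < 0.1

    def test_locus_plus_remainder_close_to_total(self):
        from liabkit.grm import compute_grm
        from liabkit.greml import h2_liability_from_fit, reml_fit

        totals, sums = [], []
        for seed in range(4):
            gm, y = quantitative_cohort(30 + seed)
            loci = [(1, int(gm.positions[50]))]
            res = risk_loci_partition(gm, y, loci, IDENTITY_CTX)
            sums.append(res.estimates.sum())
            fit = reml_fit(compute_grm(gm), y)
            totals.append(h2_liability_from_fit(fit, IDENTITY_CTX).total)
        assert np.mean(sums) == pytest.approx(np.mean(totals), abs=0.08)

    def test_empty_locus_set_rejected(self):
        gm, y = quantitative_cohort(1)
        with pytest.warns(UserWarning, match="absent"):
            with pytest.raises(ValueError, match="no SNPs"):
                risk_loci_partition(gm, y, [(99, 1000)], IDENTITY_CTX)


class TestAnnotation:
    def _ann_covering(self, gm, mask):
        return AnnotationSet([
            (int(s.chromosome), int(s.position) - 1, int(s.position))
            for s, flag in zip(gm.snps, mask) if flag
        ])

    def test_all_snps_in_class_degenerate(self):
        gm, y = quantitative_cohort(5)
        ann = self._ann_covering(gm, np.ones(gm.n_snps, dtype=bool))
        with pytest.raises(ValueError, match="non_transcript"):
            annotation_partition(gm, y, ann, IDENTITY_CTX)

    def test_label_swap_swaps_estimates(self):
        gm, y = quantitative_cohort(6)
        mask = np.zeros(gm.n_snps, dtype=bool)
        mask[::2] = True
        res_a = annotation_partition(gm, y, self._ann_covering(gm, mask), IDENTITY_CTX)
        res_b = annotation_partition(gm, y, self._ann_covering(gm, ~mask), IDENTITY_CTX)
        assert res_a.estimates[0] == pytest.approx(res_b.estimates[1], abs=1e-6)
        assert res_a.estimates[1] == pytest.approx(res_b.estimates[0], abs=1e-6)

    def test_fraction_reported(self):
        gm, y = quantitative_cohort(7)
        mask = np.zeros(gm.n_snps, dtype=bool)
        mask[:400] = True
        res = annotation_partition(gm, y, self._ann_covering(gm, mask), IDENTITY_CTX)
        assert res.extras["fraction_in_class"] == pytest.approx(400 / gm.n_snps)
        assert res.snp_counts == [400, gm.n_snps - 400]


class TestStratified:
    def _cohort(self, seed=1):
        cfg = SimulationConfig(
            n_cases=150, n_controls=350, m=700, h2_l=0.152, K=0.00739,
            seed=seed, n_chromosomes=2,
        )
        return simulate_ascertained_cohort(cfg)

    def test_single_subtype_matches_overall(self):
        from liabkit.grm import compute_grm
        from liabkit.greml import h2_liability_from_fit, reml_fit

        cohort = self._cohort()
        assign_subtypes(cohort, [1.0], names=["all"])
        res = stratified_heritability(
            cohort.genotypes, cohort.phenotypes, 0.00739, min_cases=10
        )
        grm = compute_grm(cohort.genotypes)
        y = cohort.phenotypes.status
        ctx = liability_context(0.00739, float(y.mean()))
        overall = h2_liability_from_fit(reml_fit(grm, y.astype(float)), ctx)
        assert res["all"][0] == pytest.approx(overall.total, abs=1e-6)

    def test_small_stratum_skipped(self):
        cohort = self._cohort()
        assign_subtypes(cohort, [0.95, 0.05], names=["big", "tiny"])
        with pytest.warns(UserWarning, match="skipped"):
            res = stratified_heritability(
                cohort.genotypes, cohort.phenotypes, 0.00739, min_cases=30
            )
        assert "tiny" not in res
        assert "big" in res

    def test_se_grows_as_stratum_shrinks(self):
        cohort = self._cohort(3)
        assign_subtypes(cohort, [0.7, 0.3], names=["major", "minor"])
        res = stratified_heritability(
            cohort.genotypes, cohort.phenotypes, 0.00739, min_cases=10
        )
        assert res["minor"][1] > res["major"][1]

    def test_unlabeled_phenotypes_rejected(self):
        cohort = self._cohort()
        with pytest.raises(ValueError, match="subtype"):
            stratified_heritability(cohort.genotypes, cohort.phenotypes, 0.00739)
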