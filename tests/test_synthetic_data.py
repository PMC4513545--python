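import numpy as np
import pytest
from scipy.stats import norm

from liabkit.synthetic_data import (
    RiskSnpSpec,
    SimulationConfig,
    assign_subtypes,
    simulate_ascertained_cohort,
    simulate_genotypes,
    simulate_liability_phenotype,
)


def _config(**kw):
    base = dict(n_cases=50, n_controls=150, m=200, h2_l=0.15, K=0.00739, seed=1)
    base.update(kw)
    return SimulationConfig(**base)


class TestConfigValidation:
    def test_shares_must_fit_under_h2(self):
        with pytest.raises(ValueError, match="risk shares"):
            _config(h2_l=0.01, risk_snps=(RiskSnpSpec(0.3, 0.02),))

    def test_K_range(self):
        with pytest.raises(ValueError):
            _config(K=0.0)

    def test_chrom_counts_must_sum(self):
        with pytest.raises(ValueError, match="sum to m"):
            _config(chrom_snp_counts=[100, 50])

    def test_case_fraction(self):
        assert _config(n_cases=305, n_controls=695).case_fraction == pytest.approx(0.305)


class TestGenotypes:
    def test_deterministic_under_seed(self):
        a = simulate_genotypes(_config(), n=50)
        b = simulate_genotypes(_config(), n=50)
        assert np.array_equal(a.dosages, b.dosages)

    def test_different_seed_differs(self):
        a = simulate_genotypes(_config(seed=1), n=50)
        b = simulate_genotypes(_config(seed=2), n=50)
        assert not np.array_equal(a.dosages, b.dosages)

    def test_degenerate_maf_law(self):
        cfg = _config(maf_law=("uniform", 0.3, 0.3), m=400)
        gm = simulate_genotypes(cfg, n=5000)
        maf = gm.dosages.mean(axis=0) / 2
        assert maf.mean() == pytest.approx(0.30, abs=0.01)

    def test_no_ld_means_no_adjacent_correlation(self):
        cfg = _config(m=100, ld_block_size=1, ld_rho=0.0)
        gm = simulate_genotypes(cfg, n=3000)
        d = gm.dosages.astype(float)
        cors = [np.corrcoef(d[:, j], d[:, j + 1])[0, 1] for j in range(0, 80, 2)]
        assert abs(np.mean(cors)) < 0.02

    def test_block_ld_induces_correlation(self):
        cfg = _config(m=100, ld_block_size=10, ld_rho=0.8)
        gm = simulate_genotypes(cfg, n=3000)
        d = gm.dosages.astype(float)
        within = np.mean([np.corrcoef(d[:, 10 * b], d[:, 10 * b + 1])[0, 1] for b in range(9)])
        across = np.mean([np.corrcoef(d[:, 10 * b + 9], d[:, 10 * b + 10])[0, 1] for b in range(9)])
        assert within > 0.3
        assert abs(across) < 0.1

    def test_layout_positions_and_chromosomes(self):
        cfg = _config(m=10, n_chromosomes=2)
        gm = simulate_genotypes(cfg, n=3)
        assert gm.chromosomes.tolist() == [1] * 5 + [2] * 5
        assert (gm.positions > 0).all()


class TestLiabilityPhenotype:
    def test_zero_heritability_independent_of_genotype(self):
        cfg = _config(h2_l=0.0, m=300)
        gm = simulate_genotypes(cfg, n=2000)
        pheno, truth = simulate_liability_phenotype(gm, cfg)
        from liabkit.grm import compute_grm

        grm = compute_grm(gm)
        y = pheno.status - pheno.status.mean()
        G = grm.values.copy()
        np.fill_diagonal(G, 0)
        slope = (y @ G @ y) / np.sum(G * G)
        assert abs(slope) < 0.1

    def test_exact_genetic_variance(self):
        cfg = _config(h2_l=0.2, m=300)
        gm = simulate_genotypes(cfg, n=500)
        _, truth = simulate_liability_phenotype(gm, cfg, exact_h2=True)
        assert truth["realized_genetic_variance"] == pytest.approx(0.2, abs=1e-12)

    def test_population_case_rate_matches_K(self):
        cfg = _config(K=0.05, m=150, h2_l=0.3)
        gm = simulate_genotypes(cfg, n=50_000)
        pheno, truth = simulate_liability_phenotype(gm, cfg)
        se = np.sqrt(0.05 * 0.95 / 50_000)
        assert pheno.status.mean() == pytest.approx(0.05, abs=4 * se)

    def test_infeasible_share_rejected(self):
        with pytest.raises(ValueError):
            _config(h2_l=0.1, risk_snps=(RiskSnpSpec(0.3, 0.2),))


class TestAscertainment:
    def test_quota_and_case_fraction(self):
        cfg = _config(n_cases=61, n_controls=139)
        cohort = simulate_ascertained_cohort(cfg)
        assert cohort.phenotypes.status.sum() == 61
        assert cohort.phenotypes.case_fraction == pytest.approx(0.305)

    def test_generated_count_near_geometric_expectation(self):
        cfg = _config(n_cases=60, n_controls=140, K=0.00739)
        cohort = simulate_ascertained_cohort(cfg)
        expected = 60 / 0.00739
        assert cohort.truth["n_generated"] == pytest.approx(expected, rel=0.6)

    def test_deterministic(self):
        a = simulate_ascertained_cohort(_config())
        b = simulate_ascertained_cohort(_config())
        assert np.array_equal(a.genotypes.dosages, b.genotypes.dosages)
        assert np.array_equal(a.phenotypes.status, b.phenotypes.status)

    def test_quota_failure_raises(self):
        cfg = _config(n_cases=5000, n_controls=100, max_batches=2)
        with pytest.raises(RuntimeError, match="max_batches"):
            simulate_ascertained_cohort(cfg)

    def test_cases_enriched_for_risk_allele(self):
        share = 0.1
        cfg = _config(
            n_cases=300, n_controls=300, m=100, h2_l=0.15,
            risk_snps=(RiskSnpSpec(maf=0.3, share=share, chromosome=1),),
        )
        cohort = simulate_ascertained_cohort(cfg)
        idx = cfg.risk_snp_indices()[0]
        beta = cohort.truth["beta"][idx]
        dose = cohort.genotypes.dosages[:, idx].astype(float)
        cases = cohort.phenotypes.status == 1
        shift = (dose[cases].mean() - dose[~cases].mean()) * np.sign(beta)
        assert shift > 0.05


class TestSubtypes:
    def test_single_subtype(self):
        cohort = simulate_ascertained_cohort(_config())
        assign_subtypes(cohort, [1.0], names=["only"])
        labels = [
            l for l, y in zip(cohort.phenotypes.subtype, cohort.phenotypes.status) if y == 1
        ]
        assert set(labels) == {"only"}

    def test_binomial_split(self):
        cfg = _config(n_cases=1000, n_controls=200, m=60, K=0.05)
        cohort = simulate_ascertained_cohort(cfg)
        rng = np.random.default_rng(0)
        assign_subtypes(cohort, [0.5, 0.5], rng=rng)
        labels = [l for l in cohort.phenotypes.subtype if l is not None]
        n1 = sum(1 for l in labels if l == "subtype1")
        assert abs(n1 - 500) < 3.2 * np.sqrt(1000 * 0.25)

    def test_controls_never_labeled(self):
        cohort = simulate_ascertained_cohort(_config())
        assign_subtypes(cohort, [0.6, 0.4])
        for label, y in zip(cohort.phenotypes.subtype, cohort.phenotypes.status):
            if y == 0:
                assert label is None

    def test_proportions_must_sum_to_one(self):
        cohort = simulate_ascertained_cohort(_config())
        with pytest.raises(ValueError, match="sum to 1"):
            assign_subtypes(cohort, [0.5, 0.2])


class TestEndToEndRecovery:
    @pytest.mark.parametrize("h2", [0.0, 0.30])
    def test_pipeline_unbiased_across_truths(self, h2):
        # desk-scale version of the unbiasedness invariant (0.152 is exercised
        # at 50 replicates by the acceptance suite)
        from liabkit.replication import greml_recovery

        r = greml_recovery(seed=int(1000 * h2) + 17, truth_h2=h2, n_reps=8,
                           n_cases=150, n_controls=350, m=1200)
        assert abs(r.mean - h2) <= max(2 * r.mc_se, 0.02)


class TestAscertainmentCorrectionMatters:
    def test_uncorrected_estimates_biased(self):
        # positive control: without the P-vs-K correction the estimates are off
        from liabkit.grm import compute_grm
        from liabkit.greml import h2_liability_from_fit, reml_fit
        from liabkit.liability import liability_context

        corrected, naive = [], []
        for seed in range(4):
            cfg = _config(n_cases=120, n_controls=280, m=900, h2_l=0.152, seed=seed)
            cohort = simulate_ascertained_cohort(cfg)
            grm = compute_grm(cohort.genotypes)
            fit = reml_fit(grm, cohort.phenotypes.status.astype(float))
            P = cohort.phenotypes.case_fraction
            corrected.append(h2_liability_from_fit(fit, liability_context(0.00739, P)).total)
            # wrong transform: pretend the sample were a random draw (P = K)
            naive.append(h2_liability_from_fit(fit, liability_context(0.00739, 0.00739)).total)
        assert abs(np.mean(corrected) - 0.152) < abs(np.mean(naive) - 0.152)
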