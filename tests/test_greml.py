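import numpy as np
import pytest

from liabkit.grm import compute_grm
from liabkit.greml import (
    RemlSettings,
    covariate_difference_h2,
    h2_liability_from_fit,
    reml_fit,
)
from liabkit.liability import LiabilityContext, liability_context
from liabkit.synthetic_data import SimulationConfig, simulate_ascertained_cohort

from conftest import random_gm


def restricted_loglik_oracle(A, y, X, sg, se):
    """Direct textbook evaluation of the restricted log-likelihood
    -0.5 [ log|V| + log|X'V^-1 X| + y'Py ], independent of the fitter."""
    n = len(y)
    V = sg * A + se * np.eye(n)
    Vinv = np.linalg.inv(V)
    XtVX = X.T @ Vinv @ X
    P = Vinv - Vinv @ X @ np.linalg.inv(XtVX) @ X.T @ Vinv
    _, ld_v = np.linalg.slogdet(V)
    _, ld_x = np.linalg.slogdet(XtVX)
    return -0.5 * (ld_v + ld_x + y @ P @ y)


def simulate_quantitative(rng, n, m, h2):
    gm = random_gm(rng, n, m)
    X = gm.dosages.astype(float)
    p = X.mean(axis=0) / 2
    Z = (X - 2 * p) / np.sqrt(2 * p * (1 - p))
    beta = rng.standard_normal(m) * np.sqrt(h2 / m)
    y = Z @ beta + rng.standard_normal(n) * np.sqrt(1 - h2)
    return gm, y


class TestRemlCore:
    def test_grid_search_oracle_n30(self, rng):
        gm, y = simulate_quantitative(rng, 30, 100, 0.4)
        A = compute_grm(gm).values
        X = np.ones((30, 1))
        fit = reml_fit(A, y, settings=RemlSettings(tol=1e-8))
        grid = np.linspace(1e-4, 2.5, 120)
        best = max(
            restricted_loglik_oracle(A, y, X, sg, se) for sg in grid for se in grid
        )
        assert fit.loglik >= best - 1e-3
        # and the fitter's loglik is a genuine restricted likelihood value
        direct = restricted_loglik_oracle(A, y, X, fit.sigma[0], fit.sigma[1])
        assert fit.loglik == pytest.approx(direct, abs=1e-6)

    def test_loglik_monotone_over_iterations(self, rng):
        gm, y = simulate_quantitative(rng, 150, 300, 0.3)
        A = compute_grm(gm).values
        fit = reml_fit(A, y)
        lls = [ll for _, ll, _ in fit.trace]
        assert all(b >= a - 1e-8 for a, b in zip(lls, lls[1:]))

    def test_eigen_and_dense_paths_agree(self, rng):
        gm, y = simulate_quantitative(rng, 120, 250, 0.35)
        grm = compute_grm(gm)
        fit_e = reml_fit(grm, y, settings=RemlSettings(use_eigen_single=True, tol=1e-8))
        fit_d = reml_fit(grm, y, settings=RemlSettings(use_eigen_single=False, tol=1e-8))
        assert fit_e.sigma == pytest.approx(fit_d.sigma, abs=1e-8)
        assert fit_e.loglik == pytest.approx(fit_d.loglik, abs=1e-6)

    def test_identical_grms_sum_matches_single(self, rng):
        gm, y = simulate_quantitative(rng, 150, 300, 0.4)
        grm = compute_grm(gm)
        single = reml_fit(grm, y, settings=RemlSettings(tol=1e-8))
        with pytest.warns(UserWarning, match="identifiable"):
            double = reml_fit([grm, grm], y, settings=RemlSettings(tol=1e-8))
        assert not double.identifiable
        assert double.sigma[:2].sum() == pytest.approx(single.sigma[0], abs=5e-3)

    def test_null_phenotype_component_near_zero(self, rng):
        hits = 0
        n_reps = 20
        for _ in range(n_reps):
            gm = random_gm(rng, 200, 400)
            y = rng.standard_normal(200)
            fit = reml_fit(compute_grm(gm), y)
            se = max(fit.se_h2_obs_total, 1e-6)
            if fit.h2_obs_total <= 2 * se:
                hits += 1
        assert hits >= int(0.9 * n_reps)

    def test_parameter_recovery_quantitative(self, rng):
        # mean estimate across replicates within 2 MC SEs for several truths
        for h2 in (0.1, 0.25, 0.5):
            ests = []
            for _ in range(10):
                gm, y = simulate_quantitative(rng, 300, 600, h2)
                fit = reml_fit(compute_grm(gm), y)
                ests.append(fit.h2_obs_total)
            ests = np.asarray(ests)
            mc_se = ests.std(ddof=1) / np.sqrt(len(ests))
            assert abs(ests.mean() - h2) < max(2 * mc_se, 0.02), h2

    def test_singular_design_rejected(self, rng):
        gm, y = simulate_quantitative(rng, 50, 80, 0.3)
        X = np.ones((50, 2))  # two identical constant columns
        with pytest.raises(ValueError, match="singular"):
            reml_fit(compute_grm(gm), y, covariates=X)

    def test_nonconvergence_flagged(self, rng):
        gm, y = simulate_quantitative(rng, 80, 100, 0.3)
        with pytest.warns(UserWarning, match="converge"):
            fit = reml_fit(compute_grm(gm), y, settings=RemlSettings(max_iter=1))
        assert not fit.converged


class TestLiabilityTransform:
    def test_identity_factor(self, rng):
        gm, y = simulate_quantitative(rng, 100, 150, 0.3)
        fit = reml_fit(compute_grm(gm), y)
        ctx = LiabilityContext(K=0.5, P=0.5, t=0.0, z=1.0, factor=1.0)
        liab = h2_liability_from_fit(fit, ctx)
        assert liab.total == pytest.approx(fit.h2_obs_total)
        assert liab.se_total == pytest.approx(fit.se_h2_obs_total)

    def test_half_pi_factor(self, rng):
        gm, y = simulate_quantitative(rng, 100, 150, 0.3)
        fit = reml_fit(compute_grm(gm), y)
        ctx = liability_context(0.5, 0.5)
        liab = h2_liability_from_fit(fit, ctx)
        assert liab.total == pytest.approx(fit.h2_obs_total * np.pi / 2)

    def test_ascertained_recovery_small(self):
        # recovery of the simulated liability-scale truth on a few cohorts
        ests = []
        for seed in range(6):
            cfg = SimulationConfig(
                n_cases=120, n_controls=280, m=1200, h2_l=0.152,
                K=0.00739, seed=seed, n_chromosomes=2,
            )
            cohort = simulate_ascertained_cohort(cfg)
            fit = reml_fit(compute_grm(cohort.genotypes), cohort.phenotypes.status.astype(float))
            ctx = liability_context(0.00739, cohort.phenotypes.case_fraction)
            ests.append(h2_liability_from_fit(fit, ctx).total)
        ests = np.asarray(ests)
        mc_se = ests.std(ddof=1) / np.sqrt(len(ests))
        assert abs(ests.mean() - 0.152) < max(2.5 * mc_se, 0.05)


class TestCovariateDifference:
    def _cohort(self, seed, share):
        from liabkit.synthetic_data import RiskSnpSpec

        cfg = SimulationConfig(
            n_cases=150, n_controls=350, m=800, h2_l=0.12 + share,
            K=0.00739, seed=seed, n_chromosomes=2,
            risk_snps=(RiskSnpSpec(maf=0.3, share=share, chromosome=1),) if share else (),
        )
        return simulate_ascertained_cohort(cfg), cfg

    def test_null_snp_difference_near_zero(self):
        diffs = []
        for seed in range(5):
            cohort, cfg = self._cohort(seed, 0.0)
            gm = cohort.genotypes
            ctx = liability_context(0.00739, cohort.phenotypes.case_fraction)
            diff, se = covariate_difference_h2(
                gm, cohort.phenotypes.status.astype(float), gm.snps[10].id, ctx
            )
            diffs.append((diff, se))
        mean = np.mean([d for d, _ in diffs])
        assert abs(mean) < 2 * np.std([d for d, _ in diffs]) / np.sqrt(5) + 0.01

    def test_known_share_recovered(self):
        share = 0.02
        diffs = []
        for seed in range(8):
            cohort, cfg = self._cohort(100 + seed, share)
            gm = cohort.genotypes
            ctx = liability_context(0.00739, cohort.phenotypes.case_fraction)
            idx = cfg.risk_snp_indices()[0]
            diff, _ = covariate_difference_h2(
                gm, cohort.phenotypes.status.astype(float), gm.snps[idx].id, ctx
            )
            diffs.append(diff)
        diffs = np.asarray(diffs)
        mc_se = diffs.std(ddof=1) / np.sqrt(len(diffs))
        assert abs(diffs.mean() - share) < max(2 * mc_se, 0.01)

    def test_missing_snp_errors(self):
        cohort, _ = self._cohort(7, 0.0)
        ctx = liability_context(0.00739, cohort.phenotypes.case_fraction)
        with pytest.raises(ValueError, match="not present"):
            covariate_difference_h2(
                cohort.genotypes, cohort.phenotypes.status.astype(float), "nope", ctx
            )
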