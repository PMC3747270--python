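"""Cohort simulator, association scan and empirical power/accuracy."""

import dataclasses

import numpy as np
import pytest

from gwasdesign.accuracy import accuracy_disease_cc, accuracy_disease_population
from gwasdesign.liability import make_design
from gwasdesign.power import ncp_bt_cc, ncp_qt_pop, power_from_ncp
from gwasdesign.simulate import (
    SimConfig,
    association_scan,
    empirical_accuracy,
    empirical_power,
    marginal_effect_estimates,
    simulate_cohort,
    write_cohort_tsv,
)


def small_config(**kw):
    base = dict(M=50, N=500, h2=0.1, K=0.1, P=0.5, design="BT",
                n_replicates=3, seed=99)
    base.update(kw)
    return SimConfig(**base)


class TestCohort:
    def test_population_case_rate_near_prevalence(self, rng):
        cfg = small_config(N=20000, ascertained=False)
        cohort = simulate_cohort(cfg, rng)
        k_hat = cohort.status.mean()
        se = np.sqrt(0.1 * 0.9 / cfg.N)
        assert abs(k_hat - 0.1) < 4 * se
        assert cohort.n_draws == cfg.N

    def test_zero_heritability_cohort(self, rng):
        cohort = simulate_cohort(small_config(h2=0.0), rng)
        assert np.allclose(cohort.g, 0.0)
        assert np.allclose(cohort.liability, cohort.e)

    def test_ascertained_quota_exact(self, rng):
        cfg = small_config(N=401, P=0.6, ascertained=True)
        cohort = simulate_cohort(cfg, rng)
        assert cohort.status.sum() == round(401 * 0.6)
        assert cohort.genotypes.shape == (401, cfg.M)
        # status is exactly liability > threshold
        t = make_design(cfg.K, cfg.P).t
        assert np.array_equal(cohort.status, cohort.liability > t)

    def test_rejection_draw_count_matches_waiting_time(self):
        """Filling 1000 cases at K=0.1 needs ~10^4 population draws."""
        cfg = small_config(M=20, N=2000, ascertained=True, K=0.1, P=0.5)
        draws = [
            simulate_cohort(cfg, np.random.default_rng(s)).n_draws
            for s in range(30)
        ]
        assert abs(np.mean(draws) - 10_000) / 10_000 < 0.2

    def test_genetic_variance_targets_h2(self):
        """Empirical var(g) across replicates brackets h2 = 0.1."""
        cfg = small_config(M=100, N=1000, h2=0.1)
        var_g = [
            simulate_cohort(cfg, np.random.default_rng(s)).g.var()
            for s in range(100)
        ]
        se = np.std(var_g, ddof=1) / 10
        assert abs(np.mean(var_g) - 0.1) < 3 * se

    def test_response_codings(self, rng):
        for design, check in [
            ("BT", lambda c: np.array_equal(c.response, c.status.astype(float))),
            ("QT", lambda c: np.array_equal(c.response, c.liability)),
            ("QB", lambda c: np.array_equal(
                c.response, np.where(c.status, c.liability, 0.0))),
        ]:
            cohort = simulate_cohort(
                small_config(design=design, ascertained=True),
                np.random.default_rng(5),
            )
            assert check(cohort), design

    def test_effect_distributions_hit_target_variance(self, rng):
        for dist in ("equal", "normal", "exponential"):
            cohort = simulate_cohort(
                small_config(M=200, effect_distribution=dist), rng
            )
            realised = np.sum(cohort.beta**2) * 0.5  # 2p(1-p) = 0.5
            assert realised == pytest.approx(0.1, rel=1e-9), dist

    def test_quota_budget_exhaustion_raises(self):
        cfg = small_config(N=2000, K=0.01, ascertained=True, max_draws=1000)
        with pytest.raises(RuntimeError, match="max_draws"):
            simulate_cohort(cfg, np.random.default_rng(0))


class TestAssociationScan:
    def test_null_calibration(self, rng):
        """Random response: rejection rate at alpha within binomial noise."""
        x = rng.binomial(2, 0.5, size=(500, 2000)).astype(np.int8)
        y = rng.standard_normal(500)
        _, pvals = association_scan(x, y)
        rate = np.mean(pvals < 0.05)
        assert abs(rate - 0.05) < 3 * np.sqrt(0.05 * 0.95 / 2000)

    def test_matches_ols_t_squared(self, rng):
        """Score statistic N*r^2 agrees with the OLS Wald t^2 to O(1/N)."""
        import statsmodels.api as sm

        cohort = simulate_cohort(small_config(M=10, N=50, h2=0.3), rng)
        stats_, pvals = association_scan(cohort.genotypes, cohort.response)
        for j in range(10):
            x = sm.add_constant(cohort.genotypes[:, j].astype(float))
            fit = sm.OLS(cohort.response, x).fit()
            t2 = fit.tvalues[1] ** 2
            assert stats_[j] == pytest.approx(t2, rel=0.15)

    def test_monomorphic_marker(self, rng):
        x = rng.binomial(2, 0.5, size=(100, 3)).astype(np.int8)
        x[:, 1] = 2
        stats_, pvals = association_scan(x, rng.standard_normal(100))
        assert stats_[1] == 0.0 and pvals[1] == 1.0
        assert (pvals[[0, 2]] < 1.0).all()

    def test_zero_variance_response_rejected(self, rng):
        x = rng.binomial(2, 0.5, size=(100, 3))
        with pytest.raises(ValueError, match="zero variance"):
            association_scan(x, np.ones(100))


class TestEmpiricalPower:
    def test_reproducible_bit_for_bit(self):
        cfg = small_config(n_replicates=4, seed=123)
        assert empirical_power(cfg) == empirical_power(cfg)

    def test_replicate_streams_stable_under_extension(self, rng):
        """Adding replicates never perturbs earlier ones."""
        short = small_config(n_replicates=2, seed=7)
        long = dataclasses.replace(short, n_replicates=4)
        # first-replicate cohort must be identical under both configs
        from gwasdesign.simulate import _replicate_rngs

        c1 = simulate_cohort(short, _replicate_rngs(short)[0])
        c2 = simulate_cohort(long, _replicate_rngs(long)[0])
        assert np.array_equal(c1.genotypes, c2.genotypes)
        assert np.array_equal(c1.response, c2.response)

    def test_matches_analytic_qt_pop(self):
        cfg = SimConfig(M=100, N=2000, h2=0.1, K=0.1, design="QT",
                        n_replicates=20, seed=31)
        summ = empirical_power(cfg)
        expected = power_from_ncp(ncp_qt_pop(2000, 0.001), 0.05)
        assert abs(summ.estimate - expected) < 3 * summ.se

    def test_matches_analytic_bt_cc(self):
        cfg = SimConfig(M=100, N=2000, h2=0.1, K=0.1, P=0.5, design="BT",
                        ascertained=True, n_replicates=20, seed=32)
        summ = empirical_power(cfg)
        expected = power_from_ncp(ncp_bt_cc(2000, 0.001, 0.1, 0.5), 0.05)
        assert abs(summ.estimate - expected) < 3 * summ.se
        assert summ.n_tests == 2000
        assert summ.se_replicate > 0


class TestEmpiricalAccuracy:
    def test_true_effects_give_perfect_correlation(self, rng):
        cohort = simulate_cohort(small_config(M=200, h2=0.5), rng)
        xc = cohort.genotypes - cohort.genotypes.mean(axis=0, dtype=float)
        assert np.corrcoef(cohort.g, xc @ cohort.beta)[0, 1] > 0.999

    def test_marginal_estimates_unbiased_scale(self, rng):
        """Slopes of status on genotype track the observed-scale effects."""
        cfg = small_config(M=40, N=4000, h2=0.2, K=0.1,
                           effect_distribution="normal")
        cohort = simulate_cohort(cfg, rng)
        beta_hat = marginal_effect_estimates(cohort.genotypes, cohort.response)
        assert beta_hat.shape == (40,)
        assert np.corrcoef(beta_hat, cohort.beta)[0, 1] > 0.2

    def test_matches_expected_case_control(self):
        """Scaled-down ascertained run vs the case-control formula."""
        cfg = SimConfig(M=500, N=500, h2=0.5, K=0.1, P=0.5, design="BT",
                        ascertained=True, n_replicates=10, seed=41,
                        N_validation=500)
        summ = empirical_accuracy(cfg)
        expected = accuracy_disease_cc(500, 500, 0.5, 0.1, 0.5).r
        assert abs(summ.estimate - expected) < 3 * summ.se

    def test_matches_expected_population(self):
        cfg = SimConfig(M=500, N=500, h2=0.5, K=0.2, design="BT",
                        ascertained=False, n_replicates=10, seed=42,
                        N_validation=500)
        summ = empirical_accuracy(cfg)
        expected = accuracy_disease_population(500, 500, 0.5, 0.2).r
        assert abs(summ.estimate - expected) < 3 * summ.se

    def test_reproducible(self):
        cfg = small_config(n_replicates=3, seed=5, N_validation=200)
        assert empirical_accuracy(cfg) == empirical_accuracy(cfg)


def test_cohort_tsv_round_trip(tmp_path, rng):
    import pandas as pd

    cohort = simulate_cohort(small_config(M=5, N=20), rng)
    gpath, ppath = tmp_path / "geno.tsv", tmp_path / "pheno.tsv"
    write_cohort_tsv(cohort, gpath, ppath)
    geno = pd.read_csv(gpath, sep="\t")
    pheno = pd.read_csv(ppath, sep="\t")
    assert list(geno.columns) == [f"snp{j}" for j in range(1, 6)]
    assert geno.shape == (20, 5)
    assert set(np.unique(geno.values)) <= {0, 1, 2}
    assert list(pheno.columns) == ["id", "g", "liability", "status", "response"]
    assert np.allclose(pheno["g"], cohort.g)
    assert set(pheno["status"]) <= {0, 1}


def test_invalid_configs_rejected():
    with pytest.raises(ValueError, match="design"):
        small_config(design="XX")
    with pytest.raises(ValueError, match="h2"):
        small_config(h2=1.0)
    with pytest.raises(ValueError, match="effect_distribution"):
        small_config(effect_distribution="uniform")
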