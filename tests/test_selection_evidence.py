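import numpy as np
import pytest
from scipy import integrate, stats

import unigev as ug
from unigev.selection_evidence import (
    alternate_hypothesis,
    chi2_site_statistic,
    combined_eos,
    dirichlet_null_hypothesis,
    eos_score,
    homogeneity_test,
    point_mass_hypothesis,
    reliability,
    site_log_likelihood,
)
from unigev.seqdata import SiteCounts

LN2 = np.log(2)


class TestSiteLogLikelihood:
    def test_empty_site_has_probability_one(self):
        assert site_log_likelihood(0, 0, 0.9, 0.1) == pytest.approx(0.0)

    def test_direct_binomial(self):
        # n=2, one nonsynonymous at p_ns = 0.5: 2 * 0.5 * 0.5
        assert site_log_likelihood(1, 1, 0.5, 0.5) == pytest.approx(np.log(0.5))

    def test_maximized_at_empirical_frequency(self):
        n_sn, n_ns = 60, 27
        grid = np.linspace(0.01, 0.99, 197)
        ll = site_log_likelihood(n_sn, n_ns, 1 - grid, grid)
        assert abs(grid[np.argmax(ll)] - n_ns / (n_sn + n_ns)) < 0.01

    def test_zero_probability_positive_count(self):
        assert site_log_likelihood(0, 3, 1.0, 0.0) == -np.inf


class TestEosScore:
    def test_identical_hypotheses_score_zero(self):
        site = SiteCounts(1, "TAT", 0, 3, 87)
        h = point_mass_hypothesis(0.05)
        res = eos_score(site, h, h, n_mc=5000, seed=0)
        assert res.R == pytest.approx(0.0, abs=1e-12)

    def test_no_clones_scores_exactly_zero(self):
        site = SiteCounts(1, "TAT", 0, 0, 0)
        res = eos_score(site, point_mass_hypothesis(0.05), point_mass_hypothesis(0.3))
        assert res.R == 0.0 and res.mc_se == 0.0

    def test_matches_quadrature_oracle(self):
        """Conserved site (87 clones, zero nonsynonymous) against a
        near-point-mass null: MC estimate matches 1-D quadrature over the
        alternate's Beta posterior."""
        site = SiteCounts(1, "TAT", 0, 0, 87)
        null = point_mass_hypothesis(0.05)
        alt = alternate_hypothesis(site)
        res = eos_score(site, null, alt, n_mc=50_000, seed=3)
        f = lambda q: stats.beta.pdf(q, 0.5, 87.5) * 87 * (
            np.log1p(-q) - np.log(0.95)
        )
        oracle_nats, _ = integrate.quad(f, 0, 1)
        assert res.R == pytest.approx(oracle_nats / LN2, abs=3 * res.mc_se)

    def test_seeded_reproducibility(self, ibmoi_us):
        site = SiteCounts(1, "TAT", 2, 1, 87)
        null = dirichlet_null_hypothesis(ibmoi_us, "TAT")
        alt = alternate_hypothesis(site)
        r1 = eos_score(site, null, alt, n_mc=2000, seed=9)
        r2 = eos_score(site, null, alt, n_mc=2000, seed=9)
        assert r1.R == r2.R

    def test_prior_odds_shift(self):
        site = SiteCounts(1, "TAT", 0, 2, 87)
        null = point_mass_hypothesis(0.05)
        r1 = eos_score(site, null, alternate_hypothesis(site), n_mc=4000, seed=1)
        r4 = eos_score(
            site, null, alternate_hypothesis(site, prior_odds=4.0), n_mc=4000, seed=1
        )
        assert r4.R - r1.R == pytest.approx(2.0, abs=1e-9)  # log2(4)


class TestCombinedEos:
    def _res(self, site, R):
        return ug.EoSResult(site_index=site, population="mx", R=R, mc_se=0.01)

    def test_single_site(self):
        assert combined_eos([self._res(1, 2.5)]) == 2.5

    def test_additivity_and_cancellation(self):
        assert combined_eos([self._res(1, 3.0), self._res(2, -3.0)]) == 0.0

    def test_duplicate_sites_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            combined_eos([self._res(1, 1.0), self._res(1, 1.0)])

    def test_additivity_on_synthetic_selected_sites(self, ibmoi_us):
        """Three conserved sites with individually-large scores combine to
        approximately the sum of their scores."""
        null = dirichlet_null_hypothesis(ibmoi_us, "TAT")
        results = []
        for j in range(1, 4):
            site = SiteCounts(j, "TAT", 3, 0, 87)
            results.append(eos_score(site, null, alternate_hypothesis(site),
                                     n_mc=20_000, seed=j))
        total = combined_eos(results)
        assert total == pytest.approx(
            sum(r.R for r in results), abs=1e-12
        )
        assert total > 3 * np.log2(20)  # each site is individually decisive


class TestReliability:
    def test_identical_hypotheses_give_zero(self):
        h = point_mass_hypothesis(0.1)
        d_ha, d_h0 = reliability(h, h, n_clones=50, n_mc=10, seed=0)
        assert d_ha == pytest.approx(0.0, abs=1e-12)
        assert d_h0 == pytest.approx(0.0, abs=1e-12)

    def test_nonnegative_by_gibbs(self, ibmoi_us):
        site = SiteCounts(1, "TAT", 4, 1, 87)
        null = dirichlet_null_hypothesis(ibmoi_us, "TAT")
        alt = alternate_hypothesis(site)
        d_ha, d_h0 = reliability(null, alt, n_clones=87, n_mc=500, seed=4)
        assert d_ha >= 0 and d_h0 >= 0

    def test_point_mass_pair_matches_exact_binomial_kl(self):
        null, alt = point_mass_hypothesis(0.01), point_mass_hypothesis(0.2)
        d_ha, d_h0 = reliability(null, alt, n_clones=87, n_mc=5, seed=0)
        x = np.arange(88)
        la = stats.binom.logpmf(x, 87, 0.2)
        l0 = stats.binom.logpmf(x, 87, 0.01)
        assert d_ha == pytest.approx(np.sum(np.exp(la) * (la - l0)) / LN2, abs=1e-9)
        assert d_h0 == pytest.approx(np.sum(np.exp(l0) * (l0 - la)) / LN2, abs=1e-9)


class TestHomogeneity:
    def test_no_data_is_neutral(self):
        s = SiteCounts(1, "AAA", 0, 0, 0)
        assert homogeneity_test(s, s) == pytest.approx(0.0)

    def test_identical_counts_favor_homogeneity(self):
        s = SiteCounts(1, "AAA", 0, 5, 100)
        assert homogeneity_test(s, s) > 0

    def test_divergent_counts_favor_heterogeneity(self):
        a = SiteCounts(1, "AAA", 0, 40, 87)
        b = SiteCounts(1, "AAA", 0, 2, 87)
        assert homogeneity_test(a, b) < 0


class TestChi2:
    def test_zero_when_observed_equals_expected(self):
        site = SiteCounts(1, "AAA", 0, 5, 100)
        assert chi2_site_statistic(site, 0.05) == pytest.approx(0.0)

    def test_direct_formula(self):
        site = SiteCounts(1, "AAA", 0, 0, 100)
        # (0-5)^2/5 + (100-95)^2/95
        assert chi2_site_statistic(site, 0.05) == pytest.approx(25 / 5 + 25 / 95)

    def test_zero_expectation_rejected(self):
        with pytest.raises(ValueError):
            chi2_site_statistic(SiteCounts(1, "AAA", 0, 0, 10), 0.0)

    def test_rank_correlation_with_eos(self, ibmoi_us):
        """Chi-square and EoS are strongly (if nonlinearly) rank-correlated
        across sites with varying observed counts."""
        null = dirichlet_null_hypothesis(ibmoi_us, "TAT")
        p_ns0 = 1.0 - float(
            ug.synonymous_probability(
                ug.natural_parameter_matrix(ibmoi_us).matrix, "TAT"
            )
        )
        rng = np.random.default_rng(5)
        eos_vals, chi_vals = [], []
        for j, n_ns in enumerate([0, 1, 2, 3, 5, 8, 11, 15, 20, 26]):
            site = SiteCounts(j + 1, "TAT", 2, n_ns, 87)
            res = eos_score(site, null, alternate_hypothesis(site),
                            n_mc=4000, seed=int(rng.integers(2**31)))
            eos_vals.append(res.R)
            chi_vals.append(chi2_site_statistic(site, p_ns0))
        rho = stats.spearmanr(eos_vals, chi_vals).statistic
        assert rho > 0.7
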