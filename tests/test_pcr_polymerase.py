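import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import comb
from scipy.stats import multinomial

import unigev as ug
from unigev.pcr_polymerase import (
    CONSTRAINT_BASIS,
    ChainSettings,
    PolymeraseMatrix,
    QUOTIENT_BASIS,
    StrandPair,
    complement_operator,
    counts_log_likelihood,
    fisher_information,
    initial_polymerase,
    jeffreys_log_prior,
    pcr_cycle,
    pcr_model_with_derivatives,
    pcr_mutation_matrix,
)
from unigev.seqdata import COMPLEMENT_INDEX, MisincorporationCounts

from conftest import random_stochastic_matrix


def expansion_oracle(T: np.ndarray, k: int, s0: np.ndarray, n0: np.ndarray) -> np.ndarray:
    """Closed-form binomial expansion of the sense strand after k cycles:
    2^k s_k = sum_m C(k, m) T^m (s0 if m even else n0)."""
    acc = np.zeros(4)
    for m in range(k + 1):
        vec = s0 if m % 2 == 0 else n0
        acc += comb(k, m, exact=True) * (np.linalg.matrix_power(T, m) @ vec)
    return acc / 2**k


class TestPcrCycle:
    def test_perfect_polymerase_fixed_point(self):
        K = complement_operator()
        sp = StrandPair(np.array([1.0, 0, 0, 0]), np.array([0, 0, 0, 1.0]))
        out = pcr_cycle(sp, K)
        assert np.allclose(out.s, sp.s) and np.allclose(out.n, sp.n)

    @settings(max_examples=25, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_markov_conservation(self, seed):
        rng = np.random.default_rng(seed)
        T = random_stochastic_matrix(rng)
        sp = StrandPair(rng.dirichlet(np.ones(4)), rng.dirichlet(np.ones(4)))
        out = pcr_cycle(sp, T)
        assert np.isclose(out.s.sum(), 1.0) and np.isclose(out.n.sum(), 1.0)
        assert np.all(out.s >= 0) and np.all(out.n >= 0)

    def test_two_cycle_expansion(self):
        rng = np.random.default_rng(0)
        T = random_stochastic_matrix(rng)
        s0, n0 = rng.dirichlet(np.ones(4)), rng.dirichlet(np.ones(4))
        sp = pcr_cycle(pcr_cycle(StrandPair(s0, n0), T), T)
        # 2^2 s_2 = T^2 s0 + 2 T n0 + s0
        assert np.allclose(4 * sp.s, T @ T @ s0 + 2 * T @ n0 + s0, atol=1e-14)


class TestPcrMutationMatrix:
    def test_zero_cycles_is_identity(self):
        T = random_stochastic_matrix(np.random.default_rng(1))
        assert np.allclose(pcr_mutation_matrix(T, 0).matrix, np.eye(4))

    def test_perfect_polymerase_any_k_is_identity(self):
        assert np.allclose(pcr_mutation_matrix(complement_operator(), 25).matrix, np.eye(4))

    @pytest.mark.parametrize("k", range(8))
    def test_matches_binomial_expansion(self, k):
        rng = np.random.default_rng(k + 10)
        T = random_stochastic_matrix(rng)
        P = pcr_mutation_matrix(T, k).matrix
        for ell in range(4):
            s0 = np.eye(4)[ell]
            n0 = np.eye(4)[COMPLEMENT_INDEX[ell]]
            assert np.allclose(P[:, ell], expansion_oracle(T, k, s0, n0), atol=1e-12)

    @settings(max_examples=20, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.integers(1, 40))
    def test_column_stochastic_for_all_k(self, seed, k):
        T = random_stochastic_matrix(np.random.default_rng(seed))
        P = pcr_mutation_matrix(T, k).matrix
        assert np.allclose(P.sum(axis=0), 1.0, atol=1e-12)
        assert np.all(P >= -1e-15)


class TestLikelihood:
    def test_perfect_fit_has_probability_one(self):
        C = MisincorporationCounts(np.diag([10, 20, 30, 40]))
        assert counts_log_likelihood(C, complement_operator(), 12) == pytest.approx(0.0)

    def test_matches_direct_multinomial_product(self):
        rng = np.random.default_rng(3)
        T = random_stochastic_matrix(rng)
        k = 5
        P = pcr_mutation_matrix(T, k).matrix
        counts = rng.integers(0, 20, size=(4, 4))
        C = MisincorporationCounts(counts)
        direct = sum(
            multinomial.logpmf(counts[:, j], counts[:, j].sum(), P[:, j])
            for j in range(4)
        )
        assert counts_log_likelihood(C, T, k) == pytest.approx(direct, abs=1e-10)

    def test_zero_probability_with_positive_count(self):
        C = MisincorporationCounts(np.ones((4, 4), dtype=int))
        assert counts_log_likelihood(C, complement_operator(), 3) == -np.inf


class TestDerivatives:
    def test_first_derivatives_match_finite_differences(self):
        rng = np.random.default_rng(7)
        ttilde = rng.normal(0, 1, 16)
        _, dP, _ = pcr_model_with_derivatives(ttilde, 9, order=1)
        h = 1e-5
        for a in range(16):
            tp, tm = ttilde.copy(), ttilde.copy()
            tp[a] += h
            tm[a] -= h
            Pp, _, _ = pcr_model_with_derivatives(tp, 9, order=0)
            Pm, _, _ = pcr_model_with_derivatives(tm, 9, order=0)
            fd = (Pp - Pm) / (2 * h)
            assert np.allclose(dP[:, :, a], fd, atol=1e-6 * max(1, np.abs(fd).max()))

    def test_second_derivatives_match_finite_differences(self):
        rng = np.random.default_rng(8)
        ttilde = rng.normal(0, 1, 16)
        _, _, d2P = pcr_model_with_derivatives(ttilde, 9, order=2)
        h = 1e-5
        for a, b in [(0, 0), (3, 9), (14, 2), (7, 7)]:
            tp, tm = ttilde.copy(), ttilde.copy()
            tp[b] += h
            tm[b] -= h
            _, dPp, _ = pcr_model_with_derivatives(tp, 9, order=1)
            _, dPm, _ = pcr_model_with_derivatives(tm, 9, order=1)
            fd = (dPp[:, :, a] - dPm[:, :, a]) / (2 * h)
            assert np.allclose(d2P[:, :, a, b], fd, atol=1e-6)


class TestFisherInformation:
    TOTALS = np.array([24273.0, 18096.0, 11223.0, 15834.0])

    def _ttilde(self):
        rng = np.random.default_rng(11)
        T = complement_operator() * 0.97 + 0.01
        T = T / T.sum(axis=0)
        return np.log(T).ravel(order="F") + 0.05 * rng.normal(size=16)

    def test_symmetric_and_psd_on_quotient(self):
        info = fisher_information(None, self.TOTALS, 10, ttilde=self._ttilde())
        assert np.allclose(info.F, info.F.T, atol=1e-10)
        eigs = np.linalg.eigvalsh(info.projected)
        assert np.all(eigs > 0)

    def test_four_null_directions_are_column_constraints(self):
        info = fisher_information(None, self.TOTALS, 10, ttilde=self._ttilde())
        assert np.max(np.abs(info.F @ CONSTRAINT_BASIS)) < 1e-6 * np.abs(info.F).max()

    def test_score_form_equals_full_expected_hessian(self):
        tt = self._ttilde()
        F1 = fisher_information(None, self.TOTALS, 10, ttilde=tt).F
        F2 = fisher_information(
            None, self.TOTALS, 10, ttilde=tt, include_hessian_term=True
        ).F
        assert np.allclose(F1, F2, atol=1e-8 * np.abs(F1).max())


class TestJeffreysPrior:
    TOTALS = TestFisherInformation.TOTALS

    def test_gauge_invariance(self):
        tt = TestFisherInformation()._ttilde()
        lp = jeffreys_log_prior(None, self.TOTALS, 10, ttilde=tt)
        shifted = tt.copy()
        shifted[8:12] += 2.5  # shift one column's log-parameters
        assert jeffreys_log_prior(None, self.TOTALS, 10, ttilde=shifted) == pytest.approx(
            lp, abs=1e-8
        )

    def test_total_scaling_adds_six_log_c(self):
        tt = TestFisherInformation()._ttilde()
        lp1 = jeffreys_log_prior(None, self.TOTALS, 10, ttilde=tt)
        lp2 = jeffreys_log_prior(None, 7.0 * self.TOTALS, 10, ttilde=tt)
        assert lp2 - lp1 == pytest.approx(6 * np.log(7.0), abs=1e-8)

    def test_finite_near_complement_identity(self):
        T = complement_operator() * 0.994 + 0.002
        T = T / T.sum(axis=0)
        lp = jeffreys_log_prior(None, self.TOTALS, 30, ttilde=np.log(T).ravel(order="F"))
        assert np.isfinite(lp)


class TestMapEstimate:
    def test_recovers_generating_matrix(self):
        """Counts simulated from a known polymerase are recovered within
        3 Laplace posterior SD of the implied mutation matrix."""
        rng = np.random.default_rng(21)
        T_true = complement_operator() * 0.997
        T_true += rng.uniform(0.0002, 0.002, size=(4, 4)) * (T_true == 0)
        T_true = T_true / T_true.sum(axis=0)
        k = 30
        P_true = pcr_mutation_matrix(T_true, k).matrix
        totals = np.array([25000, 18000, 11000, 16000])
        counts = np.column_stack(
            [rng.multinomial(totals[j], P_true[:, j]) for j in range(4)]
        )
        fit = ug.map_estimate(MisincorporationCounts(counts), k)
        sd = fit.posterior_sd_P()
        assert np.all(np.abs(fit.P.matrix - P_true) <= 3 * sd + 1e-6)

    def test_deterministic(self, ibmoi_us, ibmoi_map):
        again = ug.map_estimate(ibmoi_us, 30)
        assert np.allclose(again.P.matrix, ibmoi_map.P.matrix, atol=1e-9)

    def test_counter_diagonal_dominates(self, ibmoi_map):
        T = ibmoi_map.T.T
        counter = T[COMPLEMENT_INDEX, np.arange(4)]
        assert np.all(counter > 0.99)

    def test_initial_guess_is_valid(self, ibmoi_us):
        T0 = initial_polymerase(ibmoi_us, 30)
        assert np.allclose(T0.T.sum(axis=0), 1.0)


@pytest.fixture(scope="module")
def chain(ibmoi_us, ibmoi_map):
    settings_ = ChainSettings(length=2500, burn_in=500, thin=5, seed=17)
    return ug.sample_posterior_T(ibmoi_us, 30, settings_, map_fit=ibmoi_map)


class TestPosteriorSampling:
    def test_seed_reproducibility(self, ibmoi_us, ibmoi_map, chain):
        settings_ = ChainSettings(length=2500, burn_in=500, thin=5, seed=17)
        again = ug.sample_posterior_T(ibmoi_us, 30, settings_, map_fit=ibmoi_map)
        assert np.array_equal(again.T_draws, chain.T_draws)

    def test_posterior_mean_near_map(self, ibmoi_map, chain):
        # mean and mode of the skewed log-space posterior differ, but for
        # these count scales stay within a few Laplace SD of each other
        sd = ibmoi_map.posterior_sd_P()
        diff = np.abs(chain.P_draws.mean(axis=0) - ibmoi_map.P.matrix)
        assert np.all(diff < 3 * sd)

    def test_complementary_entry_similarity(self, chain):
        """Posterior mutation matrices show the complementary-base symmetry
        the polymerase mechanism predicts: p_ij ~ p_(comp i)(comp j)."""
        P_mean = chain.P_draws.mean(axis=0)
        P_comp = P_mean[np.ix_(COMPLEMENT_INDEX, COMPLEMENT_INDEX)]
        off = ~np.eye(4, dtype=bool)
        ratio = P_mean[off] / P_comp[off]
        assert np.all((ratio > 1 / 3) & (ratio < 3))

    def test_acceptance_rate_workable(self, chain):
        assert 0.01 <= chain.acceptance_rate <= 0.9


def test_polymerase_matrix_validation():
    with pytest.raises(ValueError):
        PolymeraseMatrix(np.eye(4) * 0.9)
    T = PolymeraseMatrix(np.eye(4))
    assert np.allclose(T.T, np.eye(4))


def test_log_param_round_trip():
    T = random_stochastic_matrix(np.random.default_rng(2))
    back = PolymeraseMatrix.from_log_params(PolymeraseMatrix(T).log_params)
    assert np.allclose(back.T, T, atol=1e-12)
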