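"""PWM estimation, gauge fixing, maxent fitting, and greedy BIC growth."""
import numpy as np
import pytest

from pimotif.core import (
    PIMParams,
    SiteSet,
    log_partition,
    model_marginals,
    probability,
    pwm_probability,
)
from pimotif.inference import (
    bic,
    build_pim,
    empirical_frequencies,
    estimate_pwm,
    fit_pim,
    fix_gauge,
    select_next_pair,
)
from pimotif.synth import sample_sites
from .conftest import all_states, random_pim


class TestEstimatePWM:
    def test_laplace_arithmetic(self):
        sites = SiteSet.from_strings(["AA", "AC", "AG", "CA"])
        # position 0 counts (3,1,0,0), beta=1 -> (4,2,1,1)/8
        pwm = estimate_pwm(sites, beta=1.0)
        np.testing.assert_allclose(pwm.probs[0], [0.5, 0.25, 0.125, 0.125])

    def test_beta_zero_is_raw_frequency(self):
        sites = SiteSet.from_strings(["AA"] * 3 + ["CA"])
        pwm = estimate_pwm(sites, beta=0.0)
        np.testing.assert_allclose(pwm.probs[0], [0.75, 0.25, 0, 0])

    def test_prior_dominates_uninformative_cells(self):
        sites = SiteSet.from_strings(["A"])
        pwm = estimate_pwm(sites, beta=1000.0)
        np.testing.assert_allclose(pwm.probs[0], 0.25, atol=1e-3)


class TestEmpiricalFrequencies:
    def test_single_site_beta_zero(self):
        f = empirical_frequencies(SiteSet.from_strings(["AA"]), 0.0, 0.0)
        expected = np.zeros((4, 4))
        expected[0, 0] = 1.0
        np.testing.assert_allclose(f.pair(0, 1), expected)

    def test_pair_marginal_consistency_beta_zero(self, rng):
        sites = SiteSet(rng.integers(0, 4, size=(100, 3)))
        f = empirical_frequencies(sites, 0.0, 0.0)
        np.testing.assert_allclose(f.pair(0, 2).sum(axis=1), f.singles[0],
                                   atol=1e-12)

    def test_pair_marginal_consistency_with_pseudocounts(self, rng):
        # the rebalanced pair tables must match the pseudo-counted singles
        sites = SiteSet(rng.integers(0, 4, size=(50, 3)))
        f = empirical_frequencies(sites)
        np.testing.assert_allclose(f.pair(0, 1).sum(axis=1), f.singles[0],
                                   atol=1e-12)

    def test_duplication_invariance_beta_zero(self, rng):
        seqs = rng.integers(0, 4, size=(30, 3))
        f1 = empirical_frequencies(SiteSet(seqs), 0.0, 0.0)
        f2 = empirical_frequencies(SiteSet(np.vstack([seqs, seqs])), 0.0, 0.0)
        np.testing.assert_allclose(f1.singles, f2.singles, atol=1e-12)
        np.testing.assert_allclose(f1.pairs, f2.pairs, atol=1e-12)


class TestGauge:
    def test_zero_sum_conditions(self, rng):
        g = fix_gauge(random_pim(4, [(0, 1), (2, 3)], rng))
        np.testing.assert_allclose(g.h.sum(axis=1), 0.0, atol=1e-10)
        for block in g.couplings.values():
            np.testing.assert_allclose(block.sum(axis=0), 0.0, atol=1e-10)
            np.testing.assert_allclose(block.sum(axis=1), 0.0, atol=1e-10)

    def test_idempotent(self, rng):
        g = fix_gauge(random_pim(3, [(0, 2)], rng))
        g2 = fix_gauge(g)
        np.testing.assert_allclose(g.h, g2.h, atol=1e-12)
        np.testing.assert_allclose(g.couplings[(0, 2)], g2.couplings[(0, 2)],
                                   atol=1e-12)

    def test_constant_fields_removed(self):
        h = np.full((2, 4), 3.7)
        g = fix_gauge(PIMParams(h))
        np.testing.assert_allclose(g.h, 0.0, atol=1e-12)

    def test_constant_row_block_absorbed(self):
        # J(a, b) = r(a): constant rows -> fields, block exactly zero
        r = np.array([1.0, -2.0, 0.5, 0.5])
        J = np.tile(r[:, None], (1, 4))
        g = fix_gauge(PIMParams(np.zeros((2, 4)), {(0, 1): J}))
        np.testing.assert_allclose(g.couplings[(0, 1)], 0.0, atol=1e-12)
        # by hand: h_0 gains r minus its mean
        np.testing.assert_allclose(g.h[0], r - r.mean(), atol=1e-12)

    def test_probabilities_preserved(self, rng):
        p = random_pim(3, [(0, 1), (1, 2)], rng)
        g = fix_gauge(p)
        states = all_states(3)
        np.testing.assert_allclose(probability(p, states),
                                   probability(g, states), atol=1e-10)


def _ipf_maxent(singles, pair_01, n_pos, iters=5000):
    """Independent maxent oracle: iterative proportional fitting directly on
    the probability vector over all states (no exponential parameterization).
    """
    states = all_states(n_pos)
    P = np.full(4 ** n_pos, 4.0 ** -n_pos)
    for _ in range(iters):
        for i in range(n_pos):
            marg = np.bincount(states[:, i], weights=P, minlength=4)
            P *= (singles[i] / marg)[states[:, i]]
        code = states[:, 0] * 4 + states[:, 1]
        marg = np.bincount(code, weights=P, minlength=16)
        P *= (pair_01.ravel() / marg)[code]
        if np.abs(marg - pair_01.ravel()).max() < 1e-13:
            break
    return P


class TestFitPIM:
    def test_no_couplings_equals_pwm_product(self, rng):
        sites = SiteSet(rng.integers(0, 4, size=(500, 3)))
        fitted, info = fit_pim(sites, [])
        assert info["converged"]
        pwm = estimate_pwm(sites, beta=1.0)
        states = all_states(3)
        np.testing.assert_allclose(probability(fitted, states),
                                   pwm_probability(pwm, states), atol=2e-4)

    def test_l2_full_pair_reproduces_joint(self, rng):
        sites = SiteSet(rng.integers(0, 4, size=(400, 2)))
        fitted, info = fit_pim(sites, [(0, 1)], tol=1e-8)
        assert info["converged"]
        target = empirical_frequencies(sites)
        f = model_marginals(fitted)
        np.testing.assert_allclose(f.pair(0, 1), target.pair(0, 1), atol=1e-7)

    def test_matches_ipf_oracle(self, rng):
        truth = random_pim(3, [(0, 1)], rng, h_scale=0.7, j_scale=0.7)
        sites = sample_sites(truth, 500, seed=5)
        target = empirical_frequencies(sites)
        fitted, info = fit_pim(target, [(0, 1)], tol=1e-9)
        assert info["converged"]
        oracle = _ipf_maxent(target.singles, target.pair(0, 1), 3)
        np.testing.assert_allclose(probability(fitted, all_states(3)),
                                   oracle, atol=1e-6)

    def test_init_independence(self, rng):
        sites = SiteSet(rng.integers(0, 4, size=(300, 3)))
        a, _ = fit_pim(sites, [(0, 2)], tol=1e-9)
        start = random_pim(3, [(0, 2)], rng, h_scale=0.3, j_scale=0.3)
        b, _ = fit_pim(sites, [(0, 2)], init=start, tol=1e-9)
        states = all_states(3)
        np.testing.assert_allclose(probability(a, states),
                                   probability(b, states), atol=1e-6)


class TestSelectNextPair:
    def test_planted_correlation_found(self, rng):
        # positions 0 and 1 perfectly correlated, position 2 independent
        a = rng.integers(0, 4, size=600)
        c = rng.integers(0, 4, size=600)
        sites = SiteSet(np.stack([a, a, c], axis=1))
        fitted, _ = fit_pim(sites, [])
        assert select_next_pair(fitted, sites) == (0, 1)

    def test_all_excluded_returns_none(self, rng):
        sites = SiteSet(rng.integers(0, 4, size=(50, 3)))
        fitted, _ = fit_pim(sites, [])
        pairs = [(0, 1), (0, 2), (1, 2)]
        assert select_next_pair(fitted, sites, excluded=pairs) is None

    def test_null_case_lexicographic_tiebreak(self):
        # model marginals match data exactly: all p-values 1, first pair wins
        sites = SiteSet(all_states(2).repeat(4, axis=0))
        fitted, _ = fit_pim(sites, [], beta_single=0.0, beta_pair=0.0,
                            tol=1e-10)
        assert select_next_pair(fitted, sites) == (0, 1)


class TestBIC:
    def test_k_zero_is_nll(self):
        assert bic(12.5, 0, 1000) == pytest.approx(12.5)

    def test_penalty_difference(self):
        # at N = e^2 the penalty for 9 extra parameters is (9/2) ln N = 9
        N = np.exp(2)
        assert bic(0.0, 9, N) - bic(0.0, 0, N) == pytest.approx(9.0)

    def test_monotone_in_k(self):
        vals = [bic(5.0, k, 100) for k in range(5)]
        assert all(b < c for b, c in zip(vals, vals[1:]))


class TestBuildPIM:
    def test_pwm_data_selects_few_couplings(self, rng):
        hits = 0
        for seed in range(5):
            probs = np.random.default_rng(seed).dirichlet(np.ones(4) * 2,
                                                          size=6)
            from pimotif.core import PWM
            sites = sample_sites(PWM(probs), 2000, seed=100 + seed)
            params, _ = build_pim(sites)
            if len(params.active_pairs) <= 2:
                hits += 1
        assert hits >= 5 * 0.9 - 1e-9

    def test_planted_adjacent_coupling_found_first(self, rng):
        J = np.zeros((4, 4))
        J[0, 0] = -2.0
        J[2, 2] = -2.0
        truth = PIMParams(rng.normal(0, 0.3, (5, 4)), {(2, 3): J})
        sites = sample_sites(truth, 4000, seed=9)
        for universe in ("all", "nearest_neighbor"):
            _, trace = build_pim(sites, pair_universe=universe)
            assert trace.records[1].pair == (2, 3)

    def test_nearest_neighbor_universe_bound(self, rng):
        sites = SiteSet(rng.integers(0, 4, size=(200, 5)))
        params, trace = build_pim(sites, pair_universe="nearest_neighbor",
                                  patience=100)
        assert all(r.pair is None or r.pair[1] == r.pair[0] + 1
                   for r in trace.records)
        assert len(trace.records) - 1 <= 4

    def test_likelihood_nondecreasing_along_trace(self, rng):
        truth = random_pim(5, [(0, 1), (2, 4)], rng, h_scale=0.6, j_scale=0.8)
        sites = sample_sites(truth, 3000, seed=3)
        _, trace = build_pim(sites)
        nlls = [r.nll for r in trace.records]
        for a, b in zip(nlls, nlls[1:]):
            assert b <= a + 1e-6 * sites.N

    def test_nnm_bic_not_better_than_pim_on_nonadjacent_truth(self, rng):
        J = np.zeros((4, 4))
        J[1, 1] = -2.5
        J[3, 3] = -2.5
        truth = PIMParams(rng.normal(0, 0.3, (6, 4)), {(0, 4): J})
        sites = sample_sites(truth, 4000, seed=21)
        _, trace_full = build_pim(sites, "all")
        _, trace_nn = build_pim(sites, "nearest_neighbor")
        best_full = min(r.bic for r in trace_full.records)
        best_nn = min(r.bic for r in trace_nn.records)
        assert best_nn >= best_full


class TestParameterRecovery:
    def test_moderate_scale_recovery(self, rng):
        # scaled-down cousin of the headline recovery check
        pairs = [(0, 1), (2, 3)]
        truth = fix_gauge(random_pim(5, pairs, rng, h_scale=0.5, j_scale=0.5))
        sites = sample_sites(truth, 20000, seed=13)
        fitted, info = fit_pim(sites, pairs, tol=1e-5)
        assert info["converged"]
        assert np.abs(fitted.h - truth.h).max() < 0.08
        for p in pairs:
            assert np.abs(fitted.couplings[p] - truth.couplings[p]).max() < 0.08
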