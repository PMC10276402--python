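import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from burstkit.distributions import (
    BurstParams,
    ConversionRates,
    UracilDistribution,
    capture_pmf,
    conversions_given_m,
    conversions_given_umi,
    fsp_bound,
    log_capture_pmf,
    log_nb_steady_state,
    log_umi_marginal,
    nb_pmf_vector,
    nb_steady_state,
    new_given_total,
    new_transcript_pmf,
    new_transcript_pmf_vector,
    pooled_conversion_pmf,
    poisson_mixture,
    posterior_m_given_l,
    surviving_conditional,
    surviving_marginal,
    surviving_pmf_vector,
    umi_marginal,
)


def make_params(a: float, b: float, gamma: float = 1000.0) -> BurstParams:
    return BurstParams(mu=a * b, a=a, gamma=gamma)


# ---------------------------------------------------------------------------
# BurstParams
# ---------------------------------------------------------------------------


class TestBurstParams:
    def test_derived_quantities(self, fig9_params):
        p = fig9_params
        assert p.a == pytest.approx(2.0)
        assert p.b == pytest.approx(25.0)
        assert p.mu == pytest.approx(50.0)
        assert p.delta == pytest.approx(0.001)
        assert p.kappa == pytest.approx(0.002)
        assert p.tau(1000.0) == pytest.approx(1.0)

    @given(
        b=st.floats(0.01, 500.0),
        kappa=st.floats(1e-5, 0.5),
        gamma=st.floats(1.0, 1e5),
    )
    @settings(max_examples=50, deadline=None)
    def test_round_trip(self, b, kappa, gamma):
        delta = 1.0 / gamma
        p = BurstParams.from_burst(b=b, kappa=kappa, delta=delta)
        assert p.b == pytest.approx(b, rel=1e-12)
        assert p.kappa == pytest.approx(kappa, rel=1e-12)
        assert p.delta == pytest.approx(delta, rel=1e-12)
        assert p.mu == pytest.approx(p.a * p.b, rel=1e-12)

    @pytest.mark.parametrize("bad", [dict(mu=0, a=1, gamma=10), dict(mu=1, a=-1, gamma=10), dict(mu=1, a=1, gamma=0.5)])
    def test_invalid(self, bad):
        with pytest.raises(ValueError):
            BurstParams(**bad)


# ---------------------------------------------------------------------------
# steady state + FSP
# ---------------------------------------------------------------------------


class TestSteadyState:
    def test_geometric_case(self):
        # a=1, b=1: geometric with success prob 1/2
        assert nb_steady_state(0, make_params(1, 1)) == pytest.approx(0.5)

    def test_fig9_point(self, fig9_params):
        assert nb_steady_state(0, fig9_params) == pytest.approx((1 / 26) ** 2, rel=1e-12)

    def test_normalization(self, fig9_params):
        M = fsp_bound(fig9_params, 1 - 1e-12).M
        total = nb_pmf_vector(np.arange(M + 1), fig9_params).sum()
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_log_consistency(self, fig9_params):
        for m in (0, 3, 50):
            assert log_nb_steady_state(m, fig9_params) == pytest.approx(
                math.log(nb_steady_state(m, fig9_params)), rel=1e-12
            )

    def test_negative_m_rejected(self, fig9_params):
        with pytest.raises(ValueError):
            nb_steady_state(-1, fig9_params)


class TestFSPBound:
    def test_geometric_bound_is_13(self):
        # 0.5^(M+1) <= 1e-4 first at M=13 (brute-force verified below)
        assert fsp_bound(make_params(1, 1), 0.9999).M == 13

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            a = rng.uniform(0.1, 10)
            b = rng.uniform(1, 300)
            p = make_params(a, b)
            M = fsp_bound(p).M
            # independent oracle: scan the CDF
            grid = np.arange(M + 2)
            cdf = np.cumsum(nb_pmf_vector(grid, p))
            assert cdf[M] >= 0.9999
            assert M == 0 or cdf[M - 1] < 0.9999

    def test_tiny_b_gives_zero(self):
        assert fsp_bound(make_params(2.0, 1e-9)).M == 0

    def test_tail_mass_bounded(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            p = make_params(rng.uniform(0.1, 10), rng.uniform(1, 300))
            bound = fsp_bound(p)
            tail = 1.0 - stats.nbinom.cdf(bound.M, p.a, 1 / (1 + p.b))
            assert tail <= 1e-4


# ---------------------------------------------------------------------------
# capture model
# ---------------------------------------------------------------------------


class TestCapture:
    def test_empty_cell(self):
        assert capture_pmf(0, 0, 0.3) == pytest.approx(1.0)

    def test_poisson_value(self):
        # Poisson(10) at 10, closed form
        expected = math.exp(-10) * 10**10 / math.factorial(10)
        assert capture_pmf(10, 100, 0.1) == pytest.approx(expected, rel=1e-12)

    def test_l_exceeding_m_is_possible(self):
        assert capture_pmf(5, 3, 0.1) > 0

    def test_log_consistency(self):
        assert log_capture_pmf(4, np.array([30]), 0.2)[0] == pytest.approx(
            math.log(capture_pmf(4, 30, 0.2))
        )

    def test_invalid_alpha(self):
        with pytest.raises(ValueError):
            capture_pmf(1, 1, 0.0)


class TestUmiMarginal:
    def test_nothing_captured(self, fig9_params):
        # equals 1 up to the FSP truncation error of 1e-4
        assert umi_marginal(0, 1e-9, fig9_params) == pytest.approx(1.0, abs=2e-4)

    def test_normalization(self, fig9_params):
        total = sum(umi_marginal(l, 0.1, fig9_params) for l in range(80))
        assert total >= 0.9999

    def test_monte_carlo_oracle(self, fig9_params):
        # sample m ~ NB, l ~ Poisson(m * alpha); compare frequencies
        rng = np.random.default_rng(7)
        n = 10**6
        alpha = 0.1
        m = rng.negative_binomial(fig9_params.a, 1 / (1 + fig9_params.b), size=n)
        l = rng.poisson(m * alpha)
        for li in range(11):
            phat = np.mean(l == li)
            se = math.sqrt(phat * (1 - phat) / n)
            assert umi_marginal(li, alpha, fig9_params) == pytest.approx(phat, abs=3 * se + 1e-9)

    def test_log_consistency(self, fig9_params):
        assert log_umi_marginal(3, 0.1, fig9_params) == pytest.approx(
            math.log(umi_marginal(3, 0.1, fig9_params))
        )


class TestPosteriorMGivenL:
    def test_sums_to_one(self, fig9_params):
        post = posterior_m_given_l(3, 0.1, fig9_params)
        assert post.sum() == pytest.approx(1.0, abs=1e-12)
        assert (post >= 0).all()

    def test_uninformative_observation_returns_prior(self, fig9_params):
        post = posterior_m_given_l(0, 1e-9, fig9_params)
        prior = nb_pmf_vector(np.arange(post.size), fig9_params)
        prior = prior / prior.sum()
        assert np.abs(post - prior).max() < 1e-6

    def test_brute_force(self, fig9_params):
        bound = fsp_bound(fig9_params)
        expected = np.array(
            [
                capture_pmf(3, m, 0.1) * nb_steady_state(m, fig9_params)
                for m in range(bound.M + 1)
            ]
        )
        expected /= expected.sum()
        got = posterior_m_given_l(3, 0.1, fig9_params, bound)
        assert np.abs(got - expected).max() < 1e-12

    def test_impossible_observation_raises(self):
        p = make_params(2.0, 1e-9)  # M = 0, so l > 0 has zero mass at alpha -> tiny
        with pytest.raises(ValueError):
            posterior_m_given_l(5, 1e-12, p)


# ---------------------------------------------------------------------------
# surviving transcripts
# ---------------------------------------------------------------------------


class TestSurviving:
    def test_no_decay(self):
        assert surviving_conditional(7, 7, 0.0) == pytest.approx(1.0)

    def test_single_transcript_death(self):
        assert surviving_conditional(0, 1, 1.0) == pytest.approx(1 - math.exp(-1), rel=1e-12)

    def test_s_above_m_is_zero(self):
        assert surviving_conditional(4, 3, 1.0) == 0.0

    @pytest.mark.parametrize("tau", [0.1, 1.0, 10.0])
    def test_row_sums(self, tau):
        for m in (0, 1, 17, 50):
            total = sum(surviving_conditional(s, m, tau) for s in range(m + 1))
            assert total == pytest.approx(1.0, abs=1e-12)

    def test_tau_zero_is_steady_state(self, fig9_params):
        s = np.arange(200)
        assert np.abs(
            surviving_pmf_vector(s, fig9_params, 0.0) - nb_pmf_vector(s, fig9_params)
        ).max() < 1e-14

    def test_long_pulse_leaves_nothing(self, fig9_params):
        assert surviving_marginal(0, fig9_params, 20.0) == pytest.approx(1.0, abs=1e-6)

    def test_thinning_identity_vs_brute_force(self, fig9_params):
        # explicit compound sum over the conditional against the thinned NB
        tau = 1.0
        m_grid = np.arange(3000)
        pm = nb_pmf_vector(m_grid, fig9_params)
        q = math.exp(-tau)
        for s in range(0, 101, 10):
            brute = float(np.dot(stats.binom.pmf(s, m_grid, q), pm))
            assert surviving_marginal(s, fig9_params, tau) == pytest.approx(brute, abs=1e-10)


# ---------------------------------------------------------------------------
# new transcripts (approximate solution + instability)
# ---------------------------------------------------------------------------


class TestNewTranscripts:
    def test_n0_closed_form(self):
        for a, b, tau in [(2, 25, 1.0), (0.5, 50, 0.3), (1.7, 3.3, 5.0)]:
            p = make_params(a, b)
            val, flag = new_transcript_pmf(0, p, tau)
            closed = ((1 + b * math.exp(-tau)) / (1 + b)) ** a
            assert not flag.unstable
            assert val == pytest.approx(closed, rel=1e-12)

    def test_long_pulse_converges_to_steady_state(self, fig9_params):
        vec, flag = new_transcript_pmf_vector(fig9_params, 20.0, 200)
        assert not flag.unstable
        expected = nb_pmf_vector(np.arange(201), fig9_params)
        assert np.abs(vec - expected).max() < 1e-6

    def test_matches_mpmath(self, fig9_params):
        import mpmath

        tau = 1.0
        vec, flag = new_transcript_pmf_vector(fig9_params, tau, 60)
        assert not flag.unstable
        a, b = fig9_params.a, fig9_params.b
        z = (1 + b) / (math.exp(tau) + b)
        for n in (1, 7, 33, 60):
            pref = (
                mpmath.gamma(a + n) / (mpmath.gamma(n + 1) * mpmath.gamma(a))
                * (b / (1 + b)) ** n
                * ((1 + b * mpmath.exp(-tau)) / (1 + b)) ** a
            )
            exact = float(pref * mpmath.hyp2f1(-n, -a, 1 - a - n, z))
            assert vec[n] == pytest.approx(exact, rel=1e-9)

    def test_instability_found_by_scan(self):
        # large a and b with small tau must eventually go negative
        found = False
        for a, b, tau in [(10, 50, 0.01), (10, 100, 0.1), (20, 100, 0.05)]:
            p = make_params(a, b)
            M = min(fsp_bound(p).M, 1500)
            _, flag = new_transcript_pmf_vector(p, tau, M)
            if flag.unstable:
                found = True
                assert flag.first_negative_n is not None
        assert found

    def test_stable_points_sum_to_one(self, fig9_params, sim_params):
        for p in (fig9_params, sim_params):
            M = fsp_bound(p, 1 - 1e-8).M
            vec, flag = new_transcript_pmf_vector(p, 1.0, M)
            assert not flag.unstable
            assert (vec >= 0).all()
            assert vec.sum() == pytest.approx(1.0, abs=1e-4)

    def test_tau_zero_rejected(self, fig9_params):
        with pytest.raises(ValueError):
            new_transcript_pmf(0, fig9_params, 0.0)


class TestNewGivenTotal:
    def test_empty_cell(self, fig9_params):
        vec, flag = new_given_total(0, fig9_params, 1.0)
        assert not flag.unstable
        assert vec.tolist() == [1.0]

    def test_normalization(self, fig9_params):
        for m in (1, 10, 100):
            vec, flag = new_given_total(m, fig9_params, 1.0)
            assert not flag.unstable
            assert vec.sum() == pytest.approx(1.0, abs=1e-12)
            assert (vec >= 0).all()

    def test_convolution_approximates_steady_state(self, fig9_params):
        # the normalizer of P(n|m) should track P(m) at the distribution bulk
        from burstkit.distributions import new_fraction_weights

        M = fsp_bound(fig9_params).M
        _, Z, flag = new_fraction_weights(fig9_params, 1.0, M)
        assert not flag.unstable
        pm = nb_pmf_vector(np.arange(M + 1), fig9_params)
        bulk = pm > 0.05 * pm.max()
        rel = np.abs(Z[bulk] - pm[bulk]) / pm[bulk]
        assert rel.max() < 0.05

    def test_brute_force(self, fig9_params):
        m = 40
        tau = 1.0
        pn = np.array([new_transcript_pmf(n, fig9_params, tau)[0] for n in range(m + 1)])
        ps = np.array([surviving_marginal(m - n, fig9_params, tau) for n in range(m + 1)])
        expected = pn * ps / (pn * ps).sum()
        got, flag = new_given_total(m, fig9_params, tau)
        assert not flag.unstable
        assert np.abs(got - expected).max() < 1e-12


# ---------------------------------------------------------------------------
# conversion mixtures
# ---------------------------------------------------------------------------


class TestConversionsGivenM:
    def test_no_label_collapses(self, fig9_params, udist60):
        rates = ConversionRates(lambda_s=0.01, lambda_n=0.0, t=1000.0)
        bg = poisson_mixture(np.arange(5), 0.01, udist60)
        for m in (1, 5, 40):
            for i in range(5):
                val, flag = conversions_given_m(i, m, fig9_params, rates, udist60)
                assert not flag.unstable
                assert val == pytest.approx(bg[i], rel=1e-9)

    def test_no_conversion_sources(self, fig9_params, udist60):
        rates = ConversionRates(lambda_s=0.0, lambda_n=0.0, t=1000.0)
        val, _ = conversions_given_m(0, 10, fig9_params, rates, udist60)
        assert val == pytest.approx(1.0)
        val, _ = conversions_given_m(1, 10, fig9_params, rates, udist60)
        assert val == pytest.approx(0.0, abs=1e-12)

    def test_m_zero_is_background_only(self, fig9_params, rates1000, udist60):
        bg = poisson_mixture(np.arange(3), rates1000.lambda_s, udist60)
        for i in range(3):
            val, flag = conversions_given_m(i, 0, fig9_params, rates1000, udist60)
            assert not flag.unstable
            assert val == pytest.approx(bg[i], rel=1e-12)

    def test_normalization_fig9(self, fig9_params, rates1000, udist60):
        total = 0.0
        for i in range(80):
            val, flag = conversions_given_m(i, 30, fig9_params, rates1000, udist60)
            assert not flag.unstable
            total += val
        assert total == pytest.approx(1.0, abs=1e-8)

    def test_brute_force_triple_sum(self, fig9_params, rates1000):
        # literal evaluation of the double sum over n and u
        udist = UracilDistribution.from_poisson(8.0)
        m, i = 12, 1
        tau = fig9_params.tau(rates1000.t)
        pnm, _ = new_given_total(m, fig9_params, tau)
        expected = 0.0
        for n in range(m + 1):
            for u, pu in zip(udist.u, udist.p):
                lab = stats.poisson.pmf(i, u * (rates1000.lambda_n + rates1000.lambda_s))
                bg = stats.poisson.pmf(i, u * rates1000.lambda_s)
                expected += pu * ((n / m) * lab + (1 - n / m) * bg) * pnm[n]
        got, _ = conversions_given_m(i, m, fig9_params, rates1000, udist)
        assert got == pytest.approx(expected, rel=1e-10)


class TestConversionsGivenUmi:
    def test_no_label_collapses(self, fig9_params, udist60):
        rates = ConversionRates(lambda_s=0.01, lambda_n=0.0, t=1000.0)
        bg = poisson_mixture(np.arange(4), 0.01, udist60)
        for l, alpha in ((0, 0.1), (4, 0.2)):
            for i in range(4):
                val, flag = conversions_given_umi(i, l, alpha, fig9_params, rates, udist60)
                assert not flag.unstable
                assert val == pytest.approx(bg[i], rel=1e-9)

    def test_normalization(self, fig9_params, rates1000, udist60):
        total = sum(
            conversions_given_umi(i, 3, 0.1, fig9_params, rates1000, udist60)[0]
            for i in range(80)
        )
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_monte_carlo_oracle(self, fig9_params, rates1000):
        # generative chain: m ~ steady state, l ~ Poisson(m alpha) conditioned
        # on the observed value, n|m from the joint of new and surviving
        # counts, read labelled with probability n/m, i ~ Poisson(u * rate)
        udist = UracilDistribution.from_poisson(8.0)
        alpha, l_obs = 0.1, 2
        tau = fig9_params.tau(rates1000.t)
        rng = np.random.default_rng(123)
        n_draws = 400_000
        m = rng.negative_binomial(fig9_params.a, 1 / (1 + fig9_params.b), size=n_draws)
        l = rng.poisson(m * alpha)
        m_acc = m[l == l_obs]
        # P(n|m) lookup per unique m via the (tested) scalar pieces
        table = {}
        for mv in np.unique(m_acc):
            if mv == 0:
                table[mv] = np.array([1.0])
                continue
            pn, flag = new_transcript_pmf_vector(fig9_params, tau, int(mv))
            assert not flag.unstable
            ps = surviving_pmf_vector(np.arange(mv + 1), fig9_params, tau)
            joint = pn * ps[::-1]
            table[mv] = joint / joint.sum()
        n_samp = np.array([rng.choice(len(table[mv]), p=table[mv]) for mv in m_acc])
        frac = np.divide(n_samp, m_acc, out=np.zeros(len(m_acc)), where=m_acc > 0)
        labelled = rng.random(len(m_acc)) < frac
        u = udist.u[rng.choice(len(udist.u), p=udist.p, size=len(m_acc))]
        rate = np.where(labelled, rates1000.lambda_n + rates1000.lambda_s, rates1000.lambda_s)
        i_samp = rng.poisson(u * rate)
        for i in range(4):
            phat = np.mean(i_samp == i)
            se = math.sqrt(phat * (1 - phat) / len(i_samp))
            got, flag = conversions_given_umi(i, l_obs, alpha, fig9_params, rates1000, udist)
            assert not flag.unstable
            assert got == pytest.approx(phat, abs=3 * se + 1e-9)


class TestPooledConversion:
    def test_weights_sum_to_one(self, fig9_params):
        tau = fig9_params.tau(1000.0)
        e = math.exp(-tau)
        assert (1 - e) + e == pytest.approx(1.0)

    def test_no_label_collapses(self, fig9_params, udist60):
        rates = ConversionRates(lambda_s=0.01, lambda_n=0.0, t=1000.0)
        bg = poisson_mixture(np.arange(4), 0.01, udist60)
        for i in range(4):
            assert pooled_conversion_pmf(i, fig9_params, rates, udist60) == pytest.approx(
                bg[i], rel=1e-12
            )

    def test_long_pulse_fully_labelled(self, udist60, rates1000):
        p = BurstParams(mu=50, a=2, gamma=1.0)  # tau = 1000
        lab = poisson_mixture(np.arange(4), rates1000.lambda_n + rates1000.lambda_s, udist60)
        for i in range(4):
            assert pooled_conversion_pmf(i, p, rates1000, udist60) == pytest.approx(
                lab[i], rel=1e-12
            )

    def test_normalization(self, fig9_params, rates1000, udist60):
        total = sum(pooled_conversion_pmf(i, fig9_params, rates1000, udist60) for i in range(80))
        assert total == pytest.approx(1.0, abs=1e-8)


# ---------------------------------------------------------------------------
# property suite
# ---------------------------------------------------------------------------


@given(
    a=st.floats(0.2, 5.0),
    b=st.floats(1.0, 100.0),
    tau=st.floats(0.2, 5.0),
)
@settings(max_examples=25, deadline=None)
def test_stable_pmfs_are_proper(a, b, tau):
    p = make_params(a, b)
    M = fsp_bound(p).M
    vec, flag = new_transcript_pmf_vector(p, tau, M)
    if flag.unstable:
        return  # flagged points are excluded from the properness contract
    assert (vec >= 0).all()
    assert vec.sum() <= 1.0 + 1e-9
    surv = surviving_pmf_vector(np.arange(M + 1), p, tau)
    assert (surv >= 0).all()
    assert surv.sum() <= 1.0 + 1e-9


@given(u_hat=st.floats(1.0, 120.0))
@settings(max_examples=25, deadline=None)
def test_uracil_distribution_proper(u_hat):
    ud = UracilDistribution.from_poisson(u_hat)
    assert (ud.p >= 0).all()
    assert ud.p.sum() == pytest.approx(1.0, abs=1e-12)
    assert ud.u.size == np.unique(ud.u).size
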