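"""Core smoother correctness: oracle equivalence, limits, invariants."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bcpseq.bcmix import BcmixConfig
from bcpseq.model import (
    ModelParams,
    backward_filter,
    forward_filter,
    log_likelihood,
    posterior_means,
    segment_evidence,
)

from conftest import enumerate_posterior, make_track, oracle_log_marginal


class TestSegmentEvidence:
    def test_single_zero_block_geometric_marginal(self):
        # Poisson-Gamma(1,1) marginal at y=0 is 1/2
        sp = segment_evidence(ModelParams(1, 1, 0.5), np.array([0]), 0, 0)
        assert sp.shape == 1 and sp.rate == 2
        assert sp.log_marginal == pytest.approx(np.log(0.5), abs=1e-12)

    def test_two_block_segment_matches_numerical_integration(self):
        # independent oracle: integrate prod Poisson(y|lam) * Gamma(lam;1,1)
        from scipy.integrate import quad
        from scipy.stats import gamma as gamma_dist, poisson

        y = np.array([2, 2])
        val, _ = quad(
            lambda lam: poisson.pmf(2, lam) ** 2 * gamma_dist.pdf(lam, 1, scale=1),
            0, 60,
        )
        sp = segment_evidence(ModelParams(1, 1, 0.5), y, 0, 1)
        assert sp.shape == 5 and sp.rate == 3
        assert sp.log_marginal == pytest.approx(np.log(val), rel=1e-9)

    def test_length_one_segment_rate(self):
        sp = segment_evidence(ModelParams(2.5, 0.7, 0.1), np.array([3, 1, 4]), 1, 1)
        assert sp.rate == pytest.approx(0.7 + 1)
        assert sp.shape == pytest.approx(2.5 + 1)

    def test_out_of_range_raises(self):
        with pytest.raises(IndexError):
            segment_evidence(ModelParams(1, 1, 0.5), np.array([1, 2]), 1, 2)


@st.composite
def small_problem(draw):
    n = draw(st.integers(1, 8))
    y = draw(st.lists(st.integers(0, 10), min_size=n, max_size=n))
    alpha = draw(st.floats(0.3, 5.0))
    beta = draw(st.floats(0.3, 5.0))
    p = draw(st.floats(0.01, 0.9))
    return np.array(y), alpha, beta, p


class TestOracleEquivalence:
    """The recursion must agree with brute-force enumeration of all
    2^(n-1) change configurations on small tracks."""

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(small_problem())
    def test_posterior_means_and_likelihood(self, problem):
        y, alpha, beta, p = problem
        track = make_track(y)
        params = ModelParams(alpha, beta, p)
        oll, olam, _ = enumerate_posterior(y, alpha, beta, p)
        assert log_likelihood(track, params) == pytest.approx(oll, abs=1e-10)
        values = posterior_means(track, params).values
        np.testing.assert_allclose(values, olam, rtol=1e-8)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(small_problem())
    def test_forward_weights(self, problem):
        y, alpha, beta, p = problem
        track = make_track(y)
        fs = forward_filter(track, ModelParams(alpha, beta, p))
        _, _, oracle_fwd = enumerate_posterior(y, alpha, beta, p)
        for t in range(len(y)):
            got = fs.weights_at(t)
            want = oracle_fwd[t]
            assert set(got) == set(want)
            for i in want:
                assert got[i] == pytest.approx(want[i], abs=1e-10)

    def test_backward_is_reflected_forward(self):
        y = np.array([0, 3, 3, 0, 7])
        params = ModelParams(1.2, 0.8, 0.2)
        n = len(y)
        bwd = backward_filter(make_track(y), params)
        fwd_rev = forward_filter(make_track(y[::-1]), params)
        for t in range(n):
            got = bwd.weights_at(t)
            want = {n - 1 - i: w for i, w in fwd_rev.weights_at(n - 1 - t).items()}
            assert got.keys() == want.keys()
            for j in want:
                assert got[j] == pytest.approx(want[j], abs=1e-12)


class TestLimits:
    def test_p_to_one_every_block_its_own_segment(self):
        track = make_track([0, 4])
        values = posterior_means(track, ModelParams(1, 1, 1 - 1e-12)).values
        np.testing.assert_allclose(values, [0.5, 2.5], atol=1e-9)

    def test_p_to_zero_single_segment(self):
        track = make_track([2, 2, 2])
        values = posterior_means(track, ModelParams(1, 1, 1e-12)).values
        np.testing.assert_allclose(values, [1.75, 1.75, 1.75], atol=1e-9)

    def test_constant_track_tiny_p_puts_weight_on_first_index(self):
        track = make_track([3] * 6)
        fs = forward_filter(track, ModelParams(2, 1, 1e-12))
        for t in range(6):
            assert fs.weights_at(t).get(0, 0.0) == pytest.approx(1.0, abs=1e-6)

    def test_single_block(self):
        track = make_track([0])
        params = ModelParams(1, 1, 0.3)
        assert log_likelihood(track, params) == pytest.approx(np.log(0.5), abs=1e-12)
        fs = forward_filter(track, params)
        assert fs.weights_at(0) == pytest.approx({0: 1.0})


class TestInvariants:
    def test_weights_normalised_each_step(self):
        rng = np.random.default_rng(42)
        y = rng.poisson(3, 60)
        fs = forward_filter(make_track(y), ModelParams(2, 1, 0.05))
        for t in range(60):
            assert sum(fs.weights_at(t).values()) == pytest.approx(1.0, abs=1e-12)
            assert all(i <= t for i in fs.weights_at(t))

    def test_likelihood_invariant_under_reversal(self):
        rng = np.random.default_rng(3)
        y = rng.poisson(2, 40)
        params = ModelParams(1.5, 0.9, 0.07)
        ll = log_likelihood(make_track(y), params)
        ll_rev = log_likelihood(make_track(y[::-1]), params)
        assert ll == pytest.approx(ll_rev, abs=1e-9)

    def test_posterior_mean_in_convex_hull_of_segment_means(self):
        rng = np.random.default_rng(8)
        y = rng.poisson(4, 30)
        params = ModelParams(2, 1, 0.1)
        values = posterior_means(make_track(y), params).values
        # hull bounds over all segments containing t
        S = np.concatenate([[0], np.cumsum(y)])
        for t in range(30):
            means = [
                (2 + S[j + 1] - S[i]) / (1 + j - i + 1)
                for i in range(t + 1)
                for j in range(t, 30)
            ]
            assert min(means) - 1e-9 <= values[t] <= max(means) + 1e-9

    def test_adding_constant_increases_every_posterior_mean(self):
        rng = np.random.default_rng(5)
        y = rng.poisson(2, 50)
        params = ModelParams(2, 1, 0.05)
        base = posterior_means(make_track(y), params).values
        up = posterior_means(make_track(y + 3), params).values
        assert np.all(up > base)

    def test_posterior_means_strictly_positive(self):
        values = posterior_means(make_track([0] * 40), ModelParams(2, 1, 0.01)).values
        assert np.all(values > 0)


class TestParamValidation:
    @pytest.mark.parametrize(
        "alpha,beta,p", [(0, 1, 0.5), (1, 0, 0.5), (1, 1, 0.0), (1, 1, 1.0), (-2, 1, 0.5)]
    )
    def test_invalid_params_rejected(self, alpha, beta, p):
        with pytest.raises(ValueError):
            ModelParams(alpha, beta, p)
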