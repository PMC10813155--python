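"""Inference against closed forms and the path-enumeration oracle."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from swayhmm import (
    DiscreteHMMParams,
    GaussianHMM,
    GaussianMixtureEmission,
    MarkovChainParams,
    brute_force_log_likelihood,
    forward_backward,
    forward_log_likelihood,
    log_emission_matrix,
    sample_sequence,
    viterbi,
)
from swayhmm.errors import (
    DimensionMismatchError,
    ModelValidityError,
    SequenceError,
)
from swayhmm.hmm import enumerate_path_posteriors

from conftest import as_sequence, random_gaussian_hmm, standard_normal_hmm

LOG_STD_NORMAL_AT_0 = -0.5 * math.log(2 * math.pi)


class TestTypes:
    def test_non_stochastic_transition_matrix_rejected(self):
        with pytest.raises(ModelValidityError):
            MarkovChainParams(K=2, A=np.array([[0.5, 0.6], [0.5, 0.5]]),
                              pi=np.array([0.5, 0.5]))

    def test_non_simplex_pi_rejected(self):
        with pytest.raises(ModelValidityError):
            MarkovChainParams(K=2, A=np.eye(2), pi=np.array([0.7, 0.7]))

    def test_higher_order_chain_representable_but_not_inferable(self):
        chain = MarkovChainParams(K=1, A=np.ones((1, 1)), pi=np.ones(1), order=2)
        model = GaussianHMM(chain=chain, d=1, emissions=[
            GaussianMixtureEmission(np.ones(1), np.zeros((1, 1)), np.eye(1)[None])
        ])
        with pytest.raises(ModelValidityError, match="order"):
            forward_log_likelihood(model, as_sequence([0.0]))

    def test_emission_weight_simplex_enforced(self):
        with pytest.raises(ModelValidityError):
            GaussianMixtureEmission(
                weights=np.array([0.6, 0.6]),
                means=np.zeros((2, 1)),
                covariances=np.stack([np.eye(1)] * 2),
            )

    def test_sequence_rejects_nan(self):
        with pytest.raises(SequenceError):
            as_sequence([0.0, np.nan])


class TestLogEmissionMatrix:
    def test_standard_normal_at_mode(self):
        model = standard_normal_hmm()
        out = log_emission_matrix(model, as_sequence([0.0]))
        assert out.shape == (1, 1)
        assert out[0, 0] == pytest.approx(LOG_STD_NORMAL_AT_0, abs=1e-12)

    def test_duplicate_components_collapse_to_single(self):
        single = standard_normal_hmm()
        dup = GaussianHMM(
            chain=single.chain,
            d=1,
            emissions=[
                GaussianMixtureEmission(
                    weights=np.array([0.5, 0.5]),
                    means=np.zeros((2, 1)),
                    covariances=np.stack([np.eye(1)] * 2),
                )
            ],
        )
        x = as_sequence([-1.3, 0.0, 2.1])
        np.testing.assert_allclose(
            log_emission_matrix(dup, x), log_emission_matrix(single, x),
            rtol=0, atol=1e-12,
        )

    def test_matches_termwise_mixture_summation(self, rng):
        model = random_gaussian_hmm(rng, K=2, d=2, C=2)
        X = rng.normal(size=(6, 2))
        got = log_emission_matrix(model, as_sequence(X))
        for i in range(6):
            for k, em in enumerate(model.emissions):
                total = 0.0
                for j in range(em.n_components):
                    S = em.covariances[j]
                    dev = X[i] - em.means[j]
                    dens = math.exp(-0.5 * dev @ np.linalg.inv(S) @ dev) / (
                        2 * math.pi * math.sqrt(np.linalg.det(S))
                    )
                    total += em.weights[j] * dens
                assert got[i, k] == pytest.approx(math.log(total), rel=1e-12)

    def test_dimension_mismatch_names_both_dimensions(self, rng):
        model = random_gaussian_hmm(rng, d=2)
        with pytest.raises(DimensionMismatchError, match="1.*2|2.*1"):
            log_emission_matrix(model, as_sequence([0.0, 1.0]))

    def test_non_positive_definite_covariance_rejected(self):
        em = GaussianMixtureEmission(
            weights=np.ones(1), means=np.zeros((1, 2)),
            covariances=np.array([[[1.0, 2.0], [2.0, 1.0]]]),  # eigenvalues -1, 3
        )
        model = GaussianHMM(
            chain=MarkovChainParams(K=1, A=np.ones((1, 1)), pi=np.ones(1)),
            d=2, emissions=[em],
        )
        with pytest.raises(ModelValidityError, match="positive definite"):
            log_emission_matrix(model, as_sequence(np.zeros((3, 2))))


class TestForwardLikelihood:
    def test_single_state_iid_closed_form(self):
        model = standard_normal_hmm()
        ll = forward_log_likelihood(model, as_sequence([0.0, 0.0]))
        assert ll == pytest.approx(2 * LOG_STD_NORMAL_AT_0, abs=1e-12)

    def test_identical_emissions_make_transitions_irrelevant(self, rng):
        # all states share one emission -> likelihood is the i.i.d. one
        x = as_sequence(rng.normal(size=5))
        iid = forward_log_likelihood(standard_normal_hmm(K=1), x)
        for _ in range(20):
            K = int(rng.integers(2, 4))
            model = standard_normal_hmm(K=K)
            model.chain.A = rng.dirichlet(np.ones(K), size=K)
            model.chain.pi = rng.dirichlet(np.ones(K))
            assert forward_log_likelihood(model, x) == pytest.approx(iid, rel=1e-10)

    def test_agrees_with_path_enumeration(self, rng):
        for _ in range(50):
            K = int(rng.integers(1, 4))
            n = int(rng.integers(1, 9))
            d = int(rng.integers(1, 3))
            model = random_gaussian_hmm(rng, K=K, d=d, C=int(rng.integers(1, 3)))
            seq, _ = sample_sequence(model, n, rng)
            ll = forward_log_likelihood(model, seq)
            bf = brute_force_log_likelihood(model, seq)
            assert ll == pytest.approx(bf, rel=1e-8)

    def test_scaled_and_log_space_paths_agree(self, rng):
        for _ in range(10):
            model = random_gaussian_hmm(rng, K=3, d=1, C=2)
            seq, _ = sample_sequence(model, 40, rng)
            a = forward_log_likelihood(model, seq, method="scaled")
            b = forward_log_likelihood(model, seq, method="log")
            assert a == pytest.approx(b, abs=1e-10)

    def test_minute_long_sequence_does_not_underflow(self, rng):
        model = random_gaussian_hmm(rng, K=3, d=2, C=2)
        seq, _ = sample_sequence(model, 60_000, 7)
        assert np.isfinite(forward_log_likelihood(model, seq))

    def test_discrete_hmm_likelihood_matches_enumeration(self, rng):
        chain = MarkovChainParams(
            K=2, A=rng.dirichlet(np.ones(2), size=2), pi=rng.dirichlet(np.ones(2))
        )
        model = DiscreteHMMParams(chain=chain, M=3,
                                  B=rng.dirichlet(np.ones(3), size=2))
        obs = rng.integers(0, 3, size=6)
        assert forward_log_likelihood(model, obs) == pytest.approx(
            brute_force_log_likelihood(model, obs), rel=1e-10
        )

    def test_empty_and_nan_sequences_rejected(self, rng):
        model = random_gaussian_hmm(rng)
        with pytest.raises((SequenceError, Exception)):
            forward_log_likelihood(model, np.empty((0, 1)))
        with pytest.raises(SequenceError):
            forward_log_likelihood(model, np.array([[np.nan]]))


class TestForwardBackward:
    def test_single_state_gamma_all_ones(self, rng):
        model = standard_normal_hmm(K=1)
        post = forward_backward(model, as_sequence(rng.normal(size=10)))
        np.testing.assert_allclose(post.gamma, 1.0)

    def test_symmetric_two_state_gamma_half(self, rng):
        post = forward_backward(
            standard_normal_hmm(K=2), as_sequence(rng.normal(size=8))
        )
        np.testing.assert_allclose(post.gamma, 0.5, atol=1e-12)

    def test_gamma_matches_enumeration_oracle(self, rng):
        for _ in range(25):
            K = int(rng.integers(1, 4))
            n = int(rng.integers(2, 8))
            model = random_gaussian_hmm(rng, K=K, d=1, C=1)
            seq, _ = sample_sequence(model, n, rng)
            post = forward_backward(model, seq)
            gamma_exact, ll_exact, _, _ = enumerate_path_posteriors(model, seq)
            np.testing.assert_allclose(post.gamma, gamma_exact, atol=1e-8)
            assert post.loglik == pytest.approx(ll_exact, rel=1e-8)

    def test_invariants_hold_on_random_instances(self, rng):
        for _ in range(10):
            model = random_gaussian_hmm(rng, K=3, d=2, C=2)
            seq, _ = sample_sequence(model, 50, rng)
            post = forward_backward(model, seq)
            post.validate()
            assert post.loglik == pytest.approx(
                forward_log_likelihood(model, seq), abs=1e-10
            )


class TestViterbi:
    def test_single_state_path(self, rng):
        model = standard_normal_hmm(K=1)
        path, _ = viterbi(model, as_sequence(rng.normal(size=5)))
        assert np.all(path == 0)

    def test_absorbing_start_forces_path(self, rng):
        model = random_gaussian_hmm(rng, K=2, d=1)
        model.chain.pi = np.array([1.0, 0.0])
        model.chain.A = np.eye(2)
        path, _ = viterbi(model, as_sequence(rng.normal(size=6)))
        assert np.all(path == 0)

    def test_optimal_and_tie_consistent_with_enumeration(self, rng):
        for _ in range(50):
            K = int(rng.integers(1, 3))
            n = int(rng.integers(1, 7))
            model = random_gaussian_hmm(rng, K=K, d=1, C=1)
            seq, _ = sample_sequence(model, n, rng)
            path, logjoint = viterbi(model, seq)
            _, ll, best_path, best_joint = enumerate_path_posteriors(model, seq)
            assert logjoint == pytest.approx(best_joint, rel=1e-8)
            assert tuple(path) == best_path  # lower-index tie-break = lexicographic
            assert logjoint <= ll + 1e-9

    def test_exact_tie_broken_toward_lower_index(self, rng):
        # two identical states: every path has equal joint probability
        model = standard_normal_hmm(K=2)
        path, logjoint = viterbi(model, as_sequence([0.3, -0.2, 0.5]))
        assert np.all(path == 0)
        _, _, best_path, best_joint = enumerate_path_posteriors(
            model, as_sequence([0.3, -0.2, 0.5])
        )
        assert logjoint == pytest.approx(best_joint, rel=1e-12)


class TestSampling:
    def test_same_seed_reproduces_sequence_and_path(self, rng):
        model = random_gaussian_hmm(rng, K=3, d=2, C=2)
        s1, p1 = sample_sequence(model, 100, 42)
        s2, p2 = sample_sequence(model, 100, 42)
        np.testing.assert_array_equal(s1.values, s2.values)
        np.testing.assert_array_equal(p1, p2)

    def test_law_of_large_numbers_single_state(self):
        seq, _ = sample_sequence(standard_normal_hmm(), 10_000, 0)
        assert abs(seq.values.mean()) < 4 / math.sqrt(10_000)

    def test_occupancy_matches_stationary_distribution(self, rng):
        model = random_gaussian_hmm(rng, K=3, d=1)
        # fast-mixing chain so the 0.02 occupancy tolerance is meaningful
        model.chain.A = np.array(
            [[0.8, 0.15, 0.05], [0.1, 0.8, 0.1], [0.05, 0.15, 0.8]]
        )
        _, states = sample_sequence(model, 50_000, 3)
        occ = np.bincount(states, minlength=3) / len(states)
        target = model.chain.stationary_distribution()
        np.testing.assert_allclose(occ, target, atol=0.02)

    def test_invalid_length_rejected(self, rng):
        with pytest.raises(SequenceError):
            sample_sequence(random_gaussian_hmm(rng), 0, 0)


class TestBruteForce:
    def test_single_observation_closed_form(self, rng):
        model = random_gaussian_hmm(rng, K=3, d=1)
        x = as_sequence([0.7])
        logb = log_emission_matrix(model, x)
        expected = np.log(np.sum(model.chain.pi * np.exp(logb[0])))
        assert brute_force_log_likelihood(model, x) == pytest.approx(expected, rel=1e-12)

    def test_enumeration_guard(self, rng):
        model = random_gaussian_hmm(rng, K=3, d=1)
        seq, _ = sample_sequence(model, 20, 0)
        with pytest.raises(ValueError, match="smaller"):
            brute_force_log_likelihood(model, seq)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    seed=st.integers(0, 10_000),
    K=st.integers(1, 3),
    n=st.integers(1, 6),
)
def test_property_joint_never_exceeds_total_likelihood(seed, K, n):
    rng = np.random.default_rng(seed)
    model = random_gaussian_hmm(rng, K=K, d=1, C=1)
    seq, _ = sample_sequence(model, n, seed)
    _, logjoint = viterbi(model, seq)
    assert logjoint <= forward_log_likelihood(model, seq) + 1e-9


@settings(max_examples=25, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000), n=st.integers(2, 30))
def test_property_posterior_normalization(seed, n):
    rng = np.random.default_rng(seed)
    model = random_gaussian_hmm(rng, K=3, d=2, C=2)
    seq, _ = sample_sequence(model, n, seed)
    forward_backward(model, seq).validate()
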