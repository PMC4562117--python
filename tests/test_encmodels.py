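"""Per-stimulus encoding models: moments, maxent fits, enumeration, sampling."""

import itertools

import numpy as np
import pytest

from neurothesaurus.encmodels import (CondIndepModel, PairwiseMaxEntModel,
                                      empirical_moments, enumerate_distribution,
                                      fit_cond_independent, fit_pairwise_maxent,
                                      log_likelihood_matrix,
                                      log_likelihood_ratio,
                                      pattern_log_probability, sample_patterns,
                                      smoothed_moments,
                                      spike_count_distribution)
from neurothesaurus.infotools import plugin_entropy


def brute_force_pairwise(alpha, beta):
    """Independent enumeration oracle: probabilities by direct energy sums."""
    n = len(alpha)
    pairs = list(itertools.combinations(range(n), 2))
    probs = []
    for bits in itertools.product([0, 1], repeat=n):
        bits = bits[::-1]  # match bit-i-of-index convention
        e = sum(alpha[i] * bits[i] for i in range(n))
        e += sum(beta[k] * bits[i] * bits[j] for k, (i, j) in enumerate(pairs))
        probs.append(np.exp(e))
    probs = np.array(probs)
    return probs / probs.sum()


class TestMoments:
    def test_two_pattern_sample(self):
        first, second = empirical_moments(np.array([[0, 0], [1, 1]]))
        np.testing.assert_allclose(first, [0.5, 0.5])
        np.testing.assert_allclose(second, [0.5])

    def test_single_sample(self):
        first, second = empirical_moments(np.array([[1, 0]]))
        np.testing.assert_allclose(first, [1, 0])
        np.testing.assert_allclose(second, [0])

    def test_random_sample_matches_counting_oracle(self, rng):
        pats = (rng.random((100, 4)) < 0.4).astype(int)
        first, second = empirical_moments(pats)
        np.testing.assert_allclose(first, pats.mean(axis=0))
        k = 0
        for i in range(4):
            for j in range(i + 1, 4):
                assert second[k] == pytest.approx(
                    np.mean(pats[:, i] * pats[:, j]))
                k += 1

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            empirical_moments(np.empty((0, 3)))

    def test_smoothed_moments_formula(self):
        pats = np.zeros((100, 2), dtype=int)  # silent neurons
        first, second = smoothed_moments(pats, 0.5)
        np.testing.assert_allclose(first, 0.5 / 101)
        np.testing.assert_allclose(second, 0.5 / 101)


class TestCondIndependent:
    def test_silent_neuron_pseudocount(self):
        pats = np.zeros((100, 1), dtype=int)
        model = fit_cond_independent([pats], pseudocount=0.5)
        assert model.rates[0, 0] == pytest.approx(0.5 / 101)

    def test_zero_pseudocount_rejected(self):
        pats = np.ones((10, 1), dtype=int)
        with pytest.raises(ValueError):
            fit_cond_independent([pats], pseudocount=0.0)

    def test_rate_recovery_within_binomial_error(self, rng):
        true_p = 0.3
        n = 2000
        pats = (rng.random((n, 1)) < true_p).astype(int)
        model = fit_cond_independent([pats])
        se = np.sqrt(true_p * (1 - true_p) / n)
        assert abs(model.rates[0, 0] - true_p) < 4 * se


class TestPairwiseFit:
    def test_balanced_sample_gives_zero_parameters(self):
        # all four 2-neuron patterns equally often: moments (.5,.5,.25)
        pats = np.array([[0, 0], [0, 1], [1, 0], [1, 1]] * 5)
        model = fit_pairwise_maxent([pats], pseudocount=0.0, tol=1e-8)
        np.testing.assert_allclose(model.alpha, 0, atol=1e-5)
        np.testing.assert_allclose(model.beta, 0, atol=1e-5)

    def test_two_neuron_closed_form(self, rng):
        """For N=2 the smoothed moments determine the joint exactly."""
        pats = (rng.random((300, 2)) < [0.4, 0.3]).astype(int)
        model = fit_pairwise_maxent([pats], tol=1e-8)
        m1, m2 = smoothed_moments(pats, 0.5)
        p11 = m2[0]
        p10 = m1[0] - p11
        p01 = m1[1] - p11
        p00 = 1 - m1[0] - m1[1] + p11
        dist = enumerate_distribution(model, 0)
        # support order: 00, 10, 01, 11 (bit i of index = neuron i)
        np.testing.assert_allclose(dist.probs, [p00, p10, p01, p11], atol=1e-6)

    def test_moment_matching_at_convergence(self, rng):
        pats = (rng.random((400, 4)) < [0.2, 0.5, 0.3, 0.6]).astype(int)
        tol = 1e-6
        model = fit_pairwise_maxent([pats], tol=tol)
        first, second = smoothed_moments(pats, 0.5)
        dist = enumerate_distribution(model, 0)
        # model moments = probability-weighted means over support
        mfirst = dist.probs @ dist.support
        iu, ju = np.triu_indices(4, 1)
        msecond = dist.probs @ (dist.support[:, iu] * dist.support[:, ju])
        assert np.max(np.abs(mfirst - first)) < 1e-4
        assert np.max(np.abs(msecond - second)) < 1e-4
        assert model.converged.all()

    def test_generative_parameter_recovery_improves_with_samples(self):
        rng = np.random.default_rng(11)
        n_neurons = 5
        alpha_true = rng.normal(-1.0, 0.7, n_neurons)
        beta_true = rng.normal(0.0, 0.5, n_neurons * 4 // 2)
        gen = PairwiseMaxEntModel(alpha_true[None], beta_true[None],
                                  np.array([0.0]))
        # logZ consistency is irrelevant for sampling via enumeration
        rmses = []
        for n_samp in (500, 8000):
            pats = sample_patterns(gen, 0, n_samp, seed=5)
            fit = fit_pairwise_maxent([pats], tol=1e-6)
            err = np.concatenate([fit.alpha[0] - alpha_true,
                                  fit.beta[0] - beta_true])
            rmses.append(np.sqrt(np.mean(err ** 2)))
        assert rmses[1] < rmses[0]

    def test_exact_cap_enforced(self, rng):
        pats = (rng.random((20, 5)) < 0.3).astype(int)
        with pytest.raises(ValueError, match="cap"):
            fit_pairwise_maxent([pats], exact_cap=4)

    def test_entropy_ordering_maxent_hierarchy(self, rng):
        """H[independent fit] >= H[pairwise fit] >= H[smoothed empirical]."""
        for trial in range(3):
            pats = (rng.random((150, 4)) < rng.uniform(0.15, 0.7, 4)).astype(int)
            # inject correlation
            pats[:, 1] = np.where(rng.random(150) < 0.7, pats[:, 0], pats[:, 1])
            pc = 0.5
            ind = fit_cond_independent([pats], pseudocount=pc)
            pair = fit_pairwise_maxent([pats], pseudocount=pc, tol=1e-7)
            h_ind = plugin_entropy(enumerate_distribution(ind, 0).probs)
            h_pair = plugin_entropy(enumerate_distribution(pair, 0).probs)
            # smoothed empirical distribution: data mixed with pc
            # pseudo-observations of the all-ones and all-zeros words
            uniq, counts = np.unique(pats, axis=0, return_counts=True)
            table = {tuple(u): c for u, c in zip(uniq.tolist(), counts)}
            for corner in [(0, 0, 0, 0), (1, 1, 1, 1)]:
                table[corner] = table.get(corner, 0) + pc
            probs = np.array(list(table.values()), dtype=float)
            h_emp = plugin_entropy(probs / probs.sum())
            assert h_ind >= h_pair - 1e-6
            assert h_pair >= h_emp - 1e-4


class TestEnumeration:
    def test_single_neuron(self):
        model = CondIndepModel(np.array([[0.3]]), 0.5)
        dist = enumerate_distribution(model, 0)
        np.testing.assert_allclose(dist.probs, [0.7, 0.3])

    def test_zero_energy_is_uniform(self):
        model = PairwiseMaxEntModel(np.zeros((1, 3)), np.zeros((1, 3)),
                                    np.array([3 * np.log(2)]))
        dist = enumerate_distribution(model, 0)
        np.testing.assert_allclose(dist.probs, 1 / 8)

    def test_matches_brute_force_oracle(self, rng):
        alpha = rng.normal(0, 1, 3)
        beta = rng.normal(0, 0.8, 3)
        from scipy.special import logsumexp

        from neurothesaurus.encmodels import _log_weights
        logz = logsumexp(_log_weights(alpha, beta))
        model = PairwiseMaxEntModel(alpha[None], beta[None], np.array([logz]))
        dist = enumerate_distribution(model, 0)
        np.testing.assert_allclose(dist.probs, brute_force_pairwise(alpha, beta),
                                   atol=1e-12)

    def test_normalization_invariant(self, rng):
        for _ in range(5):
            alpha = rng.normal(0, 2, 4)
            beta = rng.normal(0, 1, 6)
            from scipy.special import logsumexp

            from neurothesaurus.encmodels import _log_weights
            logz = logsumexp(_log_weights(alpha, beta))
            model = PairwiseMaxEntModel(alpha[None], beta[None],
                                        np.array([logz]))
            assert abs(enumerate_distribution(model, 0).probs.sum() - 1) < 1e-10


class TestLogProbability:
    def test_matches_enumeration(self, rng):
        pats = (rng.random((50, 4)) < 0.4).astype(int)
        model = fit_pairwise_maxent([pats], tol=1e-6)
        dist = enumerate_distribution(model, 0)
        for idx in [0, 3, 9, 15]:
            lp = pattern_log_probability(model, 0, dist.support[idx])
            assert lp == pytest.approx(np.log2(dist.probs[idx]), abs=1e-8)

    def test_cond_indep_all_zeros_closed_form(self):
        rates = np.array([[0.2, 0.4, 0.1]])
        model = CondIndepModel(rates, 0.5)
        expected = np.log2(1 - rates[0]).sum()
        assert pattern_log_probability(model, 0, [0, 0, 0]) == \
            pytest.approx(expected)

    def test_probabilities_sum_to_one(self, rng):
        pats = (rng.random((60, 3)) < 0.5).astype(int)
        model = fit_pairwise_maxent([pats])
        states = enumerate_distribution(model, 0).support
        ll = log_likelihood_matrix(model, states)[:, 0]
        assert 2.0 ** ll.sum() != 0  # finite
        assert np.sum(2.0 ** ll) == pytest.approx(1.0, abs=1e-8)

    def test_unknown_stimulus_rejected(self, rng):
        pats = (rng.random((30, 2)) < 0.5).astype(int)
        model = fit_pairwise_maxent([pats])
        with pytest.raises(IndexError):
            pattern_log_probability(model, 5, [0, 1])


class TestLikelihoodRatio:
    def test_identical_models_zero(self, rng):
        pats = (rng.random((40, 3)) < 0.4).astype(int)
        model = fit_pairwise_maxent([pats])
        out = log_likelihood_ratio(model, model, [pats])
        np.testing.assert_allclose(out, 0, atol=1e-12)

    def test_coupled_data_favors_pairwise(self, rng):
        # strongly synchronized pair of neurons
        base = (rng.random(500) < 0.4).astype(int)
        pats = np.column_stack([base, base, (rng.random(500) < 0.3).astype(int)])
        train, test = pats[:250], pats[250:]
        pair = fit_pairwise_maxent([train])
        ind = fit_cond_independent([train])
        ratio = log_likelihood_ratio(pair, ind, [test])
        assert ratio[0] > 10  # log2 units over 250 held-out samples

    def test_single_sample_additivity(self, rng):
        pats = (rng.random((30, 2)) < 0.5).astype(int)
        pair = fit_pairwise_maxent([pats])
        ind = fit_cond_independent([pats])
        one = pats[:1]
        out = log_likelihood_ratio(pair, ind, [one])
        expected = (pattern_log_probability(pair, 0, one[0]) -
                    pattern_log_probability(ind, 0, one[0]))
        assert out[0] == pytest.approx(expected)

    def test_mismatched_neuron_sets_rejected(self, rng):
        a = fit_cond_independent([(rng.random((10, 2)) < 0.5).astype(int)])
        b = fit_cond_independent([(rng.random((10, 3)) < 0.5).astype(int)])
        with pytest.raises(ValueError):
            log_likelihood_ratio(a, b, [np.zeros((5, 2), dtype=int)])


class TestSampling:
    def test_zero_samples(self):
        model = CondIndepModel(np.array([[0.3, 0.6]]), 0.5)
        assert sample_patterns(model, 0, 0, seed=0).shape == (0, 2)

    def test_seed_determinism(self):
        model = CondIndepModel(np.array([[0.3, 0.6]]), 0.5)
        a = sample_patterns(model, 0, 50, seed=9)
        b = sample_patterns(model, 0, 50, seed=9)
        np.testing.assert_array_equal(a, b)

    def test_frequencies_approach_probabilities(self):
        model = CondIndepModel(np.array([[0.2, 0.5, 0.7]]), 0.5)
        dist = enumerate_distribution(model, 0)
        pats = sample_patterns(model, 0, 100_000, seed=1)
        idx = pats @ (1 << np.arange(3))
        freqs = np.bincount(idx, minlength=8) / len(pats)
        np.testing.assert_allclose(freqs, dist.probs, atol=0.01)


class TestSpikeCounts:
    def test_uniform_two_neurons_binomial(self):
        model = PairwiseMaxEntModel(np.zeros((1, 2)), np.zeros((1, 1)),
                                    np.array([2 * np.log(2)]))
        dist = enumerate_distribution(model, 0)
        np.testing.assert_allclose(spike_count_distribution(dist),
                                   [0.25, 0.5, 0.25])

    def test_delta_on_all_ones(self):
        pats = np.ones((10, 4), dtype=int)
        out = spike_count_distribution(pats)
        np.testing.assert_allclose(out, [0, 0, 0, 0, 1])

    def test_matches_enumeration_grouping(self, rng):
        pats = (rng.random((80, 5)) < 0.4).astype(int)
        model = fit_pairwise_maxent([pats])
        dist = enumerate_distribution(model, 0)
        out = spike_count_distribution(dist)
        expected = np.zeros(6)
        for p, s in zip(dist.probs, dist.support.sum(axis=1)):
            expected[s] += p
        np.testing.assert_allclose(out, expected, atol=1e-12)


class TestSerialization:
    def test_npz_round_trip(self, tmp_path, rng):
        pats = (rng.random((50, 3)) < 0.4).astype(int)
        model = fit_pairwise_maxent([pats, pats[::-1]])
        path = tmp_path / "m.npz"
        model.to_npz(path)
        back = PairwiseMaxEntModel.from_npz(path)
        np.testing.assert_array_equal(model.alpha, back.alpha)
        np.testing.assert_array_equal(model.beta, back.beta)
        np.testing.assert_array_equal(model.logZ, back.logZ)
        assert back.pseudocount == model.pseudocount
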