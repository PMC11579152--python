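import numpy as np
import pytest
from scipy.stats import norm

from thetanav.errors import FitError, ValidationError
from thetanav.hmm import (
    GaussianHMM, GaussianHMMParams, aic_profile, forward_loglik,
    posterior_occupancy, state_frequencies, viterbi_decode,
)

from conftest import enumerate_best_path, enumerate_loglik, random_hmm_params


@pytest.fixture(scope="module")
def two_state_params():
    return GaussianHMMParams(
        means=[-2.0, 2.0], variances=[1.0, 1.0],
        transition=[[0.9, 0.1], [0.1, 0.9]], initial=[0.5, 0.5],
    )


class TestParams:
    def test_rejects_non_stochastic_transition(self):
        with pytest.raises(ValidationError):
            GaussianHMMParams([0, 1], [1, 1], [[0.5, 0.4], [0.1, 0.9]],
                              [0.5, 0.5])

    def test_rejects_non_positive_variance(self):
        with pytest.raises(ValidationError):
            GaussianHMMParams([0, 1], [1, 0], [[0.5, 0.5], [0.1, 0.9]],
                              [0.5, 0.5])

    def test_free_parameter_count(self):
        p = random_hmm_params(np.random.default_rng(0), 4)
        assert p.n_free_params == 4 * 4 + 2 * 4 - 1  # 23

    def test_canonical_order_is_ascending_mean(self, rng):
        p = random_hmm_params(rng, 3)
        canon, order = p.canonical()
        assert np.all(np.diff(canon.means) >= 0)
        # permuting then canonicalising returns the same params
        perm = rng.permutation(3)
        canon2, _ = p.reordered(perm).canonical()
        np.testing.assert_allclose(canon2.means, canon.means)
        np.testing.assert_allclose(canon2.transition, canon.transition)


class TestForward:
    def test_single_state_equals_sum_of_gaussian_logpdfs(self, rng):
        x = rng.normal(1.0, 2.0, size=50)
        p = GaussianHMMParams([1.0], [4.0], [[1.0]], [1.0])
        expected = norm.logpdf(x, 1.0, 2.0).sum()
        assert forward_loglik(p, x) == pytest.approx(expected, abs=1e-10)

    def test_length_one_closed_form(self, two_state_params):
        p = two_state_params
        x1 = 0.7
        expected = np.log(
            0.5 * norm.pdf(x1, -2, 1) + 0.5 * norm.pdf(x1, 2, 1))
        assert forward_loglik(p, [x1]) == pytest.approx(expected, abs=1e-12)

    def test_matches_exhaustive_enumeration(self, rng):
        for _ in range(10):
            M = int(rng.integers(2, 4))
            T = int(rng.integers(2, 9))
            p = random_hmm_params(rng, M)
            x = rng.normal(0, 2, size=T)
            assert forward_loglik(p, x) == pytest.approx(
                enumerate_loglik(p, x), abs=1e-8)


class TestViterbi:
    def test_single_state_constant_path(self, rng):
        p = GaussianHMMParams([0.0], [1.0], [[1.0]], [1.0])
        path = viterbi_decode(p, rng.normal(size=20))
        assert np.all(path == 0)

    def test_matches_exhaustive_argmax(self, rng):
        for _ in range(5):
            M = int(rng.integers(2, 4))
            T = int(rng.integers(3, 8))
            p = random_hmm_params(rng, M)
            x = rng.normal(0, 2, size=T)
            path = viterbi_decode(p, x)
            best_path, best_lp = enumerate_best_path(p, x)
            # joint probability of the decoded path must equal the optimum
            lp = np.log(p.initial[path[0]]) + norm.logpdf(
                x[0], p.means[path[0]], np.sqrt(p.variances[path[0]]))
            for t in range(1, T):
                lp += np.log(p.transition[path[t - 1], path[t]]) + \
                    norm.logpdf(x[t], p.means[path[t]],
                                np.sqrt(p.variances[path[t]]))
            assert lp == pytest.approx(best_lp, abs=1e-8)

    def test_well_separated_means_threshold_classification(self,
                                                           two_state_params):
        x = np.array([-2.1, -1.9, 2.2, 1.8, -2.0, 2.0])
        path = viterbi_decode(two_state_params, x)
        np.testing.assert_array_equal(path, (x > 0).astype(int))

    def test_viterbi_beats_posterior_argmax(self, rng):
        for _ in range(5):
            p = random_hmm_params(rng, 3)
            x = rng.normal(0, 2, size=30)
            vpath = viterbi_decode(p, x)
            gpath = posterior_occupancy(p, x).argmax(axis=1)

            def joint_lp(path):
                lp = np.log(p.initial[path[0]]) + norm.logpdf(
                    x[0], p.means[path[0]], np.sqrt(p.variances[path[0]]))
                for t in range(1, len(x)):
                    lp += np.log(p.transition[path[t - 1], path[t]]) + \
                        norm.logpdf(x[t], p.means[path[t]],
                                    np.sqrt(p.variances[path[t]]))
                return lp

            assert joint_lp(vpath) >= joint_lp(gpath) - 1e-10


class TestPosteriors:
    def test_rows_sum_to_one(self, rng):
        p = random_hmm_params(rng, 3)
        gamma = posterior_occupancy(p, rng.normal(0, 2, size=100))
        np.testing.assert_allclose(gamma.sum(axis=1), 1.0, atol=1e-10)


class TestStateFrequencies:
    def test_simple_counting(self):
        np.testing.assert_allclose(
            state_frequencies([0, 0, 1, 1], 2), [0.5, 0.5])
        np.testing.assert_allclose(
            state_frequencies([0] * 7, 3), [1.0, 0.0, 0.0])

    def test_matches_direct_counting(self, rng):
        path = rng.integers(0, 4, size=1000)
        freqs = state_frequencies(path, 4)
        expected = np.array([(path == m).mean() for m in range(4)])
        np.testing.assert_array_equal(freqs, expected)
        assert freqs.sum() == pytest.approx(1.0)


class TestFit:
    def test_single_state_closed_form(self, rng):
        x = rng.normal(3.0, 1.5, size=200)
        res = GaussianHMM(x, n_states=1).fit()
        assert res.params.means[0] == pytest.approx(np.mean(x), abs=1e-6)
        assert res.params.variances[0] == pytest.approx(np.var(x), abs=1e-6)
        assert res.aic == pytest.approx(-2 * res.loglik + 2 * 2)

    def test_two_state_recovery(self, two_state_params, rng):
        from thetanav.simulate import simulate_hmm_series
        x, _ = simulate_hmm_series(two_state_params, 2000, seed=rng)
        res = GaussianHMM(x, n_states=2).fit(seed=1)
        np.testing.assert_allclose(res.params.means, [-2, 2], atol=0.1)
        np.testing.assert_allclose(np.diag(res.params.transition),
                                   [0.9, 0.9], atol=0.05)

    def test_mle_dominates_truth(self, two_state_params, rng):
        from thetanav.simulate import simulate_hmm_series
        x, _ = simulate_hmm_series(two_state_params, 500, seed=rng)
        res = GaussianHMM(x, n_states=2).fit(seed=0)
        assert res.loglik >= forward_loglik(two_state_params, x) - 1e-6

    def test_short_series_rejected(self, rng):
        with pytest.raises(FitError):
            GaussianHMM(rng.normal(size=20), n_states=4).fit()

    def test_matches_hmmlearn_forward_score(self, rng):
        """Independent cross-check of the likelihood computation."""
        hmmlearn = pytest.importorskip("hmmlearn.hmm")
        p = random_hmm_params(rng, 3)
        x = rng.normal(0, 2, size=200)
        ref = hmmlearn.GaussianHMM(n_components=3, covariance_type="diag",
                                   init_params="")
        ref.startprob_ = p.initial
        ref.transmat_ = p.transition
        ref.means_ = p.means.reshape(-1, 1)
        ref.covars_ = p.variances.reshape(-1, 1)
        assert forward_loglik(p, x) == pytest.approx(
            ref.score(x.reshape(-1, 1)), abs=1e-8)


class TestFeatures:
    def test_m4_gives_eleven_features(self, rng):
        from thetanav.simulate import simulate_hmm_series
        from conftest import random_hmm_params as rp
        x, _ = simulate_hmm_series(rp(rng, 4), 300, seed=rng)
        res = GaussianHMM(x, n_states=4).fit(seed=0)
        feats = res.features()
        assert len(feats) == 11

    def test_m2_gives_five_features(self, rng):
        x = rng.normal(size=100)
        res = GaussianHMM(x, n_states=2).fit(seed=0)
        assert len(res.features()) == 2 * 2 + 1

    def test_transition_flag_adds_free_entries(self, rng):
        x = rng.normal(size=100)
        res = GaussianHMM(x, n_states=2).fit(seed=0)
        feats = res.features(include_transitions=True)
        assert len(feats) == 5 + 2 * 1  # M(M-1) free transition entries

    def test_features_invariant_to_label_permutation(self, rng):
        from thetanav.hmm import GaussianHMMResults
        p = random_hmm_params(rng, 4)
        x = rng.normal(0, 2, size=120)
        model = GaussianHMM(x, n_states=4)
        res = GaussianHMMResults(model, p.canonical()[0], 0.0, 1, True, False)
        perm = rng.permutation(4)
        res_perm = GaussianHMMResults(
            model, p.reordered(perm).canonical()[0], 0.0, 1, True, False)
        assert res.features() == res_perm.features()

    def test_frequency_features_bounded(self, rng):
        x = rng.normal(size=200)
        feats = GaussianHMM(x, n_states=4).fit(seed=0).features()
        freqs = [feats[f"hmm_freq_{k}"] for k in (1, 2, 3)]
        assert all(0 <= f <= 1 for f in freqs)
        assert sum(freqs) <= 1 + 1e-12


class TestAIC:
    def test_m1_aic_formula(self, rng):
        x = rng.normal(size=100)
        df = aic_profile([x], M_values=(1,))
        res = GaussianHMM(x, n_states=1).fit()
        assert df["aic"].iloc[0] == pytest.approx(-2 * res.loglik + 2 * 2)

    def test_larger_model_dominates_in_loglik(self, rng):
        series = [rng.normal(size=150) for _ in range(3)]
        df = aic_profile(series, M_values=(1, 2), seed=0)
        for sid, grp in df.groupby("series"):
            ll = grp.set_index("M")["loglik"]
            assert ll[2] >= ll[1] - 1e-6

    def test_true_two_state_data_prefers_m2(self, two_state_params, rng):
        from thetanav.simulate import simulate_hmm_series
        series = [simulate_hmm_series(two_state_params, 300, seed=rng)[0]
                  for _ in range(8)]
        df = aic_profile(series, M_values=(1, 2), seed=0)
        med = df.groupby("M")["aic"].median()
        assert med[2] < med[1]
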