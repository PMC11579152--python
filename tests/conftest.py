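import numpy as np
import pytest

from thetanav.simulate import CohortSpec, simulate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort():
    """A 5-per-group cohort, shared across fast tests."""
    spec = CohortSpec(n_per_group=5, seed=77)
    theta, traj, truth = simulate_cohort(spec)
    return spec, theta, traj, truth


def enumerate_loglik(params, x):
    """Brute-force log P(x) by summing over all M^T state paths."""
    from itertools import product

    from scipy.stats import norm

    x = np.asarray(x, dtype=float)
    M, T = params.n_states, len(x)
    sd = np.sqrt(params.variances)
    total = 0.0
    for path in product(range(M), repeat=T):
        p = params.initial[path[0]] * norm.pdf(x[0], params.means[path[0]],
                                               sd[path[0]])
        for t in range(1, T):
            p *= (params.transition[path[t - 1], path[t]]
                  * norm.pdf(x[t], params.means[path[t]], sd[path[t]]))
        total += p
    return np.log(total)


def enumerate_best_path(params, x):
    """Brute-force jointly most probable state path."""
    from itertools import product

    from scipy.stats import norm

    x = np.asarray(x, dtype=float)
    M, T = params.n_states, len(x)
    sd = np.sqrt(params.variances)
    best, best_path = -np.inf, None
    for path in product(range(M), repeat=T):
        lp = np.log(params.initial[path[0]]) + norm.logpdf(
            x[0], params.means[path[0]], sd[path[0]])
        for t in range(1, T):
            lp += np.log(params.transition[path[t - 1], path[t]]) \
                + norm.logpdf(x[t], params.means[path[t]], sd[path[t]])
        if lp > best:
            best, best_path = lp, path
    return np.array(best_path), best


def random_hmm_params(rng, M):
    """A random valid Gaussian-HMM parameter set."""
    from thetanav.hmm import GaussianHMMParams

    P = rng.uniform(0.2, 1.0, size=(M, M))
    P /= P.sum(axis=1, keepdims=True)
    delta = rng.uniform(0.2, 1.0, size=M)
    delta /= delta.sum()
    return GaussianHMMParams(
        means=rng.normal(0, 2, size=M),
        variances=rng.uniform(0.3, 2.0, size=M),
        transition=P,
        initial=delta,
    )
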