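"""Shared fixtures and independent brute-force oracles.

The enumeration oracles below compute HMM quantities by summing/maximising
over every possible state path; they share no code with the package's
recursions and are only feasible for Q^T up to a few thousand.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from scipy.stats import norm

import ensemblestates as es


def path_log_joint(params, y, path) -> float:
    """log p(path, y) under the HMM, summed term by term."""
    ll = np.log(params.pi[path[0]])
    for t in range(1, len(path)):
        ll += np.log(params.A[path[t - 1], path[t]])
    for t, s in enumerate(path):
        ll += norm.logpdf(y[:, t], params.mu[s], np.sqrt(params.var[s])).sum()
    return float(ll)


def enumerate_posteriors(params, y):
    """(gamma, loglik) by exhaustive summation over all Q^T state paths."""
    Q = params.Q
    T = y.shape[1]
    joint = {}
    for path in itertools.product(range(Q), repeat=T):
        with np.errstate(divide="ignore"):
            joint[path] = path_log_joint(params, y, path)
    mx = max(joint.values())
    probs = {p: np.exp(ll - mx) for p, ll in joint.items()}
    Z = sum(probs.values())
    loglik = mx + np.log(Z)
    gamma = np.zeros((Q, T))
    for path, pr in probs.items():
        for t, s in enumerate(path):
            gamma[s, t] += pr
    return gamma / Z, loglik


def enumerate_viterbi(params, y):
    """Best path by exhaustive argmax; ties resolved toward the
    lexicographically smallest path (itertools.product order)."""
    best, best_ll = None, -np.inf
    T = y.shape[1]
    for path in itertools.product(range(params.Q), repeat=T):
        with np.errstate(divide="ignore"):
            ll = path_log_joint(params, y, path)
        if ll > best_ll:
            best, best_ll = path, ll
    return np.array(best)


def random_hmm_params(rng, Q, N, mu_scale=3.0):
    """A valid random parameter set with strictly positive probabilities."""
    pi = rng.dirichlet(np.ones(Q) * 2.0)
    A = rng.dirichlet(np.ones(Q) * 2.0, size=Q)
    mu = rng.normal(0, mu_scale, size=(Q, N))
    var = rng.uniform(0.3, 2.0, size=(Q, N))
    return es.HMMParams(pi, A, mu, var)


def separated_params(Q, N, sep=4.0, self_p=0.9):
    """Well-separated states on a strong-diagonal chain (unit variances)."""
    mu = np.zeros((Q, N))
    for q in range(Q):
        mu[q, q % N] = sep * (1 + q // N)
        mu[q] += 3 + q  # keep means well above 0 and distinct on all units
    A = np.full((Q, Q), (1 - self_p) / max(Q - 1, 1))
    np.fill_diagonal(A, self_p if Q > 1 else 1.0)
    return es.HMMParams(np.full(Q, 1.0 / Q), A, mu, np.ones((Q, N)))


@pytest.fixture(scope="session")
def short_session_config():
    """A scaled-down pellet-drop session (5 min) for fast end-to-end tests."""
    return es.SessionConfig(
        n_units=10, baseline_dur=120.0, drop_period_dur=120.0, post_dur=60.0,
        n_drops=12, drop_interval=10.0, q_baseline=3, q_drop=2, seed=7,
    )


@pytest.fixture(scope="session")
def short_session(short_session_config):
    return es.simulate_session(short_session_config)


@pytest.fixture(scope="session")
def short_rates(short_session):
    spikes, _ = short_session
    return es.compute_ifr(es.filter_low_rate(spikes))
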