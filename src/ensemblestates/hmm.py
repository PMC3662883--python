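"""Gaussian-emission hidden Markov models for population rate vectors.

The latent process is a Q-state Markov chain over 500 ms bins; each state i
emits the N-dimensional population rate vector from a diagonal-covariance
normal N(mu_i, diag(var_i)).  Parameters are estimated by Baum-Welch EM from
random starts; state posteriors P[Q(t)=i | y(1:T)] come from the
forward-backward recursions and the single best path from Viterbi.  The
recursions use Rabiner per-step rescaling (with per-bin emission maxima
factored out), and Viterbi runs in log space, so sessions of 10^4+ bins are
numerically stable.

The number of states is selected with a Bayesian information criterion

    BIC(Q) = -2 L + ln(T) * (Q N + Q N + Q (Q - 1))

(means + diagonal variances + free transition-matrix entries), choosing the
Q at the BIC minimum, or the Q where the BIC curve flattens ("asymptote")
when it decreases monotonically over the candidate grid.

State labels are arbitrary: any cross-run parameter comparison should first
relabel states, e.g. with :func:`relabel_by_means`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .core import PosteriorMatrix, RateMatrix, read_json, write_json

VAR_FLOOR = 1e-3  # (spikes/s)^2; guards emission collapse on silent units


@dataclass
class HMMParams:
    """Initial distribution, transition matrix and diagonal-Gaussian emissions."""

    pi: np.ndarray   # (Q,)
    A: np.ndarray    # (Q, Q), rows sum to 1
    mu: np.ndarray   # (Q, N) spikes/s
    var: np.ndarray  # (Q, N) (spikes/s)^2, >= VAR_FLOOR

    def __post_init__(self) -> None:
        self.pi = np.asarray(self.pi, dtype=float)
        self.A = np.asarray(self.A, dtype=float)
        self.mu = np.atleast_2d(np.asarray(self.mu, dtype=float))
        self.var = np.atleast_2d(np.asarray(self.var, dtype=float))
        Q = self.pi.size
        if self.A.shape != (Q, Q) or self.mu.shape[0] != Q or self.var.shape != self.mu.shape:
            raise ValueError("inconsistent HMM parameter shapes")
        if not np.isclose(self.pi.sum(), 1.0, atol=1e-8):
            raise ValueError("pi must sum to 1")
        if not np.allclose(self.A.sum(axis=1), 1.0, atol=1e-8):
            raise ValueError("every row of A must sum to 1")
        if np.any(self.pi < -1e-12) or np.any(self.A < -1e-12):
            raise ValueError("probabilities must be non-negative")
        if np.any(self.var <= 0):
            raise ValueError("variances must be positive")

    @property
    def Q(self) -> int:
        return self.pi.size

    @property
    def n_units(self) -> int:
        return self.mu.shape[1]

    def permuted(self, perm: np.ndarray) -> "HMMParams":
        """Relabel states: state i of the result is state perm[i] of self."""
        perm = np.asarray(perm)
        return HMMParams(self.pi[perm], self.A[np.ix_(perm, perm)],
                         self.mu[perm], self.var[perm])


@dataclass
class HMMFit:
    params: HMMParams
    loglik_trace: np.ndarray      # best restart's per-iteration log-likelihood
    final_loglik: float
    posteriors: PosteriorMatrix
    viterbi: np.ndarray
    n_restarts_used: int
    seed: int


@dataclass
class ModelSelection:
    q_grid: list[int]
    bic: np.ndarray
    bic_normalized: np.ndarray
    q_star: int
    rule_fired: str               # 'minimum' or 'asymptote'
    fits: dict[int, HMMFit] = field(default_factory=dict, repr=False)
    failed: dict[int, str] = field(default_factory=dict)


def _log_emission(params: HMMParams, y: np.ndarray) -> np.ndarray:
    """log N(y_t; mu_i, diag(var_i)) as a (Q, T) array; y is (N, T)."""
    yT = y.T[None, :, :]                      # (1, T, N)
    mu = params.mu[:, None, :]                # (Q, 1, N)
    var = params.var[:, None, :]
    ll = -0.5 * (((yT - mu) ** 2) / var + np.log(2.0 * np.pi * var))
    return ll.sum(axis=2)                     # (Q, T)


def forward_backward(params: HMMParams,
                     rates: RateMatrix) -> tuple[PosteriorMatrix, float]:
    """Exact smoothed posteriors and data log-likelihood under fixed params."""
    if rates.n_units != params.n_units:
        raise ValueError("rates and params disagree on the number of units")
    logB = _log_emission(params, rates.values)
    gamma, loglik, *_ = _forward_backward_core(params, logB)
    return PosteriorMatrix(gamma, rates.bin_width, rates.t0), loglik


def _forward_backward_core(params: HMMParams, logB: np.ndarray):
    """Scaled alpha/beta recursions (Rabiner normalisation).

    Per-bin emission maxima are factored out of the densities so arbitrarily
    negative log-densities stay representable; the recursion itself then runs
    in linear space with per-step normalisation constants whose logs rebuild
    the exact data log-likelihood.  Returns (gamma, loglik, alpha_hat,
    beta_hat, btil, logc) — gamma columns sum to 1 exactly.
    """
    Q, T = logB.shape
    bmax = logB.max(axis=0)
    btil = np.exp(logB - bmax)                # (Q, T), max of each column is 1
    A = params.A
    alpha = np.empty((Q, T))
    c = np.empty(T)
    a = params.pi * btil[:, 0]
    c[0] = a.sum()
    if c[0] <= 0:
        raise FloatingPointError("zero likelihood at t=0")
    alpha[:, 0] = a / c[0]
    for t in range(1, T):
        a = (alpha[:, t - 1] @ A) * btil[:, t]
        c[t] = a.sum()
        if c[t] <= 0:
            raise FloatingPointError(f"zero likelihood at t={t}")
        alpha[:, t] = a / c[t]
    beta = np.empty((Q, T))
    beta[:, T - 1] = 1.0
    for t in range(T - 2, -1, -1):
        beta[:, t] = (A @ (btil[:, t + 1] * beta[:, t + 1])) / c[t + 1]
    logc = np.log(c)
    loglik = float(logc.sum() + bmax.sum())
    gamma = alpha * beta
    gamma /= gamma.sum(axis=0, keepdims=True)
    return gamma, loglik, alpha, beta, btil, logc


def viterbi_path(params: HMMParams, rates: RateMatrix) -> np.ndarray:
    """Maximum-probability state path; ties broken toward the lower index."""
    if rates.n_units != params.n_units:
        raise ValueError("rates and params disagree on the number of units")
    logB = _log_emission(params, rates.values)
    Q, T = logB.shape
    with np.errstate(divide="ignore"):
        log_pi = np.log(params.pi)
        log_A = np.log(params.A)
    delta = log_pi + logB[:, 0]
    back = np.empty((T, Q), dtype=int)
    for t in range(1, T):
        scores = delta[:, None] + log_A          # (from, to)
        back[t] = np.argmax(scores, axis=0)       # argmax -> first (lowest) index
        delta = scores[back[t], np.arange(Q)] + logB[:, t]
    path = np.empty(T, dtype=int)
    path[-1] = int(np.argmax(delta))
    for t in range(T - 1, 0, -1):
        path[t - 1] = back[t, path[t]]
    return path


def _random_init(rates: RateMatrix, Q: int, rng: np.random.Generator) -> HMMParams:
    """Random stochastic pi/A; means from random data columns; variances from
    the per-unit data variance (floored)."""
    y = rates.values
    N, T = y.shape
    pi = rng.dirichlet(np.ones(Q))
    A = rng.dirichlet(np.ones(Q), size=Q)
    cols = rng.choice(T, size=Q, replace=Q > T)
    mu = y[:, cols].T.copy()
    var = np.maximum(y.var(axis=1), VAR_FLOOR)
    var = np.tile(var, (Q, 1))
    return HMMParams(pi, A, mu, var)


def _em(rates: RateMatrix, params: HMMParams, max_iter: int,
        tol: float) -> tuple[HMMParams, np.ndarray]:
    y = rates.values
    N, T = y.shape
    Q = params.Q
    trace = []
    prev = -np.inf
    for _ in range(max_iter):
        logB = _log_emission(params, y)
        gamma, loglik, alpha, beta, btil, logc = _forward_backward_core(params, logB)
        trace.append(loglik)

        # expected transition counts xi_sum[i, j]
        if T > 1:
            w = btil[:, 1:] * beta[:, 1:] / np.exp(logc[1:])[None, :]
            xi_sum = (alpha[:, :-1] @ w.T) * params.A
        else:
            xi_sum = np.zeros((Q, Q))

        # M-step
        pi = gamma[:, 0] / gamma[:, 0].sum()
        occ = gamma.sum(axis=1)                        # (Q,)
        row = xi_sum.sum(axis=1, keepdims=True)
        A = np.where(row > 1e-300, xi_sum / np.maximum(row, 1e-300),
                     np.eye(Q))
        A /= A.sum(axis=1, keepdims=True)
        mu = (gamma @ y.T) / occ[:, None]
        ey2 = (gamma @ (y ** 2).T) / occ[:, None]
        var = np.maximum(ey2 - mu ** 2, VAR_FLOOR)
        params = HMMParams(pi, A, mu, var)

        if prev > -np.inf and (loglik - prev) < tol * abs(prev):
            break
        prev = loglik
    return params, np.asarray(trace)


def fit_hmm(rates: RateMatrix, Q: int, seed: int, max_iter: int = 500,
            tol: float = 1e-6, n_restarts: int = 5) -> HMMFit:
    """Baum-Welch EM from ``n_restarts`` random initialisations; the restart
    with the best final log-likelihood is kept.

    Convergence: relative log-likelihood improvement below ``tol``.
    """
    if Q < 1:
        raise ValueError("Q must be >= 1")
    if rates.n_bins <= Q:
        raise ValueError("need more bins than states")
    if not np.all(np.isfinite(rates.values)):
        raise ValueError("non-finite rates")
    rng = np.random.default_rng(seed)
    best: tuple[float, HMMParams, np.ndarray] | None = None
    for _ in range(n_restarts):
        params0 = _random_init(rates, Q, rng)
        params, trace = _em(rates, params0, max_iter, tol)
        if best is None or trace[-1] > best[0]:
            best = (float(trace[-1]), params, trace)
    final_ll, params, trace = best
    post, loglik = forward_backward(params, rates)
    path = viterbi_path(params, rates)
    return HMMFit(params, trace, loglik, post, path, n_restarts, seed)


def compute_bic(loglik: float, T: int, Q: int, N: int) -> float:
    """-2 L + ln(T) (Q N + Q N + Q (Q - 1)); natural log."""
    if T < 1:
        raise ValueError("T must be >= 1")
    k = Q * N + Q * N + Q * (Q - 1)
    return -2.0 * loglik + np.log(T) * k


def select_num_states(rates: RateMatrix, q_grid: list[int], seed: int = 0,
                      max_iter: int = 500, tol: float = 1e-6,
                      n_restarts: int = 5) -> ModelSelection:
    """Fit each candidate Q and pick the BIC minimum, or — when the BIC keeps
    decreasing to the end of the grid — the Q where it flattens: the smallest
    Q after which every further decrease is under 1% of the BIC range.
    """
    if not q_grid or list(q_grid) != sorted(set(q_grid)):
        raise ValueError("q_grid must be non-empty, ascending, unique")
    fits: dict[int, HMMFit] = {}
    failed: dict[int, str] = {}
    rng = np.random.default_rng(seed)
    for Q in q_grid:
        sub = int(rng.integers(2**31))
        try:
            fits[Q] = fit_hmm(rates, Q, sub, max_iter, tol, n_restarts)
        except Exception as exc:  # record and drop this Q
            failed[Q] = str(exc)
    if not fits:
        raise RuntimeError(f"all candidate fits failed: {failed}")
    grid = sorted(fits)
    bic = np.array([compute_bic(fits[Q].final_loglik, rates.n_bins, Q,
                                rates.n_units) for Q in grid])
    rng_bic = bic.max() - bic.min()
    norm = (bic - bic.min()) / rng_bic if rng_bic > 0 else np.zeros_like(bic)

    imin = int(np.argmin(bic))
    if imin < len(grid) - 1 or len(grid) == 1:
        q_star, rule = grid[imin], "minimum"
    else:  # monotone-trending decrease to the grid edge: asymptote rule
        drops = bic[:-1] - bic[1:]
        k = 0
        for i in range(len(grid) - 1, -1, -1):
            if i < len(drops) and drops[i] >= 0.01 * rng_bic:
                k = i + 1
                break
        q_star, rule = grid[k], "asymptote"
    return ModelSelection(grid, bic, norm, q_star, rule, fits, failed)


def relabel_by_means(reference_mu: np.ndarray, params: HMMParams) -> np.ndarray:
    """Greedy permutation matching params' states to reference states by
    nearest emission means; returns perm with params.permuted(perm) aligned
    so its state i corresponds to reference state i."""
    ref = np.atleast_2d(reference_mu)
    Q = ref.shape[0]
    d = np.linalg.norm(ref[:, None, :] - params.mu[None, :, :], axis=2)
    perm = np.full(Q, -1, dtype=int)
    used = np.zeros(Q, dtype=bool)
    for r, c in sorted(
            ((i, j) for i in range(Q) for j in range(Q)),
            key=lambda ij: d[ij[0], ij[1]]):
        if perm[r] == -1 and not used[c]:
            perm[r], used[c] = c, True
    return perm


def loglikelihood(params: HMMParams, rates: RateMatrix) -> float:
    """Data log-likelihood under fixed parameters (no fitting)."""
    logB = _log_emission(params, rates.values)
    _, loglik, *_ = _forward_backward_core(params, logB)
    return loglik


def write_hmm_params(path: str | Path, fit: HMMFit) -> None:
    write_json(path, {
        "pi": fit.params.pi, "A": fit.params.A,
        "mu": fit.params.mu, "var": fit.params.var,
        "final_loglik": fit.final_loglik, "seed": fit.seed,
        "n_restarts_used": fit.n_restarts_used,
        "loglik_trace": fit.loglik_trace,
    })


def read_hmm_params(path: str | Path) -> HMMParams:
    d = read_json(path)
    return HMMParams(np.array(d["pi"]), np.array(d["A"]),
                     np.array(d["mu"]), np.array(d["var"]))
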