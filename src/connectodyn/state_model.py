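"""K-state Gaussian-observation HMM for connectome-state decomposition.

Maximum-likelihood EM (Baum-Welch) on the concatenation of multiple subjects'
envelope sequences, each treated as an independent sequence restarted from the
initial distribution.  Point estimates are all the downstream phenotyping
needs; covariances are ridge-regularized each M-step because region-level
envelope covariances are near-singular at modest sample sizes.

Also provides the temporally-scrambled surrogate: states drawn i.i.d. from a
fractional-occupancy profile so the static (time-collapsed) covariance is
preserved while state sequencing is destroyed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy.linalg import solve_triangular
from scipy.optimize import linear_sum_assignment

__all__ = [
    "HMMParams",
    "StateTimeCourse",
    "fit_hmm",
    "forward_loglik",
    "decode",
    "simulate_surrogate",
    "mixture_moments",
    "match_states",
    "standardize_sequences",
]


@dataclass
class HMMParams:
    K: int
    means: np.ndarray                 # (K, R)
    covs: np.ndarray                  # (K, R, R)
    A: np.ndarray                     # (K, K) row-stochastic
    pi: np.ndarray                    # (K,)
    loglik_trace: list[float] = field(default_factory=list)

    def validate(self) -> None:
        if not np.allclose(self.A.sum(axis=1), 1.0, atol=1e-10):
            raise ValueError("transition rows must sum to 1")
        for k in range(self.K):
            if np.linalg.eigvalsh(self.covs[k]).min() <= 0:
                raise ValueError(f"covariance of state {k} is not positive-definite")


@dataclass
class StateTimeCourse:
    subject_id: str
    gamma: np.ndarray                 # (T, K) posterior state probabilities
    xi_sum: np.ndarray                # (K, K) expected transition counts
    viterbi: np.ndarray               # (T,) 0-based state indices
    loglik: float = 0.0


# ---------------------------------------------------------------------------
# Jitted recursions (probability domain with per-step scaling)
# ---------------------------------------------------------------------------

@njit(cache=True)
def _forward(logb, A, pi):
    T, K = logb.shape
    bnorm = np.empty((T, K))
    bmax = np.empty(T)
    for t in range(T):
        m = logb[t, 0]
        for k in range(1, K):
            if logb[t, k] > m:
                m = logb[t, k]
        bmax[t] = m
        for k in range(K):
            bnorm[t, k] = np.exp(logb[t, k] - m)
    alpha = np.empty((T, K))
    snorm = np.empty(T)
    s = 0.0
    for k in range(K):
        alpha[0, k] = pi[k] * bnorm[0, k]
        s += alpha[0, k]
    snorm[0] = s
    for k in range(K):
        alpha[0, k] /= s
    for t in range(1, T):
        s = 0.0
        for j in range(K):
            a = 0.0
            for i in range(K):
                a += alpha[t - 1, i] * A[i, j]
            a *= bnorm[t, j]
            alpha[t, j] = a
            s += a
        snorm[t] = s
        for j in range(K):
            alpha[t, j] /= s
    ll = 0.0
    for t in range(T):
        ll += np.log(snorm[t]) + bmax[t]
    return alpha, bnorm, snorm, ll


@njit(cache=True)
def _backward_smooth(alpha, bnorm, snorm, A):
    T, K = alpha.shape
    beta = np.empty((T, K))
    gamma = np.empty((T, K))
    xi = np.zeros((K, K))
    for k in range(K):
        beta[T - 1, k] = 1.0
    for t in range(T - 2, -1, -1):
        for i in range(K):
            b = 0.0
            for j in range(K):
                b += A[i, j] * bnorm[t + 1, j] * beta[t + 1, j]
            beta[t, i] = b / snorm[t + 1]
    for t in range(T):
        s = 0.0
        for k in range(K):
            g = alpha[t, k] * beta[t, k]
            gamma[t, k] = g
            s += g
        for k in range(K):
            gamma[t, k] /= s
    for t in range(T - 1):
        for i in range(K):
            for j in range(K):
                xi[i, j] += (alpha[t, i] * A[i, j] * bnorm[t + 1, j]
                             * beta[t + 1, j] / snorm[t + 1])
    return gamma, xi


@njit(cache=True)
def _viterbi(logb, logA, logpi):
    T, K = logb.shape
    delta = np.empty((T, K))
    back = np.zeros((T, K), dtype=np.int64)
    for k in range(K):
        delta[0, k] = logpi[k] + logb[0, k]
    for t in range(1, T):
        for j in range(K):
            best = delta[t - 1, 0] + logA[0, j]
            arg = 0
            for i in range(1, K):
                v = delta[t - 1, i] + logA[i, j]
                if v > best:
                    best = v
                    arg = i
            delta[t, j] = best + logb[t, j]
            back[t, j] = arg
    path = np.empty(T, dtype=np.int64)
    best = delta[T - 1, 0]
    arg = 0
    for k in range(1, K):
        if delta[T - 1, k] > best:
            best = delta[T - 1, k]
            arg = k
    path[T - 1] = arg
    for t in range(T - 2, -1, -1):
        path[t] = back[t + 1, path[t + 1]]
    return path


# ---------------------------------------------------------------------------
# Emission densities
# ---------------------------------------------------------------------------

def _log_emissions(obs: np.ndarray, means: np.ndarray, covs: np.ndarray) -> np.ndarray:
    """(T, K) log N(obs_t | mean_k, cov_k)."""
    T, R = obs.shape
    K = means.shape[0]
    logb = np.empty((T, K))
    c = R * np.log(2.0 * np.pi)
    for k in range(K):
        L = np.linalg.cholesky(covs[k])
        dev = obs - means[k]
        sol = solve_triangular(L, dev.T, lower=True)
        logdet = 2.0 * np.sum(np.log(np.diag(L)))
        logb[:, k] = -0.5 * (c + logdet + np.sum(sol ** 2, axis=0))
    return logb


# ---------------------------------------------------------------------------
# Public API
# ---------------------------------------------------------------------------

def _as_obs(x) -> np.ndarray:
    """Accept a (T, R) array or a BandTimeSeries-like object (regions x time)."""
    if hasattr(x, "data") and hasattr(x, "fs"):
        return np.ascontiguousarray(np.asarray(x.data, float).T)
    return np.ascontiguousarray(np.asarray(x, dtype=float))


def standardize_sequences(seqs: list[np.ndarray]) -> list[np.ndarray]:
    """Demean and scale each region to unit variance within each subject."""
    out = []
    for x in seqs:
        mu = x.mean(axis=0)
        sd = x.std(axis=0)
        sd[sd == 0] = 1.0
        out.append((x - mu) / sd)
    return out


def forward_loglik(params: HMMParams, obs) -> float:
    """log p(obs | params) via the scaled forward recursion."""
    x = _as_obs(obs)
    if not np.all(np.isfinite(x)):
        raise ValueError("observations contain non-finite values")
    logb = _log_emissions(x, params.means, params.covs)
    _, _, _, ll = _forward(logb, params.A, params.pi)
    return float(ll)


def decode(params: HMMParams, obs, subject_id: str = "") -> StateTimeCourse:
    """Posterior state probabilities, expected transition counts, Viterbi path."""
    x = _as_obs(obs)
    if not np.all(np.isfinite(x)):
        raise ValueError("observations contain non-finite values")
    logb = _log_emissions(x, params.means, params.covs)
    alpha, bnorm, snorm, ll = _forward(logb, params.A, params.pi)
    gamma, xi = _backward_smooth(alpha, bnorm, snorm, params.A)
    tiny = np.finfo(float).tiny
    path = _viterbi(logb, np.log(params.A + tiny), np.log(params.pi + tiny))
    return StateTimeCourse(subject_id=subject_id, gamma=gamma, xi_sum=xi,
                           viterbi=path, loglik=float(ll))


def _kmeans_init(X: np.ndarray, K: int, seed: int, reg: float):
    from sklearn.cluster import KMeans

    rng = np.random.default_rng(seed)
    sub = X if X.shape[0] <= 50_000 else X[rng.choice(X.shape[0], 50_000, replace=False)]
    km = KMeans(n_clusters=K, n_init=2, random_state=int(seed % (2 ** 31))).fit(sub)
    means = km.cluster_centers_.copy()
    R = X.shape[1]
    covs = np.empty((K, R, R))
    global_cov = np.cov(sub.T) + reg * np.eye(R)
    for k in range(K):
        pts = sub[km.labels_ == k]
        if pts.shape[0] > R + 1:
            S = np.cov(pts.T)
            covs[k] = S + max(reg, 1e-6 * np.trace(S) / R) * np.eye(R)
        else:
            covs[k] = global_cov
    A = np.full((K, K), 0.2 / max(K - 1, 1))
    np.fill_diagonal(A, 0.8 if K > 1 else 1.0)
    pi = np.full(K, 1.0 / K)
    return means, covs, A, pi


def _em_run(seqs, K, means, covs, A, pi, max_iter, tol, reg):
    R = seqs[0].shape[1]
    trace: list[float] = []
    for _ in range(max_iter):
        g0 = np.zeros(K)
        xi_tot = np.zeros((K, K))
        Nk = np.zeros(K)
        sx = np.zeros((K, R))
        sxx = np.zeros((K, R, R))
        ll = 0.0
        gammas = []
        for x in seqs:
            logb = _log_emissions(x, means, covs)
            alpha, bnorm, snorm, l = _forward(logb, A, pi)
            gamma, xi = _backward_smooth(alpha, bnorm, snorm, A)
            ll += l
            g0 += gamma[0]
            xi_tot += xi
            Nk += gamma.sum(axis=0)
            sx += gamma.T @ x
            sxx += np.einsum("tk,ti,tj->kij", gamma, x, x, optimize=True)
            gammas.append(gamma)
        trace.append(float(ll))
        if len(trace) > 1:
            rel = (trace[-1] - trace[-2]) / (abs(trace[-2]) + 1e-300)
            if rel < tol:
                break
        pi = g0 / g0.sum()
        rows = xi_tot.sum(axis=1, keepdims=True)
        A = np.where(rows > 0, xi_tot / np.maximum(rows, 1e-300), 1.0 / K)
        A /= A.sum(axis=1, keepdims=True)
        means = sx / np.maximum(Nk, 1e-300)[:, None]
        for k in range(K):
            S = sxx[k] / max(Nk[k], 1e-300) - np.outer(means[k], means[k])
            S = 0.5 * (S + S.T)
            S += reg * (np.trace(S) / R) * np.eye(R)
            if np.linalg.eigvalsh(S).min() <= 0:
                S += 1e-8 * np.eye(R)
                if np.linalg.eigvalsh(S).min() <= 0:
                    raise np.linalg.LinAlgError(
                        f"covariance of state {k} singular despite regularization"
                    )
            covs[k] = S
    return HMMParams(K=K, means=means, covs=covs, A=A, pi=pi, loglik_trace=trace)


def fit_hmm(
    envelopes,
    K: int,
    *,
    n_restarts: int = 5,
    max_iter: int = 100,
    tol: float = 1e-6,
    reg: float = 1e-6,
    seed: int = 0,
    standardize: bool = True,
    subject_ids: list[str] | None = None,
) -> tuple[HMMParams, list[StateTimeCourse]]:
    """Fit a K-state Gaussian HMM to multiple subjects' envelope sequences.

    Each subject is an independent sequence re-initialized from the initial
    distribution; parameters are shared across subjects (group-level model)
    and each subject is then decoded individually.  Returns the best of
    ``n_restarts`` EM runs by final log-likelihood, with k-means-initialized
    emission parameters and per-restart seeds derived from ``seed``.
    """
    seqs = [_as_obs(e) for e in envelopes]
    if len(seqs) == 0:
        raise ValueError("need at least one subject")
    R = seqs[0].shape[1]
    for x in seqs:
        if x.shape[1] != R:
            raise ValueError("all subjects must share the same region set")
        if not np.all(np.isfinite(x)):
            raise ValueError("observations contain non-finite values")
    total = sum(x.shape[0] for x in seqs)
    if K > total:
        raise ValueError(f"K={K} exceeds the number of observations ({total})")
    if standardize:
        seqs = standardize_sequences(seqs)
    X = np.vstack(seqs)

    child_seeds = np.random.SeedSequence(seed).generate_state(n_restarts)
    best: HMMParams | None = None
    for r in range(n_restarts):
        means, covs, A, pi = _kmeans_init(X, K, int(child_seeds[r]), reg)
        try:
            fit = _em_run(seqs, K, means, covs, A, pi, max_iter, tol, reg)
        except np.linalg.LinAlgError as exc:
            warnings.warn(f"restart {r} failed: {exc}", stacklevel=2)
            continue
        if best is None or fit.loglik_trace[-1] > best.loglik_trace[-1]:
            best = fit
    if best is None:
        raise np.linalg.LinAlgError("all EM restarts failed with singular covariances")

    ids = subject_ids or [f"sub-{i + 1:04d}" for i in range(len(seqs))]
    stcs = [decode(best, x, subject_id=ids[i]) for i, x in enumerate(seqs)]
    return best, stcs


def simulate_surrogate(params: HMMParams, fo, T: int, rng) -> tuple[np.ndarray, np.ndarray]:
    """Temporally-scrambled surrogate: states i.i.d. from ``fo``, Gaussian emissions.

    The time-collapsed covariance of the output matches the analytic mixture
    covariance sum_k fo_k (cov_k + mean_k mean_k^T) - m m^T while all Markov
    memory in the state sequence is destroyed.
    """
    fo = np.asarray(fo, dtype=float)
    if np.any(fo < 0) or not np.isclose(fo.sum(), 1.0, atol=1e-8):
        raise ValueError("fo must lie on the probability simplex")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    states = rng.choice(params.K, size=T, p=fo / fo.sum())
    from .simulate import gen_envelopes

    obs = gen_envelopes(states, params.means, params.covs, rng)
    return obs, states


def mixture_moments(means: np.ndarray, covs: np.ndarray, fo) -> tuple[np.ndarray, np.ndarray]:
    """Analytic mean and static covariance of the state mixture."""
    fo = np.asarray(fo, dtype=float)
    m = fo @ means
    S = np.einsum("k,kij->ij", fo, covs)
    S += np.einsum("k,ki,kj->ij", fo, means, means)
    S -= np.outer(m, m)
    return m, S


def match_states(true_paths, est_paths, K: int) -> np.ndarray:
    """Permutation aligning estimated state labels to true labels.

    Returns ``perm`` with ``perm[j] = true label`` for estimated label ``j``,
    chosen by Hungarian assignment on the label confusion matrix.
    """
    tp = np.concatenate([np.asarray(p).ravel() for p in np.atleast_2d(true_paths)])
    ep = np.concatenate([np.asarray(p).ravel() for p in np.atleast_2d(est_paths)])
    C = np.zeros((K, K))
    np.add.at(C, (tp, ep), 1.0)
    row, col = linear_sum_assignment(-C)
    perm = np.empty(K, dtype=np.int64)
    perm[col] = row
    return perm
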