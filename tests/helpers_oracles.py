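"""Independent oracles used by the tests: exhaustive HMM enumeration,
sequential Gram-Schmidt comparator, and direct numeric CCA maximization.
All are deliberately brute-force and share no code with the package."""

from itertools import product

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp


def enumerate_hmm(logb, A, pi):
    """Exact log-likelihood, posteriors, and expected transition counts by
    summing over all K^T state paths."""
    T, K = logb.shape
    logA = np.log(A)
    logpi = np.log(pi)
    paths = list(product(range(K), repeat=T))
    logps = np.empty(len(paths))
    for n, p in enumerate(paths):
        lp = logpi[p[0]] + logb[0, p[0]]
        for t in range(1, T):
            lp += logA[p[t - 1], p[t]] + logb[t, p[t]]
        logps[n] = lp
    ll = logsumexp(logps)
    w = np.exp(logps - ll)
    gamma = np.zeros((T, K))
    xi = np.zeros((K, K))
    for wp, p in zip(w, paths):
        for t in range(T):
            gamma[t, p[t]] += wp
        for t in range(T - 1):
            xi[p[t], p[t + 1]] += wp
    return ll, gamma, xi


def random_hmm_instance(K, T, R, rng):
    """Random valid HMM parameters plus observations."""
    A = rng.dirichlet(np.ones(K) * 2.0, size=K)
    pi = rng.dirichlet(np.ones(K) * 2.0)
    means = rng.standard_normal((K, R)) * 2.0
    covs = np.empty((K, R, R))
    for k in range(K):
        W = rng.standard_normal((R, R)) * 0.3
        covs[k] = W @ W.T + np.eye(R)
    obs = rng.standard_normal((T, R))
    return A, pi, means, covs, obs


def gram_schmidt_columns(Z):
    """Sequential orthogonalization of columns in input order."""
    Q = np.array(Z, dtype=float, copy=True)
    for j in range(Q.shape[1]):
        for i in range(j):
            qi = Q[:, i]
            Q[:, j] -= (qi @ Q[:, j]) / (qi @ qi) * qi
    return Q


def brute_force_first_canonical_r(U, V, n_starts=30, seed=0):
    """Directly maximize corr(Ua, Vb) over weight vectors."""
    rng = np.random.default_rng(seed)
    Uc = U - U.mean(axis=0)
    Vc = V - V.mean(axis=0)
    p, q = Uc.shape[1], Vc.shape[1]

    def negcorr(w):
        x = Uc @ w[:p]
        y = Vc @ w[p:]
        sx, sy = np.linalg.norm(x), np.linalg.norm(y)
        if sx < 1e-12 or sy < 1e-12:
            return 0.0
        return -float(x @ y) / (sx * sy)

    best = 0.0
    for _ in range(n_starts):
        res = minimize(negcorr, rng.standard_normal(p + q), method="Nelder-Mead",
                       options={"maxiter": 20000, "xatol": 1e-12, "fatol": 1e-14})
        best = max(best, -res.fun)
    return best
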