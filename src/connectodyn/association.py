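"""Dimensionality reduction, covariate-adjusted CCA, and permutation inference.

Both variable sets are z-scored, the dynamics side is reduced band-wise by
PCA with Kaiser retention (eigenvalue > 1 on the correlation matrix), the
cognitive side by maximum-likelihood factor analysis with promax rotation,
and the two reduced sets enter CCA after residualizing age and sex out of
both sides.  Mode significance comes from permuting whole rows of U against a
fixed V (optionally permuting family blocks as units, since twins are not
exchangeable with singletons), comparing each observed canonical correlation
with the permutation distribution of the first (largest) canonical
correlation so that familywise error is controlled across modes.
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize

__all__ = [
    "PCAResult",
    "FactorModel",
    "CCAResult",
    "zscore_table",
    "bandwise_pca",
    "varimax",
    "promax",
    "cognitive_factors",
    "residualize",
    "cca",
    "permutation_test",
    "canonical_loadings",
    "variance_contribution",
]


# ---------------------------------------------------------------------------
# Standardization with missing-data policy
# ---------------------------------------------------------------------------

def zscore_table(X, max_missing_frac: float = 0.5):
    """Column-wise z-scoring with mean imputation of missing entries.

    Subjects missing strictly more than ``max_missing_frac`` of the columns
    are dropped (inclusion rule); zero-variance columns are dropped with a
    warning; remaining missing entries become 0 after standardization (mean
    imputation).  Returns (standardized table, info dict).
    """
    is_frame = isinstance(X, pd.DataFrame)
    df = X.copy() if is_frame else pd.DataFrame(np.asarray(X, dtype=float))
    vals = df.to_numpy(dtype=float)

    miss = np.isnan(vals)
    frac = miss.mean(axis=1)
    keep_rows = frac <= max_missing_frac
    dropped_subjects = np.flatnonzero(~keep_rows)
    vals = vals[keep_rows]

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mu = np.nanmean(vals, axis=0)
        sd = np.nanstd(vals, axis=0)
    zero_var = ~(sd > 0)
    if zero_var.any():
        warnings.warn(
            f"dropping {int(zero_var.sum())} zero-variance column(s)", stacklevel=2
        )
    keep_cols = ~zero_var
    Z = (vals[:, keep_cols] - mu[keep_cols]) / sd[keep_cols]
    Z[np.isnan(Z)] = 0.0

    info = {
        "dropped_subjects": dropped_subjects,
        "kept_subjects": np.flatnonzero(keep_rows),
        "dropped_columns": np.flatnonzero(zero_var),
    }
    if is_frame:
        out = pd.DataFrame(Z, index=df.index[keep_rows],
                           columns=df.columns[np.flatnonzero(keep_cols)])
        info["dropped_columns"] = list(df.columns[np.flatnonzero(zero_var)])
        return out, info
    return Z, info


# ---------------------------------------------------------------------------
# Band-wise PCA with Kaiser retention
# ---------------------------------------------------------------------------

@dataclass
class PCAResult:
    scores: np.ndarray           # (n, n_retained)
    coeffs: np.ndarray           # (d, n_retained) eigenvectors, unit norm
    eigenvalues: np.ndarray      # (d,) all eigenvalues, descending
    n_retained: int


def bandwise_pca(Z) -> PCAResult:
    """Correlation-matrix PCA keeping components with eigenvalue > 1.

    Input must be standardized.  Scores are returned in descending-eigenvalue
    order; each eigenvector's largest-magnitude coefficient is made positive.
    At least one component is always retained.
    """
    Z = np.asarray(Z, dtype=float)
    if Z.ndim != 2 or Z.shape[1] == 0:
        raise ValueError("need a nonempty 2-D standardized matrix")
    C = np.corrcoef(Z, rowvar=False)
    C = np.atleast_2d(C)
    w, V = np.linalg.eigh(C)
    order = np.argsort(w)[::-1]
    w, V = w[order], V[:, order]
    for j in range(V.shape[1]):
        i = int(np.argmax(np.abs(V[:, j])))
        if V[i, j] < 0:
            V[:, j] *= -1.0
    n_keep = max(1, int(np.sum(w > 1.0)))
    return PCAResult(scores=Z @ V[:, :n_keep], coeffs=V[:, :n_keep],
                     eigenvalues=w, n_retained=n_keep)


def variance_contribution(coeffs, eigenvalues, subset) -> np.ndarray:
    """Percent of a variable subset's variance captured by each PC.

    For standardized variables, PC j explains ``coeff_ij^2 * lambda_j`` of
    variable i's unit variance; the contribution to a subset is the average
    over the subset, in percent.  Summed over all PCs this is exactly 100.
    """
    subset = np.asarray(subset, dtype=int)
    if subset.size == 0:
        raise ValueError("empty variable subset")
    coeffs = np.asarray(coeffs, dtype=float)
    lam = np.asarray(eigenvalues, dtype=float)[: coeffs.shape[1]]
    return 100.0 * (coeffs[subset] ** 2 * lam).sum(axis=0) / subset.size


# ---------------------------------------------------------------------------
# Maximum-likelihood factor analysis with promax rotation
# ---------------------------------------------------------------------------

def varimax(L, tol: float = 1e-10, max_iter: int = 500, normalize: bool = True):
    """Orthogonal varimax rotation (Kaiser-normalized). Returns (rotated, rotation)."""
    L = np.asarray(L, dtype=float)
    p, k = L.shape
    if k < 2:
        return L.copy(), np.eye(k)
    h = np.sqrt((L ** 2).sum(axis=1)) if normalize else np.ones(p)
    h[h == 0] = 1.0
    X = L / h[:, None]
    Rm = np.eye(k)
    var = 0.0
    for _ in range(max_iter):
        Lr = X @ Rm
        B = X.T @ (Lr ** 3 - Lr @ np.diag((Lr ** 2).sum(axis=0)) / p)
        U, s, Vt = np.linalg.svd(B)
        Rm = U @ Vt
        new_var = s.sum()
        if new_var <= var * (1.0 + tol):
            break
        var = new_var
    rotated = (X @ Rm) * h[:, None]
    return rotated, Rm


def promax(L, kappa: float = 4.0):
    """Oblique promax rotation: varimax, then least-squares fit to a power target.

    Returns (pattern loadings, factor correlation matrix, total rotation) so
    that ``L @ rotation = pattern`` and factor correlations have unit diagonal.
    """
    V, rot_v = varimax(L)
    P = V * np.abs(V) ** (kappa - 1.0)
    U, *_ = np.linalg.lstsq(V, P, rcond=None)
    d = np.diag(np.linalg.inv(U.T @ U))
    U = U * np.sqrt(d)
    pattern = V @ U
    phi = np.linalg.inv(U.T @ U)
    return pattern, phi, rot_v @ U


def _ml_factor_loadings(R, k: int, psi_floor: float = 0.005):
    """Lawley profile-likelihood ML extraction from a correlation matrix.

    Optimizes uniquenesses; loadings follow in closed form from the top-k
    eigenpairs of the rescaled correlation matrix.  Uniquenesses are bounded
    below to guard against Heywood cases (a warning is issued if the bound is
    active).
    """
    R = np.asarray(R, dtype=float)
    p = R.shape[0]
    if not 1 <= k < p:
        raise ValueError("need 1 <= n_factors < n_measures")

    def loadings_for(psi):
        sc = 1.0 / np.sqrt(psi)
        Rs = R * np.outer(sc, sc)
        w, V = np.linalg.eigh(Rs)
        w, V = w[::-1], V[:, ::-1]
        lam = V[:, :k] * np.sqrt(np.maximum(w[:k] - 1.0, 0.0))
        return lam * np.sqrt(psi)[:, None], w

    def objective(psi):
        lam, w = loadings_for(psi)
        tail = np.maximum(w[k:], 1e-12)  # rank deficiency when n < p
        f = float(np.sum(tail - np.log(tail) - 1.0))
        g = np.diag(lam @ lam.T + np.diag(psi) - R) / psi ** 2
        return f, g

    inv_diag = np.diag(np.linalg.inv(R))
    psi0 = np.clip(1.0 / inv_diag, psi_floor * 2, 1.0)
    res = minimize(objective, psi0, jac=True, method="L-BFGS-B",
                   bounds=[(psi_floor, 1.0)] * p)
    psi = res.x
    if np.any(psi <= psi_floor * 1.01):
        warnings.warn("Heywood case: uniqueness hit its lower bound; "
                      "solution regularized at the bound", stacklevel=2)
    lam, _ = loadings_for(psi)
    # order factors by explained variance, largest coefficient positive
    order = np.argsort((lam ** 2).sum(axis=0))[::-1]
    lam = lam[:, order]
    for j in range(k):
        if lam[np.argmax(np.abs(lam[:, j])), j] < 0:
            lam[:, j] *= -1.0
    return lam, psi, bool(res.success)


@dataclass
class FactorModel:
    loadings: np.ndarray             # (m, k) promax pattern matrix
    phi: np.ndarray                  # (k, k) factor correlations
    uniquenesses: np.ndarray         # (m,)
    scores_regression: np.ndarray    # (n, k)
    scores_bartlett: np.ndarray      # (n, k)
    n_factors: int
    converged: bool


def cognitive_factors(
    Z,
    n_factors: int | None = None,
    kappa: float = 4.0,
    score_ridge: float = 0.0,
) -> FactorModel:
    """ML factor analysis of standardized measures with promax rotation.

    The factor count defaults to the Kaiser count (correlation-matrix
    eigenvalues > 1).  Both regression (Thurstone, optional ridge on the
    correlation matrix) and Bartlett factor scores are returned; regression
    scores are the default set entering CCA.
    """
    Z = np.asarray(Z, dtype=float)
    n, m = Z.shape
    R = np.corrcoef(Z, rowvar=False)
    if n_factors is None:
        n_factors = max(1, int(np.sum(np.linalg.eigvalsh(R) > 1.0)))
    lam, psi, ok = _ml_factor_loadings(R, n_factors)
    if n_factors > 1:
        pattern, phi, _ = promax(lam, kappa=kappa)
    else:
        pattern, phi = lam, np.ones((1, 1))
    # structure matrix = pattern @ phi gives covariances between measures and factors
    structure = pattern @ phi
    S_reg = np.linalg.solve(R + score_ridge * np.eye(m), structure)
    scores_reg = Z @ S_reg
    psi_inv = 1.0 / psi
    W = (psi_inv[:, None] * pattern) @ np.linalg.inv(pattern.T @ (psi_inv[:, None] * pattern))
    scores_bart = Z @ W
    return FactorModel(loadings=pattern, phi=phi, uniquenesses=psi,
                       scores_regression=scores_reg, scores_bartlett=scores_bart,
                       n_factors=n_factors, converged=ok)


# ---------------------------------------------------------------------------
# Covariate adjustment
# ---------------------------------------------------------------------------

def residualize(X, covariates, add_intercept: bool = True) -> np.ndarray:
    """OLS residuals of each column of X on the covariates (with intercept)."""
    X = np.asarray(X, dtype=float)
    C = np.asarray(covariates, dtype=float)
    if C.ndim == 1:
        C = C[:, None]
    D = np.column_stack([np.ones(len(C)), C]) if add_intercept else C
    if np.linalg.matrix_rank(D) < D.shape[1]:
        raise ValueError("covariate matrix is rank-deficient")
    beta, *_ = np.linalg.lstsq(D, X, rcond=None)
    return X - D @ beta


# ---------------------------------------------------------------------------
# CCA with parametric and permutation inference
# ---------------------------------------------------------------------------

@dataclass
class CCAResult:
    r: np.ndarray                    # canonical correlations, non-increasing
    u_scores: np.ndarray             # (n, modes)
    v_scores: np.ndarray             # (n, modes)
    weights_u: np.ndarray            # (p, modes): centered U @ weights = u_scores
    weights_v: np.ndarray
    parametric_p: np.ndarray         # Bartlett chi-square approximation per mode
    perm_p: np.ndarray | None = None
    null_r1: np.ndarray | None = None
    loadings_u: pd.DataFrame | None = None
    loadings_v: pd.DataFrame | None = None
    n_perm: int = 0
    seed: int | None = None


def _orth_basis(Xc: np.ndarray):
    """Orthonormal column basis of a centered matrix plus the back-mapping."""
    P, s, Qt = np.linalg.svd(Xc, full_matrices=False)
    tol = s[0] * max(Xc.shape) * np.finfo(float).eps if s.size else 0.0
    r = int(np.sum(s > tol))
    return P[:, :r], Qt[:r].T / s[:r], r


def cca(U, V) -> CCAResult:
    """Canonical correlation analysis via orthonormal-basis SVD.

    Scores have unit variance; weights map the centered inputs to scores.
    Parametric per-mode p-values use Bartlett's chi-square approximation of
    Wilks' lambda.
    """
    U = np.asarray(U, dtype=float)
    V = np.asarray(V, dtype=float)
    if U.shape[0] != V.shape[0]:
        raise ValueError("U and V must have the same number of rows")
    n, p = U.shape
    q = V.shape[1]
    if n <= p + q:
        warnings.warn(f"n={n} <= p+q={p + q}: canonical correlations will be inflated",
                      stacklevel=2)
    Uc = U - U.mean(axis=0)
    Vc = V - V.mean(axis=0)
    Bu, Tu, ru = _orth_basis(Uc)
    Bv, Tv, rv = _orth_basis(Vc)
    if ru < p or rv < q:
        warnings.warn("rank-deficient within-set covariance; "
                      "solving on the reduced-rank subspace", stacklevel=2)
    W, s, Zt = np.linalg.svd(Bu.T @ Bv)
    m = min(ru, rv)
    r = np.clip(s[:m], 0.0, 1.0)
    scale = np.sqrt(max(n - 1, 1))
    u_scores = Bu @ W[:, :m] * scale
    v_scores = Bv @ Zt.T[:, :m] * scale
    weights_u = Tu @ W[:, :m] * scale
    weights_v = Tv @ Zt.T[:, :m] * scale

    pvals = np.empty(m)
    c = n - 1 - (p + q + 1) / 2.0
    for k in range(m):
        lam = float(np.prod(1.0 - r[k:] ** 2))
        lam = min(max(lam, np.finfo(float).tiny), 1.0)
        chi2 = -c * np.log(lam)
        df = (p - k) * (q - k)
        pvals[k] = stats.chi2.sf(chi2, df) if df > 0 else np.nan
    return CCAResult(r=r, u_scores=u_scores, v_scores=v_scores,
                     weights_u=weights_u, weights_v=weights_v,
                     parametric_p=pvals)


def _block_permutation(labels, rng: np.random.Generator) -> np.ndarray:
    """Permute family blocks as units among blocks of equal size."""
    labels = np.asarray(labels)
    order: dict = {}
    fams: list[list[int]] = []
    for i, lab in enumerate(labels):
        if lab not in order:
            order[lab] = len(fams)
            fams.append([])
        fams[order[lab]].append(i)
    by_size: dict[int, list[list[int]]] = defaultdict(list)
    for fam in fams:
        by_size[len(fam)].append(fam)
    perm = np.empty(len(labels), dtype=np.int64)
    for fams_s in by_size.values():
        shuffled = [fams_s[j] for j in rng.permutation(len(fams_s))]
        for dst, src in zip(fams_s, shuffled):
            for a, b in zip(dst, src):
                perm[a] = b
    return perm


def permutation_test(
    U,
    V,
    n_perm: int = 10_000,
    seed: int | None = None,
    pair_labels=None,
) -> tuple[np.ndarray, np.ndarray]:
    """Permutation p-values for every canonical mode.

    Whole rows of U are permuted against a fixed V, preserving each subject's
    within-set feature coupling; with ``pair_labels``, family blocks move as
    units (twins are not exchangeable with unrelated singletons).  Each
    permutation's first canonical correlation forms the null, and mode k's
    p-value is ``(1 + #{null >= r_k}) / (n_perm + 1)`` (max-statistic control
    of familywise error across modes).
    """
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} is very small; p-values will be coarse",
                      stacklevel=2)
    U = np.asarray(U, dtype=float)
    V = np.asarray(V, dtype=float)
    n = U.shape[0]
    Uc = U - U.mean(axis=0)
    Vc = V - V.mean(axis=0)
    Bu, _, ru = _orth_basis(Uc)
    Bv, _, rv = _orth_basis(Vc)
    m = min(ru, rv)
    r_obs = np.clip(np.linalg.svd(Bu.T @ Bv, compute_uv=False)[:m], 0.0, 1.0)

    rng = np.random.default_rng(seed)
    null_r1 = np.empty(n_perm)
    for b in range(n_perm):
        perm = (_block_permutation(pair_labels, rng) if pair_labels is not None
                else rng.permutation(n))
        # row-permuting U permutes the rows of its orthonormal basis, so the
        # permuted CCA reduces to one small SVD
        null_r1[b] = np.linalg.svd(Bu[perm].T @ Bv, compute_uv=False)[0]
    perm_p = (1.0 + (null_r1[None, :] >= r_obs[:, None]).sum(axis=1)) / (n_perm + 1.0)
    return perm_p, null_r1


def canonical_loadings(scores, variables, names=None) -> pd.DataFrame:
    """Pearson correlation (with two-sided p) of each variable with a mode score."""
    s = np.asarray(scores, dtype=float).ravel()
    X = np.asarray(variables, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n = len(s)
    sc = s - s.mean()
    Xc = X - X.mean(axis=0)
    denom = np.sqrt((sc ** 2).sum() * (Xc ** 2).sum(axis=0))
    denom[denom == 0] = np.inf
    r = (Xc.T @ sc) / denom
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r ** 2, np.finfo(float).tiny))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    if names is None:
        names = [f"var_{j + 1}" for j in range(X.shape[1])]
    return pd.DataFrame({"variable": list(names), "r": r, "p": p})
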