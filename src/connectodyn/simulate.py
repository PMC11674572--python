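"""Synthetic cohorts with known state dynamics and a planted brain-behaviour mode.

Every downstream stage of the pipeline is validated by parameter recovery on
cohorts produced here: Markov state paths with subject-specific transition
matrices, Gaussian state-conditional amplitude envelopes per frequency band,
twin-pair block structure, age/sex covariates that confound both sides, and a
15-measure cognitive battery whose first latent factor carries a linear
combination of transition-probability features calibrated so the population
first canonical correlation equals ``planted_mode_r``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_BANDS",
    "SyntheticConfig",
    "GroundTruth",
    "Cohort",
    "make_transition_matrix",
    "make_state_means",
    "stationary_distribution",
    "gen_state_sequence",
    "gen_envelopes",
    "gen_raw_signals",
    "gen_cognition",
    "gen_cohort",
]

#: Heritable-phenotype band grid (name, low Hz, high Hz).
DEFAULT_BANDS = (
    ("theta", 4.0, 7.0),
    ("alpha", 8.0, 12.0),
    ("beta", 13.0, 25.0),
    ("gamma", 30.0, 45.0),
)


def make_transition_matrix(K: int, stay: float = 0.8) -> np.ndarray:
    """Sticky row-stochastic matrix with common diagonal ``stay``."""
    if not 0.0 < stay < 1.0:
        raise ValueError("stay probability must be in (0, 1)")
    A = np.full((K, K), (1.0 - stay) / (K - 1)) if K > 1 else np.ones((1, 1))
    if K > 1:
        np.fill_diagonal(A, stay)
    return A


def make_state_means(K: int, R: int, separation: float, rng: np.random.Generator) -> np.ndarray:
    """K state mean vectors in R dims with pairwise distance ``separation``.

    Means sit on mutually orthogonal random directions scaled so that any two
    means are ``separation`` apart (requires R >= K).
    """
    if R < K:
        raise ValueError("need at least as many regions as states for orthogonal means")
    Q, _ = np.linalg.qr(rng.standard_normal((R, K)))
    return (separation / np.sqrt(2.0)) * Q.T


def stationary_distribution(A: np.ndarray) -> np.ndarray:
    """Stationary distribution of an irreducible row-stochastic matrix."""
    w, v = np.linalg.eig(A.T)
    i = int(np.argmin(np.abs(w - 1.0)))
    pi = np.real(v[:, i])
    pi = np.abs(pi)
    return pi / pi.sum()


def _check_stochastic(A: np.ndarray, name: str, atol: float = 1e-12) -> None:
    A = np.asarray(A, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError(f"{name} must be square")
    if np.any(A < -atol):
        raise ValueError(f"{name} has negative entries")
    if not np.allclose(A.sum(axis=1), 1.0, atol=1e-10):
        raise ValueError(f"{name} rows must sum to 1")


def _check_simplex(p: np.ndarray, name: str) -> None:
    p = np.asarray(p, dtype=float)
    if np.any(p < 0) or not np.isclose(p.sum(), 1.0, atol=1e-10):
        raise ValueError(f"{name} must lie on the probability simplex")


@dataclass
class SyntheticConfig:
    """Cohort-level generative settings.

    Defaults mirror the study conditions the pipeline targets: 926 paired
    subjects, six states, the four heritable bands, 6 minutes of envelope data
    at 40 Hz, 15 cognitive measures with a 5-factor structure, and a planted
    canonical mode of 0.25.  Desk-scale analyses pass smaller values.
    """

    n_subjects: int = 926
    n_regions: int = 10
    K: int = 6
    T: int = 14_400
    fs_env: float = 40.0
    bands: tuple = DEFAULT_BANDS
    transition_matrix: np.ndarray | None = None
    initial_dist: np.ndarray | None = None
    state_means: np.ndarray | None = None
    state_covs: np.ndarray | None = None
    separation: float = 3.0
    stay_prob: float = 0.8
    n_measures: int = 15
    n_factors: int = 5
    planted_mode_r: float = 0.25
    noise_sd: float = 0.5
    pair_fraction: float = 1.0
    twin_rho: float = 0.5
    subject_tp_sd: float = 0.3
    tp_variation_rank: int = 2
    tp_link_entries: int = 3
    age_tp_coef: float = 0.1
    link_band: str | None = None
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.transition_matrix is not None:
            self.transition_matrix = np.asarray(self.transition_matrix, dtype=float)
            _check_stochastic(self.transition_matrix, "transition_matrix")
            if self.transition_matrix.shape[0] != self.K:
                raise ValueError("transition_matrix size must match K")
        if self.initial_dist is not None:
            self.initial_dist = np.asarray(self.initial_dist, dtype=float)
            _check_simplex(self.initial_dist, "initial_dist")
        if self.state_covs is not None:
            self.state_covs = np.asarray(self.state_covs, dtype=float)
            for k, C in enumerate(self.state_covs):
                if not np.allclose(C, C.T, atol=1e-10):
                    raise ValueError(f"state cov {k} not symmetric")
                if np.linalg.eigvalsh(C).min() <= 0:
                    raise ValueError(f"state cov {k} not positive-definite")
        if not 0.0 <= self.planted_mode_r < 1.0:
            raise ValueError("planted_mode_r must be in [0, 1)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if not 0.0 <= self.pair_fraction <= 1.0:
            raise ValueError("pair_fraction must be in [0, 1]")

    def resolve(self, rng: np.random.Generator):
        """Fill in derived defaults (base chain, state geometry)."""
        A = self.transition_matrix
        if A is None:
            A = make_transition_matrix(self.K, self.stay_prob)
        pi = self.initial_dist
        if pi is None:
            pi = stationary_distribution(A)
        means = self.state_means
        if means is None:
            means = make_state_means(self.K, self.n_regions, self.separation, rng)
        covs = self.state_covs
        if covs is None:
            covs = np.broadcast_to(np.eye(self.n_regions), (self.K, self.n_regions, self.n_regions)).copy()
        return A, pi, np.asarray(means, float), np.asarray(covs, float)


@dataclass
class GroundTruth:
    """Oracle quantities for recovery tests."""

    state_paths: dict[str, np.ndarray]           # band -> (n_subjects, T) int
    true_fo: dict[str, np.ndarray]               # band -> (n_subjects, K)
    true_tp: dict[str, np.ndarray]               # band -> (n_subjects, K, K)
    tp_latents: dict[str, np.ndarray]            # band -> (n_subjects, rank)
    mode_weights_u: np.ndarray | None            # raw-feature-space weights (link band TP off-diagonals)
    mode_weights_v: np.ndarray | None            # measure-space weights of the planted mode
    planted_support: np.ndarray | None           # indices of TP off-diag features carrying the mode
    link_band: str | None
    factor_loadings: np.ndarray | None
    pair_labels: np.ndarray
    age: np.ndarray
    sex: np.ndarray


@dataclass
class Cohort:
    config: SyntheticConfig
    envelopes: dict[str, list[np.ndarray]]       # band -> per-subject (T, R) arrays
    cognition: pd.DataFrame
    covariates: pd.DataFrame
    truth: GroundTruth


# ---------------------------------------------------------------------------
# Elementary generators
# ---------------------------------------------------------------------------

def gen_state_sequence(A, pi, T: int, rng) -> np.ndarray:
    """Sample a length-T Markov chain path (0-based state indices)."""
    A = np.asarray(A, dtype=float)
    _check_stochastic(A, "A")
    _check_simplex(pi, "pi")
    if T < 1:
        raise ValueError("T must be >= 1")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    cum = np.cumsum(A, axis=1)
    u = rng.random(T)
    path = np.empty(T, dtype=np.int64)
    path[0] = np.searchsorted(np.cumsum(pi), u[0], side="right")
    for t in range(1, T):
        path[t] = np.searchsorted(cum[path[t - 1]], u[t], side="right")
    np.clip(path, 0, A.shape[0] - 1, out=path)
    return path


def gen_envelopes(path, means, covs, rng, rectify: bool = False) -> np.ndarray:
    """State-conditional Gaussian emissions along a path: (T, R) matrix."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    path = np.asarray(path)
    means = np.asarray(means, dtype=float)
    covs = np.asarray(covs, dtype=float)
    K, R = means.shape
    chols = np.empty_like(covs)
    for k in range(K):
        try:
            chols[k] = np.linalg.cholesky(covs[k])
        except np.linalg.LinAlgError as exc:
            raise ValueError(f"state covariance {k} not positive-definite") from exc
    z = rng.standard_normal((path.shape[0], R))
    out = np.empty_like(z)
    for k in range(K):
        idx = np.flatnonzero(path == k)
        if idx.size:
            out[idx] = means[k] + z[idx] @ chols[k].T
    if rectify:
        np.abs(out, out=out)
    return out


def gen_raw_signals(envelope, fs_env: float, band, fs_raw: float, rng) -> np.ndarray:
    """Amplitude-modulated band-centred carriers from an envelope matrix.

    ``envelope`` is (T_env, R) sampled at ``fs_env``; the output is (T_raw, R)
    at ``fs_raw`` where each region is a sinusoid at its own carrier frequency
    (drawn from the central 80% of the band, random phase) multiplied by the
    linearly upsampled envelope.  Distinct carriers keep regions from being
    mutually collinear, as distinct neural populations are.  Recovering the
    envelope via bandpass + Hilbert is the end-to-end test of the signal-prep
    chain.
    """
    lo, hi = float(band[0]), float(band[1])
    if fs_raw < 4.0 * hi:
        raise ValueError("fs_raw must be at least 4x the band upper edge")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    env = np.asarray(envelope, dtype=float)
    T_env, R = env.shape
    duration = T_env / fs_env
    T_raw = int(round(duration * fs_raw))
    t_env = np.arange(T_env) / fs_env
    t_raw = np.arange(T_raw) / fs_raw
    width = hi - lo
    fc = rng.uniform(lo + 0.1 * width, hi - 0.1 * width, size=R)
    phases = rng.uniform(0.0, 2.0 * np.pi, size=R)
    out = np.empty((T_raw, R))
    for r in range(R):
        a = np.interp(t_raw, t_env, env[:, r])
        out[:, r] = a * np.sin(2.0 * np.pi * fc[r] * t_raw + phases[r])
    return out


# ---------------------------------------------------------------------------
# Cognition with a planted canonical mode
# ---------------------------------------------------------------------------

def _default_loadings(m: int, k: int, rng: np.random.Generator) -> np.ndarray:
    """Simple-structure loading matrix: each measure has one primary factor."""
    L = rng.normal(0.0, 0.05, size=(m, k))
    primary = np.arange(m) % k
    L[np.arange(m), primary] = rng.uniform(0.6, 0.85, size=m)
    return L


def gen_cognition(
    features,
    *,
    n_measures: int = 15,
    n_factors: int = 5,
    planted_mode_r: float = 0.25,
    noise_sd: float = 0.5,
    rng,
    loadings: np.ndarray | None = None,
    mode_weights: np.ndarray | None = None,
    missing_rate: float = 0.0,
    age=None,
    sex=None,
    age_beta_scale: float = 0.3,
    sex_beta_scale: float = 0.2,
    pair_labels=None,
    twin_rho: float = 0.0,
):
    """Cognitive measures whose factor 1 carries a planted feature combination.

    ``features`` must be column-standardized (subjects x p).  The planted link
    strength alpha is chosen so that, in the population, the first canonical
    correlation between features and measures equals ``planted_mode_r``:
    corr(best measure combination, factor 1) = rho (the multiple correlation
    of factor 1 with the measures, computable from loadings and noise), and
    factor 1 = alpha * s + sqrt(1 - alpha^2) * e with alpha = r / rho.

    Returns (measures ndarray with NaN for missing, truth dict).
    """
    if not 0.0 <= planted_mode_r < 1.0:
        raise ValueError("planted_mode_r must be in [0, 1)")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    X = np.asarray(features, dtype=float)
    n, p = X.shape
    L = _default_loadings(n_measures, n_factors, rng) if loadings is None else np.asarray(loadings, float)
    m, k = L.shape

    if mode_weights is None:
        w = rng.standard_normal(p)
    else:
        w = np.asarray(mode_weights, dtype=float)
    s = X @ w
    sd = s.std()
    if sd > 0:
        s = s / sd

    # latent factors: twin-correlated unique parts when pair labels are given
    def _latent(size):
        e = rng.standard_normal((n, size))
        if pair_labels is not None and twin_rho > 0:
            labels = np.asarray(pair_labels)
            fam = {}
            shared = np.empty((n, size))
            for i, lab in enumerate(labels):
                if lab not in fam:
                    fam[lab] = rng.standard_normal(size)
                shared[i] = fam[lab]
            e = np.sqrt(twin_rho) * shared + np.sqrt(1.0 - twin_rho) * e
        return e

    F = _latent(k)
    alpha = 0.0
    if planted_mode_r > 0:
        sigma_m = L @ L.T + (noise_sd ** 2) * np.eye(m)
        l0 = L[:, 0]
        rho = float(np.sqrt(l0 @ np.linalg.pinv(sigma_m) @ l0))
        alpha = planted_mode_r / rho
        if alpha >= 1.0:
            raise ValueError(
                f"planted_mode_r={planted_mode_r} unreachable: measure-side ceiling rho={rho:.3f}"
            )
        F[:, 0] = alpha * s + np.sqrt(1.0 - alpha ** 2) * F[:, 0]

    M = F @ L.T + noise_sd * rng.standard_normal((n, m))

    age_beta = sex_beta = None
    if age is not None:
        age_z = (np.asarray(age, float) - np.mean(age)) / (np.std(age) + 1e-12)
        age_beta = age_beta_scale * rng.standard_normal(m)
        M += np.outer(age_z, age_beta)
    if sex is not None:
        sex_c = np.asarray(sex, float) - np.mean(sex)
        sex_beta = sex_beta_scale * rng.standard_normal(m)
        M += np.outer(sex_c, sex_beta)

    if missing_rate > 0:
        mask = rng.random((n, m)) < missing_rate
        M = M.copy()
        M[mask] = np.nan

    # measure-side weights of the planted mode: best linear estimator of f1
    mode_v = None
    if planted_mode_r > 0:
        mode_v = np.linalg.pinv(L @ L.T + (noise_sd ** 2) * np.eye(m)) @ L[:, 0]
    truth = {
        "loadings": L,
        "mode_weights_u": w,
        "mode_weights_v": mode_v,
        "alpha": alpha,
        "planted_s": s,
        "factors": F,
        "age_beta": age_beta,
        "sex_beta": sex_beta,
    }
    return M, truth


# ---------------------------------------------------------------------------
# Full cohort
# ---------------------------------------------------------------------------

def _offdiag_index(K: int) -> np.ndarray:
    """Row-major off-diagonal flat indices of a K x K matrix."""
    idx = np.arange(K * K).reshape(K, K)
    mask = ~np.eye(K, dtype=bool)
    return idx[mask]


def _empirical_tp(path: np.ndarray, K: int) -> np.ndarray:
    counts = np.zeros((K, K))
    np.add.at(counts, (path[:-1], path[1:]), 1.0)
    rows = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        tp = np.where(rows > 0, counts / rows, 1.0 / K)
    return tp


def _residualize_cols(X: np.ndarray, C: np.ndarray) -> np.ndarray:
    D = np.column_stack([np.ones(len(X)), C])
    beta, *_ = np.linalg.lstsq(D, X, rcond=None)
    return X - D @ beta


def gen_cohort(config: SyntheticConfig, make_envelopes: bool = True) -> Cohort:
    """Generate a full multi-band cohort with ground truth at every level.

    Per-subject transition matrices vary around the base chain through a
    low-rank set of fixed log-domain perturbation directions (twin-shared and
    age-linked components included); the first direction's off-diagonal
    footprint defines the planted TP feature set for the cognitive mode.
    """
    ss = np.random.SeedSequence(config.seed)
    r_struct, r_paths, r_env, r_cog, r_cov = [np.random.default_rng(s) for s in ss.spawn(5)]

    n, K = config.n_subjects, config.K
    A, pi, means, covs = config.resolve(r_struct)

    # --- pair structure and covariates (twins share sex and age) ------------
    n_pairs = int(np.floor(config.pair_fraction * n / 2.0))
    pair_labels = np.empty(n, dtype=np.int64)
    pair_labels[: 2 * n_pairs] = np.repeat(np.arange(n_pairs), 2)
    pair_labels[2 * n_pairs:] = np.arange(n_pairs, n_pairs + (n - 2 * n_pairs))
    age = np.empty(n)
    sex = np.empty(n, dtype=np.int64)
    fam_age = r_cov.uniform(23.0, 40.0, size=n_pairs + (n - 2 * n_pairs))
    fam_sex = r_cov.integers(0, 2, size=n_pairs + (n - 2 * n_pairs))
    for i in range(n):
        age[i] = fam_age[pair_labels[i]]
        sex[i] = fam_sex[pair_labels[i]]
    age_z = (age - age.mean()) / (age.std() + 1e-12)

    # --- low-rank subject variation in the transition matrix ----------------
    rank = max(1, config.tp_variation_rank)
    dirs = np.zeros((rank, K, K))
    offd = _offdiag_index(K)
    # direction 1: sparse, entries in distinct rows -> the planted features
    n_link = min(config.tp_link_entries, K)
    rows = r_struct.permutation(K)[:n_link]
    support = []
    for j, row in enumerate(rows):
        cols = [c for c in range(K) if c != row]
        col = cols[int(r_struct.integers(0, len(cols)))]
        dirs[0, row, col] = 1.0 if j % 2 == 0 else -1.0
        support.append(row * K + col)
    for q in range(1, rank):
        D = r_struct.standard_normal((K, K))
        np.fill_diagonal(D, 0.0)
        dirs[q] = D / np.linalg.norm(D)
    D_age = r_struct.standard_normal((K, K))
    np.fill_diagonal(D_age, 0.0)
    D_age /= np.linalg.norm(D_age)

    def subject_chain(eta: np.ndarray, a_z: float) -> np.ndarray:
        logA = np.log(A) + config.subject_tp_sd * np.tensordot(eta, dirs, axes=1)
        logA += config.age_tp_coef * a_z * D_age
        Ai = np.exp(logA)
        return Ai / Ai.sum(axis=1, keepdims=True)

    # analytic sensitivity of TP entries to the first latent direction
    sens = A * (dirs[0] - (A * dirs[0]).sum(axis=1, keepdims=True))
    mode_w_raw = sens.reshape(-1)[offd]

    band_names = [b[0] for b in config.bands]
    link_band = config.link_band or ("alpha" if "alpha" in band_names else band_names[0])
    if link_band not in band_names:
        raise ValueError(f"link_band {link_band!r} not among bands")

    state_paths: dict[str, np.ndarray] = {}
    true_fo: dict[str, np.ndarray] = {}
    true_tp: dict[str, np.ndarray] = {}
    tp_latents: dict[str, np.ndarray] = {}
    envelopes: dict[str, list[np.ndarray]] = {}

    for band in band_names:
        eta = r_paths.standard_normal((n, rank))
        if config.twin_rho > 0 and n_pairs > 0:
            shared = r_paths.standard_normal((n_pairs + (n - 2 * n_pairs), rank))
            eta = (np.sqrt(config.twin_rho) * shared[pair_labels]
                   + np.sqrt(1.0 - config.twin_rho) * eta)
        paths = np.empty((n, config.T), dtype=np.int64)
        fo = np.empty((n, K))
        tp = np.empty((n, K, K))
        env_list: list[np.ndarray] = []
        for i in range(n):
            Ai = subject_chain(eta[i], age_z[i])
            tp[i] = Ai
            fo[i] = stationary_distribution(Ai)
            paths[i] = gen_state_sequence(Ai, pi, config.T, r_paths)
            if make_envelopes:
                env_list.append(gen_envelopes(paths[i], means, covs, r_env))
        state_paths[band] = paths
        true_fo[band] = fo
        true_tp[band] = tp
        tp_latents[band] = eta
        if make_envelopes:
            envelopes[band] = env_list

    # --- cognition planted on realized TP features of the link band ---------
    feats = np.stack([
        _empirical_tp(state_paths[link_band][i], K).reshape(-1)[offd] for i in range(n)
    ])
    feats = _residualize_cols(feats, np.column_stack([age_z, sex]))
    col_sd = feats.std(axis=0)
    col_sd[col_sd == 0] = 1.0
    feats_std = (feats - feats.mean(axis=0)) / col_sd
    # planted combination expressed in standardized-column space
    w_std = mode_w_raw * col_sd

    M, cog_truth = gen_cognition(
        feats_std,
        n_measures=config.n_measures,
        n_factors=config.n_factors,
        planted_mode_r=config.planted_mode_r,
        noise_sd=config.noise_sd,
        rng=r_cog,
        mode_weights=w_std,
        missing_rate=config.missing_rate,
        age=age,
        sex=sex,
        pair_labels=pair_labels,
        twin_rho=config.twin_rho,
    )

    cognition = pd.DataFrame(M, columns=[f"measure_{j + 1:02d}" for j in range(config.n_measures)])
    cognition.insert(0, "subject", [f"sub-{i + 1:04d}" for i in range(n)])
    covariates = pd.DataFrame({
        "subject": cognition["subject"],
        "age": age,
        "sex": sex,
        "family": pair_labels,
    })

    truth = GroundTruth(
        state_paths=state_paths,
        true_fo=true_fo,
        true_tp=true_tp,
        tp_latents=tp_latents,
        mode_weights_u=mode_w_raw,
        mode_weights_v=cog_truth["mode_weights_v"],
        planted_support=np.array([int(np.flatnonzero(offd == s)[0]) for s in support]),
        link_band=link_band,
        factor_loadings=cog_truth["loadings"],
        pair_labels=pair_labels,
        age=age,
        sex=sex,
    )
    return Cohort(config=config, envelopes=envelopes, cognition=cognition,
                  covariates=covariates, truth=truth)
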