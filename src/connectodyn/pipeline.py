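"""End-to-end orchestration: simulate -> fit -> phenotypes -> associate.

One HMM is fit per frequency band across all subjects jointly, each subject is
decoded individually, band-specific phenotype vectors are reduced by PCA and
aggregated into U (band order as configured), cognition is reduced to promax
factor scores (V), and the two sides enter covariate-adjusted CCA with
permutation inference.
"""

from __future__ import annotations

import datetime
import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .association import (
    CCAResult,
    FactorModel,
    PCAResult,
    bandwise_pca,
    canonical_loadings,
    cca,
    cognitive_factors,
    permutation_test,
    residualize,
    variance_contribution,
    zscore_table,
)
from .phenotypes import assemble_phenotype_vector, phenotype_table, phenotypes_from_stc
from .simulate import Cohort, SyntheticConfig, gen_cohort
from .state_model import HMMParams, StateTimeCourse, fit_hmm

__all__ = ["PipelineConfig", "AssociationOutput", "PipelineResult",
           "associate_stage", "run_pipeline", "DEFAULT_BAND_ROLES"]

#: Heritable-phenotype selection: which feature set each band contributes.
DEFAULT_BAND_ROLES = {
    "theta": "tp_only",
    "alpha": "tp_only",
    "beta": "fo_only",
    "gamma": "composite",
}


@dataclass
class PipelineConfig:
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    band_roles: dict = field(default_factory=lambda: dict(DEFAULT_BAND_ROLES))
    n_restarts: int = 3
    max_iter: int = 100
    n_perm: int = 10_000
    kappa: float = 4.0
    tp_method: str = "soft"
    n_factors: int | None = None
    use_family_blocks: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        band_names = {b[0] for b in self.synthetic.bands}
        missing = band_names - set(self.band_roles)
        if missing:
            raise ValueError(f"band_roles missing entries for bands: {sorted(missing)}")


@dataclass
class AssociationOutput:
    U: np.ndarray
    u_names: list[str]
    band_of_column: list[str]
    pca: dict[str, PCAResult]
    factors: FactorModel
    cca_result: CCAResult
    variance_contrib: dict[str, pd.DataFrame]
    kept_subjects: list[str]


@dataclass
class PipelineResult:
    config: PipelineConfig
    cohort: Cohort
    hmm: dict[str, HMMParams]
    stcs: dict[str, list[StateTimeCourse]]
    phenotypes: pd.DataFrame
    association: AssociationOutput
    provenance: dict


def _role_columns(columns, role: str):
    tp_cols = [c for c in columns if c.startswith("TP")]
    fo_cols = [c for c in columns if c.startswith("FO")]
    if role == "tp_only":
        return tp_cols
    if role == "fo_only":
        return fo_cols
    if role == "composite":
        return tp_cols + fo_cols
    raise ValueError(f"unknown band role {role!r}")


def associate_stage(
    pheno_df: pd.DataFrame,
    cognition: pd.DataFrame,
    covariates: pd.DataFrame,
    band_roles: dict,
    band_order: list[str],
    *,
    n_perm: int = 10_000,
    seed: int = 0,
    kappa: float = 4.0,
    n_factors: int | None = None,
    use_family_blocks: bool = False,
) -> AssociationOutput:
    """Association analysis from a long phenotype table and a cognition table.

    ``pheno_df`` has columns subject, band, TPi-j..., FOk...; ``cognition``
    has a subject column plus measure columns (missing values allowed);
    ``covariates`` has subject, age, sex and optionally family.
    """
    measures = cognition.drop(columns=["subject"])
    Z_cog, info = zscore_table(measures, max_missing_frac=0.5)
    kept = cognition["subject"].to_numpy()[info["kept_subjects"]]

    blocks_u = []
    u_names: list[str] = []
    band_of_column: list[str] = []
    pca_by_band: dict[str, PCAResult] = {}
    var_contrib: dict[str, pd.DataFrame] = {}
    feature_cols_by_band: dict[str, list[str]] = {}

    feature_cols = [c for c in pheno_df.columns if c not in ("subject", "band")]
    for band in band_order:
        sub = pheno_df[pheno_df["band"] == band].set_index("subject")
        sub = sub.loc[kept]
        cols = _role_columns(feature_cols, band_roles[band])
        X = sub[cols].to_numpy(dtype=float)
        Z, _ = zscore_table(X, max_missing_frac=1.0)
        pca = bandwise_pca(Z)
        pca_by_band[band] = pca
        feature_cols_by_band[band] = cols
        blocks_u.append(pca.scores)
        u_names += [f"{band}_PC{j + 1}" for j in range(pca.n_retained)]
        band_of_column += [band] * pca.n_retained
        # percent of TP / FO feature variance captured by each retained PC
        tp_idx = [i for i, c in enumerate(cols) if c.startswith("TP")]
        fo_idx = [i for i, c in enumerate(cols) if c.startswith("FO")]
        rows = {"pc": [f"PC{j + 1}" for j in range(pca.n_retained)]}
        if tp_idx:
            rows["tp_pct"] = variance_contribution(pca.coeffs, pca.eigenvalues, tp_idx)
        if fo_idx:
            rows["fo_pct"] = variance_contribution(pca.coeffs, pca.eigenvalues, fo_idx)
        var_contrib[band] = pd.DataFrame(rows)
    U = np.hstack(blocks_u)

    factors = cognitive_factors(np.asarray(Z_cog, dtype=float),
                                n_factors=n_factors, kappa=kappa)
    V = factors.scores_regression

    cov = covariates.set_index("subject").loc[kept]
    C = cov[["age", "sex"]].to_numpy(dtype=float)
    U_adj = residualize(U, C)
    V_adj = residualize(V, C)

    result = cca(U_adj, V_adj)
    labels = cov["family"].to_numpy() if (use_family_blocks and "family" in cov) else None
    result.perm_p, result.null_r1 = permutation_test(
        U_adj, V_adj, n_perm=n_perm, seed=seed, pair_labels=labels
    )
    result.n_perm = n_perm
    result.seed = seed
    result.loadings_u = canonical_loadings(result.u_scores[:, 0], U_adj, names=u_names)
    result.loadings_v = canonical_loadings(
        result.v_scores[:, 0], V_adj,
        names=[f"factor_{j + 1}" for j in range(V.shape[1])],
    )
    return AssociationOutput(U=U, u_names=u_names, band_of_column=band_of_column,
                             pca=pca_by_band, factors=factors, cca_result=result,
                             variance_contrib=var_contrib, kept_subjects=list(kept))


def _config_hash(config: PipelineConfig) -> str:
    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        return str(o)

    payload = json.dumps(asdict(config), sort_keys=True, default=default)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig, cohort: Cohort | None = None) -> PipelineResult:
    """Run simulate -> fit -> phenotypes -> associate, deterministically per seed."""
    t0 = datetime.datetime.now().isoformat(timespec="seconds")
    if cohort is None:
        cohort = gen_cohort(config.synthetic)
    bands = [b[0] for b in config.synthetic.bands]
    K = config.synthetic.K

    hmm_by_band: dict[str, HMMParams] = {}
    stc_by_band: dict[str, list[StateTimeCourse]] = {}
    phenos = []
    fit_seeds = {}
    subject_ids = list(cohort.cognition["subject"])
    for bi, band in enumerate(bands):
        fit_seed = int(np.random.SeedSequence([config.seed, bi]).generate_state(1)[0] % (2 ** 31))
        fit_seeds[band] = fit_seed
        params, stcs = fit_hmm(
            cohort.envelopes[band], K,
            n_restarts=config.n_restarts, max_iter=config.max_iter,
            seed=fit_seed, subject_ids=subject_ids,
        )
        hmm_by_band[band] = params
        stc_by_band[band] = stcs
        phenos += [phenotypes_from_stc(s, band, method=config.tp_method) for s in stcs]
    pheno_df = phenotype_table(phenos)

    assoc_seed = int(np.random.SeedSequence([config.seed, 10_000]).generate_state(1)[0] % (2 ** 31))
    association = associate_stage(
        pheno_df, cohort.cognition, cohort.covariates,
        config.band_roles, bands,
        n_perm=config.n_perm, seed=assoc_seed, kappa=config.kappa,
        n_factors=config.n_factors, use_family_blocks=config.use_family_blocks,
    )

    provenance = {
        "started": t0,
        "finished": datetime.datetime.now().isoformat(timespec="seconds"),
        "config_hash": _config_hash(config),
        "master_seed": config.seed,
        "fit_seeds": fit_seeds,
        "association_seed": assoc_seed,
        "n_subjects_in": len(subject_ids),
        "n_subjects_after_missing_filter": len(association.kept_subjects),
        "n_pcs_per_band": {b: association.pca[b].n_retained for b in bands},
        "n_factors": association.factors.n_factors,
    }
    return PipelineResult(config=config, cohort=cohort, hmm=hmm_by_band,
                          stcs=stc_by_band, phenotypes=pheno_df,
                          association=association, provenance=provenance)
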