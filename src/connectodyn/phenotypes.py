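"""Per-subject temporal phenotypes of state dynamics: FO and TP vectors.

Fractional Occupancy (FO) is the proportion of total time spent in each state
(a length-K simplex vector); Transition Probability (TP) is the row-stochastic
K x K matrix of switching probabilities between ordered state pairs.  For the
band-specific feature vectors entering dimensionality reduction, the TP
off-diagonals are taken row-major (30 entries at K = 6), FO contributes K
entries, and the composite role concatenates both (36 at K = 6).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .state_model import StateTimeCourse

__all__ = [
    "TemporalPhenotypes",
    "PhenotypeVector",
    "fractional_occupancy",
    "transition_probability",
    "phenotypes_from_stc",
    "assemble_phenotype_vector",
    "phenotype_table",
    "tp_feature_names",
]

BAND_ROLES = ("tp_only", "fo_only", "composite")


@dataclass
class TemporalPhenotypes:
    subject_id: str
    band: str
    fo: np.ndarray                 # (K,) simplex
    tp: np.ndarray                 # (K, K) row-stochastic
    visited: np.ndarray            # (K,) bool, False where a state was never occupied


@dataclass
class PhenotypeVector:
    subject_id: str
    band: str
    values: np.ndarray
    feature_names: tuple[str, ...]


def fractional_occupancy(stc: StateTimeCourse) -> np.ndarray:
    """FO_k = time-average of the posterior probability of state k."""
    if stc.gamma.shape[0] == 0:
        raise ValueError("empty state time course")
    fo = stc.gamma.mean(axis=0)
    return fo / fo.sum()


def transition_probability(
    stc: StateTimeCourse,
    method: str = "soft",
    eps: float = 1e-8,
) -> tuple[np.ndarray, np.ndarray]:
    """Row-normalized transition matrix and per-state visited mask.

    ``soft`` uses expected transition counts from the posterior (default;
    lower variance at short T); ``viterbi`` counts hard transitions along the
    decoded path.  Rows with (near-)zero outgoing mass are set uniform and
    flagged unvisited.
    """
    K = stc.gamma.shape[1]
    if method == "soft":
        counts = np.asarray(stc.xi_sum, dtype=float)
    elif method == "viterbi":
        counts = np.zeros((K, K))
        np.add.at(counts, (stc.viterbi[:-1], stc.viterbi[1:]), 1.0)
    else:
        raise ValueError(f"unknown method {method!r}")
    rows = counts.sum(axis=1)
    visited = rows >= eps
    tp = np.full((K, K), 1.0 / K)
    if visited.any():
        tp[visited] = counts[visited] / rows[visited, None]
    return tp, visited


def phenotypes_from_stc(stc: StateTimeCourse, band: str, method: str = "soft") -> TemporalPhenotypes:
    tp, visited = transition_probability(stc, method=method)
    return TemporalPhenotypes(subject_id=stc.subject_id, band=band,
                              fo=fractional_occupancy(stc), tp=tp, visited=visited)


def tp_feature_names(K: int) -> tuple[str, ...]:
    """Row-major off-diagonal names in the TP1-2 convention (1-based)."""
    return tuple(f"TP{i + 1}-{j + 1}" for i in range(K) for j in range(K) if i != j)


def assemble_phenotype_vector(pheno: TemporalPhenotypes, band_role: str) -> PhenotypeVector:
    """Band feature vector: TP off-diagonals, FO entries, or their composite."""
    if band_role not in BAND_ROLES:
        raise ValueError(f"unknown band role {band_role!r}; expected one of {BAND_ROLES}")
    K = pheno.fo.shape[0]
    mask = ~np.eye(K, dtype=bool)
    tp_vals = pheno.tp[mask]           # row-major off-diagonals
    tp_names = tp_feature_names(K)
    fo_names = tuple(f"FO{k + 1}" for k in range(K))
    if band_role == "tp_only":
        values, names = tp_vals, tp_names
    elif band_role == "fo_only":
        values, names = pheno.fo.copy(), fo_names
    else:
        values = np.concatenate([tp_vals, pheno.fo])
        names = tp_names + fo_names
    return PhenotypeVector(subject_id=pheno.subject_id, band=pheno.band,
                           values=np.asarray(values, float), feature_names=names)


def phenotype_table(phenos: list[TemporalPhenotypes]) -> pd.DataFrame:
    """Long table: one row per subject x band with TPi-j and FOk columns."""
    rows = []
    for ph in phenos:
        vec = assemble_phenotype_vector(ph, "composite")
        row = {"subject": ph.subject_id, "band": ph.band}
        row.update(dict(zip(vec.feature_names, vec.values)))
        rows.append(row)
    return pd.DataFrame(rows)
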