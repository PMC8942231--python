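"""Structural distances between reconstructions, their STATIS compromise,
and Mantel correlation against an external distance matrix.

Nine structural quantities are implemented: Jaccard distances on the sets of
metabolites, reactions, E.C. numbers, genes, and dead-end metabolites; a
normalized difference in the number of dead-end metabolites; rank-correlation
distances of E.C.-number occurrence and cofactor usage; and the SVD distance
between stoichiometric-matrix spectra.  An ensemble of such matrices is
combined by STATIS: pairwise Rv coefficients between the double-centered
matrices define weights (the first eigenvector of the Rv matrix, scaled to
sum 1), and the compromise is the weighted average of the input matrices.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy.linalg import svdvals
from scipy.stats import spearmanr

from .model_core import FLUX_EPS, MetabolicModel

#: Default cofactor identifiers (MNXref namespace) for the cofactor-usage
#: measure; configurable because reconstructions differ in their currency
#: metabolite vocabulary.
DEFAULT_COFACTORS = (
    "MNXM3",    # ATP
    "MNXM7",    # ADP
    "MNXM14",   # AMP
    "MNXM8",    # NAD+
    "MNXM10",   # NADH
    "MNXM5",    # NADP+
    "MNXM6",    # NADPH
    "MNXM33",   # FAD
    "MNXM38",   # FADH2
    "MNXM12",   # CoA
    "MNXM1",    # H+
    "MNXM2",    # H2O
)


@dataclass
class DistanceEnsemble:
    labels: list[str]
    matrices: list[np.ndarray]
    measure_names: list[str]

    def __post_init__(self) -> None:
        n = len(self.labels)
        for name, m in zip(self.measure_names, self.matrices):
            if m.shape != (n, n):
                raise ValueError(f"matrix {name} has shape {m.shape}, expected {(n, n)}")
            if np.abs(m - m.T).max() > 1e-12:
                raise ValueError(f"matrix {name} is not symmetric")
            if np.abs(np.diag(m)).max() > 0:
                raise ValueError(f"matrix {name} has nonzero diagonal")


@dataclass
class StatisResult:
    weights: np.ndarray
    rv_matrix: np.ndarray
    compromise: np.ndarray


# ---------------------------------------------------------------------------
# Elementary distances
# ---------------------------------------------------------------------------


def jaccard_distance(set_a: Iterable, set_b: Iterable) -> float:
    """1 − |A∩B| / |A∪B|; 0 when both sets are empty."""
    a, b = set(set_a), set(set_b)
    union = a | b
    if not union:
        return 0.0
    return 1.0 - len(a & b) / len(union)


def dead_end_metabolites(model: MetabolicModel) -> set[str]:
    """Metabolites that are only ever produced or only ever consumed.

    Reversible reactions count each participant as both producible and
    consumable.  Expects a boundary-stripped model.
    """
    produced: set[str] = set()
    consumed: set[str] = set()
    for rxn in model.reactions.values():
        forward = rxn.upper_bound > FLUX_EPS
        backward = rxn.lower_bound < -FLUX_EPS
        for (mid, _), coef in rxn.stoichiometry.items():
            if coef > 0:
                if forward:
                    produced.add(mid)
                if backward:
                    consumed.add(mid)
            elif coef < 0:
                if forward:
                    consumed.add(mid)
                if backward:
                    produced.add(mid)
    touched = produced | consumed
    return {m for m in touched if (m in produced) != (m in consumed)}


def dead_end_count_distance(model_a: MetabolicModel, model_b: MetabolicModel) -> float:
    """|n_a − n_b| / max(n_a, n_b) over dead-end metabolite counts (0 when
    both counts are 0)."""
    na, nb = len(dead_end_metabolites(model_a)), len(dead_end_metabolites(model_b))
    if na == 0 and nb == 0:
        return 0.0
    return abs(na - nb) / max(na, nb)


def rank_correlation_distance(
    counts_a: Mapping[str, float], counts_b: Mapping[str, float]
) -> float:
    """(1 − Spearman ρ) / 2 over the union of keys (missing keys count 0)."""
    keys = sorted(set(counts_a) | set(counts_b))
    if len(keys) < 2:
        raise ValueError("rank correlation undefined for fewer than 2 distinct keys")
    va = np.array([counts_a.get(k, 0.0) for k in keys])
    vb = np.array([counts_b.get(k, 0.0) for k in keys])
    import warnings

    from scipy.stats import ConstantInputWarning

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConstantInputWarning)
        rho = spearmanr(va, vb).statistic
    if np.isnan(rho):
        raise ValueError("rank correlation undefined (constant count vector)")
    d = float((1.0 - rho) / 2.0)
    if abs(d) < 1e-12:
        d = 0.0
    return min(max(d, 0.0), 1.0)


def _safe_rank_distance(a: Mapping[str, float], b: Mapping[str, float]) -> float:
    """Ensemble-building fallback: count vectors with no rank information
    (constant, including all-zero) contribute distance 0."""
    try:
        return rank_correlation_distance(a, b)
    except ValueError:
        return 0.0


def ec_occurrence(model: MetabolicModel) -> dict[str, int]:
    counts: dict[str, int] = {}
    for rxn in model.reactions.values():
        for ec in rxn.ec_numbers:
            counts[ec] = counts.get(ec, 0) + 1
    return counts


def cofactor_usage(
    model: MetabolicModel, cofactors: Sequence[str] = DEFAULT_COFACTORS
) -> dict[str, int]:
    """Number of reactions each cofactor participates in (0 kept for the
    full cofactor list so vectors share keys)."""
    counts = {c: 0 for c in cofactors}
    for rxn in model.reactions.values():
        present = {mid for (mid, _) in rxn.stoichiometry}
        for c in cofactors:
            if c in present:
                counts[c] += 1
    return counts


def svd_distance(model_a: MetabolicModel, model_b: MetabolicModel) -> float:
    """Distance between the singular-value spectra of the stoichiometric
    matrices: the shorter sorted spectrum is zero-padded, both are scaled to
    unit Euclidean length, and the Euclidean distance is taken."""
    sa = _spectrum(model_a)
    sb = _spectrum(model_b)
    k = max(len(sa), len(sb))
    sa = np.pad(sa, (0, k - len(sa)))
    sb = np.pad(sb, (0, k - len(sb)))
    return float(np.linalg.norm(sa / np.linalg.norm(sa) - sb / np.linalg.norm(sb)))


def _spectrum(model: MetabolicModel) -> np.ndarray:
    _, _, S = model.stoichiometric_matrix()
    if S.shape[0] == 0 or S.shape[1] == 0:
        raise ValueError(f"model {model.id} has an empty stoichiometric matrix")
    vals = svdvals(S.toarray())
    return np.sort(vals)[::-1]


# ---------------------------------------------------------------------------
# Ensemble construction
# ---------------------------------------------------------------------------

MEASURES = (
    "jaccard_metabolites",
    "jaccard_reactions",
    "jaccard_ec",
    "jaccard_genes",
    "jaccard_dead_ends",
    "dead_end_count",
    "rank_ec",
    "rank_cofactors",
    "svd",
)


def build_distance_ensemble(
    models: Sequence[MetabolicModel],
    measures: Optional[Sequence[str]] = None,
    cofactors: Sequence[str] = DEFAULT_COFACTORS,
) -> DistanceEnsemble:
    """Pairwise distance matrices over `models` for the selected measures
    (default: all nine)."""
    measures = list(measures) if measures is not None else list(MEASURES)
    unknown = set(measures) - set(MEASURES)
    if unknown:
        raise ValueError(f"unknown measures: {sorted(unknown)}")
    labels = [m.id for m in models]
    n = len(models)

    feature_sets = {
        "jaccard_metabolites": [m.metabolite_ids() for m in models],
        "jaccard_reactions": [set(m.reactions) for m in models],
        "jaccard_ec": [m.ec_numbers() for m in models],
        "jaccard_genes": [set(m.genes) for m in models],
        "jaccard_dead_ends": [dead_end_metabolites(m) for m in models],
    }
    ec_counts = [ec_occurrence(m) for m in models]
    cof_counts = [cofactor_usage(m, cofactors) for m in models]

    matrices = []
    for name in measures:
        D = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                if name in feature_sets:
                    d = jaccard_distance(feature_sets[name][i], feature_sets[name][j])
                elif name == "dead_end_count":
                    d = dead_end_count_distance(models[i], models[j])
                elif name == "rank_ec":
                    d = _safe_rank_distance(ec_counts[i], ec_counts[j])
                elif name == "rank_cofactors":
                    d = _safe_rank_distance(cof_counts[i], cof_counts[j])
                else:
                    d = svd_distance(models[i], models[j])
                D[i, j] = D[j, i] = d
        matrices.append(D)
    return DistanceEnsemble(labels=labels, matrices=matrices, measure_names=measures)


# ---------------------------------------------------------------------------
# STATIS
# ---------------------------------------------------------------------------


def _double_center(D: np.ndarray) -> np.ndarray:
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    return -0.5 * J @ D @ J


def rv_coefficient(Sa: np.ndarray, Sb: np.ndarray) -> float:
    num = np.trace(Sa @ Sb)
    den = np.sqrt(np.trace(Sa @ Sa) * np.trace(Sb @ Sb))
    if den == 0:
        return 0.0
    return float(num / den)


def statis(ensemble: DistanceEnsemble) -> StatisResult:
    """Combine k distance matrices into a compromise.

    Rv coefficients between the double-centered matrices form a k×k
    similarity matrix; its first eigenvector (sign-fixed nonnegative,
    scaled to sum 1) provides the weights; the compromise is the weighted
    average Σ wᵢ·Dᵢ of the input distance matrices.
    """
    k = len(ensemble.matrices)
    if k == 0:
        raise ValueError("STATIS requires at least one matrix")
    centered = [_double_center(D) for D in ensemble.matrices]
    rv = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            rv[i, j] = rv[j, i] = rv_coefficient(centered[i], centered[j])
    eigvals, eigvecs = np.linalg.eigh(rv)
    first = eigvecs[:, np.argmax(eigvals)]
    if first.sum() < 0:
        first = -first
    if np.any(first < -1e-10):
        raise ValueError(
            "first eigenvector has mixed signs; STATIS precondition violated"
        )
    first = np.clip(first, 0.0, None)
    weights = first / first.sum()
    compromise = sum(w * D for w, D in zip(weights, ensemble.matrices))
    return StatisResult(weights=weights, rv_matrix=rv, compromise=compromise)


# ---------------------------------------------------------------------------
# Mantel test
# ---------------------------------------------------------------------------


def mantel(
    d1: np.ndarray,
    d2: np.ndarray,
    n_perm: int = 999,
    seed: Optional[int] = None,
) -> tuple[float, float]:
    """Mantel correlation between two distance matrices.

    Pearson correlation over the lower-triangle entries, with a one-sided
    permutation p-value from `n_perm` simultaneous row/column permutations
    of the second matrix: p = (1 + #{ρ_perm ≥ ρ}) / (n_perm + 1).
    """
    d1 = np.asarray(d1, dtype=float)
    d2 = np.asarray(d2, dtype=float)
    n = d1.shape[0]
    if d1.shape != d2.shape or d1.shape != (n, n):
        raise ValueError("matrices must be square and of equal shape")
    if n < 3:
        raise ValueError("Mantel test requires n >= 3")
    il = np.tril_indices(n, k=-1)
    x = d1[il]
    if x.std() == 0 or d2[il].std() == 0:
        raise ValueError("Mantel correlation undefined for a constant matrix")
    rho = float(np.corrcoef(x, d2[il])[0, 1])
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        yp = d2[np.ix_(perm, perm)][il]
        if np.corrcoef(x, yp)[0, 1] >= rho:
            count += 1
    p = (1 + count) / (n_perm + 1)
    return rho, p


# ---------------------------------------------------------------------------
# Labeled TSV I/O for distance matrices
# ---------------------------------------------------------------------------


def write_distance_matrix(labels: Sequence[str], D: np.ndarray, path: str) -> None:
    import pandas as pd

    pd.DataFrame(D, index=list(labels), columns=list(labels)).to_csv(path, sep="\t")


def read_distance_matrix(path: str) -> tuple[list[str], np.ndarray]:
    import pandas as pd

    df = pd.read_csv(path, sep="\t", index_col=0)
    return [str(c) for c in df.columns], df.to_numpy(dtype=float)
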