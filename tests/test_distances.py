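"""Distance measures, STATIS combination, and the Mantel test."""

import numpy as np
import pytest

from commitgf.distances import (
    DistanceEnsemble,
    build_distance_ensemble,
    dead_end_count_distance,
    dead_end_metabolites,
    jaccard_distance,
    mantel,
    rank_correlation_distance,
    statis,
    svd_distance,
)
from commitgf.model_core import (
    DEFAULT_BOUND,
    MetabolicModel,
    Metabolite,
    Reaction,
)


def _model(mid, reactions):
    m = MetabolicModel(id=mid)
    for rid, stoich, lb in reactions:
        m.add_reaction(Reaction(rid, stoich, lb, DEFAULT_BOUND), create_missing=True)
    return m


def _random_model(rng, mid="r", n_mets=6, n_rxns=8):
    m = MetabolicModel(id=mid)
    mets = [f"m{i}" for i in range(n_mets)]
    for i in range(n_rxns):
        picks = rng.choice(n_mets, size=rng.integers(2, 4), replace=False)
        stoich = {}
        for j, p in enumerate(picks):
            stoich[(mets[p], "c")] = float(rng.integers(1, 4)) * (-1 if j == 0 else 1)
        lb = -DEFAULT_BOUND if rng.random() < 0.5 else 0.0
        rxn = Reaction(f"r{i}", stoich, lb, DEFAULT_BOUND,
                       ec_numbers={f"1.1.1.{int(rng.integers(1, 5))}"})
        m.add_reaction(rxn, create_missing=True)
    return m


# ---------------------------------------------------------------------------
# Jaccard
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "a,b,expected",
    [
        ({"x", "y"}, {"x", "y"}, 0.0),
        ({"x"}, {"y"}, 1.0),
        ({"a", "b"}, {"b", "c"}, 2 / 3),
        (set(), set(), 0.0),
    ],
)
def test_jaccard_examples(a, b, expected):
    assert jaccard_distance(a, b) == pytest.approx(expected)


def test_jaccard_against_brute_force_oracle():
    rng = np.random.default_rng(0)
    universe = list("abcdefghij")
    for _ in range(100):
        a = {x for x in universe if rng.random() < 0.5}
        b = {x for x in universe if rng.random() < 0.5}
        inter = sum(1 for x in universe if x in a and x in b)
        union = sum(1 for x in universe if x in a or x in b)
        oracle = 1 - inter / union if union else 0.0
        assert jaccard_distance(a, b) == pytest.approx(oracle)
        assert jaccard_distance(b, a) == jaccard_distance(a, b)
    assert jaccard_distance({"q"}, {"q"}) == 0.0


# ---------------------------------------------------------------------------
# dead ends
# ---------------------------------------------------------------------------


def test_dead_ends_on_irreversible_chain():
    m = _model("c", [
        ("R1", {("A", "c"): -1.0, ("B", "c"): 1.0}, 0.0),
        ("R2", {("B", "c"): -1.0, ("C", "c"): 1.0}, 0.0),
    ])
    assert dead_end_metabolites(m) == {"A", "C"}


def test_dead_ends_vanish_with_reversibility():
    m = _model("c", [
        ("R1", {("A", "c"): -1.0, ("B", "c"): 1.0}, -DEFAULT_BOUND),
        ("R2", {("B", "c"): -1.0, ("C", "c"): 1.0}, -DEFAULT_BOUND),
    ])
    assert dead_end_metabolites(m) == set()


def test_dead_ends_empty_model():
    assert dead_end_metabolites(MetabolicModel(id="x")) == set()


def test_dead_end_count_distance_normalized():
    a = _model("a", [("R1", {("A", "c"): -1.0, ("B", "c"): 1.0}, 0.0)])  # 2 dead ends
    b = _model("b", [("R1", {("A", "c"): -1.0, ("B", "c"): 1.0}, -DEFAULT_BOUND)])  # 0
    assert dead_end_count_distance(a, b) == pytest.approx(1.0)
    assert dead_end_count_distance(b, b) == 0.0


# ---------------------------------------------------------------------------
# rank correlation distance
# ---------------------------------------------------------------------------


def test_rank_correlation_examples():
    assert rank_correlation_distance({"x": 3, "y": 1}, {"x": 3, "y": 1}) == 0.0
    assert rank_correlation_distance({"x": 3, "y": 1}, {"x": 1, "y": 3}) == 1.0
    # reversed ranks over 4 keys
    a = {k: i for i, k in enumerate("abcd")}
    b = {k: 3 - i for i, k in enumerate("abcd")}
    assert rank_correlation_distance(a, b) == pytest.approx(1.0)


def test_rank_correlation_missing_keys_count_zero():
    # b lacks "y": counts as 0 there
    d = rank_correlation_distance({"x": 2, "y": 1}, {"x": 5})
    assert d == pytest.approx(0.0)  # ranks agree: x above y in both


def test_rank_correlation_undefined_cases():
    with pytest.raises(ValueError):
        rank_correlation_distance({"x": 1}, {"x": 2})
    with pytest.raises(ValueError):
        rank_correlation_distance({"x": 1, "y": 1}, {"x": 2, "y": 2})


def test_rank_correlation_against_manual_ranks():
    rng = np.random.default_rng(1)
    from scipy.stats import rankdata

    for _ in range(100):
        keys = [f"k{i}" for i in range(6)]
        a = {k: int(rng.integers(0, 5)) for k in keys}
        b = {k: int(rng.integers(0, 5)) for k in keys}
        va = np.array([a[k] for k in keys], dtype=float)
        vb = np.array([b[k] for k in keys], dtype=float)
        if va.std() == 0 or vb.std() == 0:
            continue
        ra, rb = rankdata(va), rankdata(vb)
        rho = np.corrcoef(ra, rb)[0, 1]  # Pearson of average ranks
        assert rank_correlation_distance(a, b) == pytest.approx((1 - rho) / 2, abs=1e-10)


# ---------------------------------------------------------------------------
# SVD distance
# ---------------------------------------------------------------------------


def test_svd_distance_self_and_symmetry():
    rng = np.random.default_rng(2)
    for _ in range(20):
        a = _random_model(rng, "a")
        b = _random_model(rng, "b")
        assert svd_distance(a, a) == pytest.approx(0.0, abs=1e-9)
        assert svd_distance(a, b) == pytest.approx(svd_distance(b, a), abs=1e-12)


def test_svd_distance_invariant_under_column_permutation():
    rng = np.random.default_rng(3)
    a = _random_model(rng, "a")
    b = a.copy()
    b.id = "b"
    # renaming reactions permutes the columns of S
    b.reactions = {f"z_{rid}": r for rid, r in b.reactions.items()}
    assert svd_distance(a, b) == pytest.approx(0.0, abs=1e-9)


def test_svd_distance_matches_spectrum_oracle():
    """Cross-check against an eigendecomposition of S^T S (independent of
    scipy's svdvals route)."""
    rng = np.random.default_rng(4)
    for _ in range(30):
        a = _random_model(rng, "a", n_mets=5, n_rxns=6)
        b = _random_model(rng, "b", n_mets=7, n_rxns=5)
        specs = []
        for m in (a, b):
            _, _, S = m.stoichiometric_matrix()
            S = S.toarray()
            eig = np.linalg.eigvalsh(S.T @ S)
            specs.append(np.sort(np.sqrt(np.clip(eig, 0, None)))[::-1])
        k = max(map(len, specs))
        sa, sb = (np.pad(s, (0, k - len(s))) for s in specs)
        oracle = np.linalg.norm(sa / np.linalg.norm(sa) - sb / np.linalg.norm(sb))
        assert svd_distance(a, b) == pytest.approx(oracle, abs=1e-8)


def test_svd_distance_empty_signalled():
    with pytest.raises(ValueError):
        svd_distance(MetabolicModel(id="x"), MetabolicModel(id="y"))


# ---------------------------------------------------------------------------
# ensemble + STATIS
# ---------------------------------------------------------------------------


def _rand_dist(rng, n):
    A = rng.random((n, n))
    D = (A + A.T) / 2
    np.fill_diagonal(D, 0.0)
    return D


def test_build_ensemble_has_all_nine_measures():
    rng = np.random.default_rng(5)
    models = [_random_model(rng, f"m{i}") for i in range(3)]
    ens = build_distance_ensemble(models)
    assert len(ens.matrices) == 9
    for D in ens.matrices:
        assert np.allclose(D, D.T)
        assert np.allclose(np.diag(D), 0.0)


def test_statis_identical_matrices_uniform_weights():
    rng = np.random.default_rng(6)
    D = _rand_dist(rng, 4)
    ens = DistanceEnsemble(labels=list("abcd"), matrices=[D.copy() for _ in range(3)],
                           measure_names=["x", "y", "z"])
    res = statis(ens)
    assert np.allclose(res.weights, 1 / 3, atol=1e-10)
    assert np.allclose(res.compromise, D, atol=1e-10)


def test_statis_single_matrix():
    rng = np.random.default_rng(7)
    D = _rand_dist(rng, 4)
    res = statis(DistanceEnsemble(labels=list("abcd"), matrices=[D], measure_names=["x"]))
    assert res.weights == pytest.approx([1.0])
    assert np.allclose(res.compromise, D)


def test_statis_scaled_pair_proportional_to_input():
    rng = np.random.default_rng(8)
    D = _rand_dist(rng, 5)
    ens = DistanceEnsemble(labels=list("abcde"), matrices=[D, 2 * D],
                           measure_names=["x", "y"])
    res = statis(ens)
    # Rv between D and 2D is 1 -> uniform weights -> compromise = 1.5 D
    assert np.allclose(res.rv_matrix, 1.0, atol=1e-10)
    assert np.allclose(res.compromise, 1.5 * D, atol=1e-10)


def _power_iteration(A, iters=5000, tol=1e-14):
    """Brute-force dominant eigenvector (independent of numpy.linalg.eigh)."""
    v = np.ones(A.shape[0]) / np.sqrt(A.shape[0])
    for _ in range(iters):
        w = A @ v
        w /= np.linalg.norm(w)
        if np.linalg.norm(w - v) < tol:
            break
        v = w
    return w


def test_statis_agrees_with_power_iteration_oracle():
    rng = np.random.default_rng(9)
    for _ in range(50):
        n, k = 4, int(rng.integers(2, 5))
        mats = [_rand_dist(rng, n) for _ in range(k)]
        ens = DistanceEnsemble(labels=[f"l{i}" for i in range(n)], matrices=mats,
                               measure_names=[f"d{i}" for i in range(k)])
        res = statis(ens)
        v = _power_iteration(res.rv_matrix)
        if v.sum() < 0:
            v = -v
        oracle_w = v / v.sum()
        assert np.allclose(res.weights, oracle_w, atol=1e-8)
        oracle_comp = sum(w * D for w, D in zip(oracle_w, mats))
        assert np.allclose(res.compromise, oracle_comp, atol=1e-7)
        assert res.weights.min() >= 0
        assert res.weights.sum() == pytest.approx(1.0)


def test_statis_weight_invariance_under_reordering():
    rng = np.random.default_rng(10)
    mats = [_rand_dist(rng, 4) for _ in range(3)]
    labels = list("abcd")
    names = ["x", "y", "z"]
    res = statis(DistanceEnsemble(labels, mats, names))
    perm = [2, 0, 1]
    res_p = statis(DistanceEnsemble(labels, [mats[i] for i in perm],
                                    [names[i] for i in perm]))
    assert np.allclose(res_p.weights, res.weights[perm], atol=1e-10)
    assert np.allclose(res_p.compromise, res.compromise, atol=1e-10)


# ---------------------------------------------------------------------------
# Mantel
# ---------------------------------------------------------------------------


def test_mantel_identity_and_affine_invariance():
    rng = np.random.default_rng(11)
    D = _rand_dist(rng, 8)
    rho, p = mantel(D, D, n_perm=99, seed=0)
    assert rho == pytest.approx(1.0)
    rho2, _ = mantel(D, 3.0 * D + 0.7, n_perm=99, seed=0)
    assert rho2 == pytest.approx(1.0)


def test_mantel_constant_matrix_signalled():
    D = np.zeros((4, 4))
    E = np.ones((4, 4)) - np.eye(4)
    with pytest.raises(ValueError):
        mantel(E, D + 0.0)


def test_mantel_rho_matches_skbio():
    skbio = pytest.importorskip("skbio")
    from skbio.stats.distance import DistanceMatrix
    from skbio.stats.distance import mantel as sk_mantel

    rng = np.random.default_rng(12)
    d1, d2 = _rand_dist(rng, 10), _rand_dist(rng, 10)
    rho, _ = mantel(d1, d2, n_perm=99, seed=0)
    sk_rho, _, _ = sk_mantel(DistanceMatrix(d1), DistanceMatrix(d2),
                             permutations=0)
    assert rho == pytest.approx(float(sk_rho), abs=1e-10)


def test_mantel_null_calibration():
    """Under independence the permutation p-value is roughly uniform: the
    fraction of p < 0.05 over repeated draws stays near the nominal level."""
    rng = np.random.default_rng(13)
    hits = 0
    n_draws = 200
    for i in range(n_draws):
        d1 = _rand_dist(rng, 12)
        d2 = _rand_dist(rng, 12)
        _, p = mantel(d1, d2, n_perm=199, seed=1000 + i)
        hits += p < 0.05
    assert 0.01 <= hits / n_draws <= 0.10
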