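import numpy as np
import pandas as pd
import pytest
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial.distance import pdist, squareform

from soilsubcomm import ForwardSelector, forward_select, pcnm
from soilsubcomm.spatial import PCNM, haversine_distances


def direct_pcnm_oracle(coords):
    """Independent eigendecomposition of the truncated double-centred
    distance matrix (planar distances)."""
    D = squareform(pdist(coords))
    t = minimum_spanning_tree(D).toarray().max()
    Dt = np.where(D > t, 4 * t, D)
    np.fill_diagonal(Dt, 0.0)
    n = len(coords)
    J = np.eye(n) - np.ones((n, n)) / n
    G = J @ (-0.5 * Dt**2) @ J
    vals = np.linalg.eigvalsh((G + G.T) / 2)[::-1]
    return t, vals[vals > 1e-10]


def test_pcnm_matches_direct_eigendecomposition():
    coords = np.column_stack([np.linspace(0, 1, 12), np.zeros(12)])
    est = PCNM(distance_mode="euclidean_on_degrees").fit(coords)
    t, vals = direct_pcnm_oracle(coords)
    assert est.threshold_ == pytest.approx(t)
    assert est.eigenvalues_ == pytest.approx(vals, abs=1e-8)


def test_pcnm_orthogonal_centred_unit_norm(meta46):
    basis = pcnm(meta46)
    V = basis.eigenvectors
    assert np.abs(V.sum(axis=0)).max() < 1e-8
    gram = V.T @ V
    assert np.abs(gram - np.eye(V.shape[1])).max() < 1e-8
    assert np.all(basis.eigenvalues > 0)
    assert np.all(np.diff(basis.eigenvalues) <= 1e-12)


def test_pcnm_rigid_motion_invariance(rng):
    coords = rng.random((15, 2))
    est1 = PCNM(distance_mode="euclidean_on_degrees").fit(coords)
    theta = 0.7
    R = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
    est2 = PCNM(distance_mode="euclidean_on_degrees").fit(coords @ R.T + [3.2, -1.5])
    assert est1.eigenvalues_ == pytest.approx(est2.eigenvalues_, abs=1e-8)


def test_pcnm_three_equidistant_sites():
    coords = np.array([[0, 0], [1, 0], [0.5, np.sqrt(3) / 2]])
    est = PCNM(distance_mode="euclidean_on_degrees").fit(coords)
    assert est.eigenvectors_.shape[1] <= 2


def test_pcnm_collocated_sites_error():
    with pytest.raises(ValueError, match="collocated"):
        PCNM(distance_mode="euclidean_on_degrees").fit(np.zeros((4, 2)))


def test_haversine_sanity():
    # one degree of latitude is ~111 km
    d = haversine_distances([0, 0], [0, 1])
    assert d[0, 1] == pytest.approx(111.19, rel=1e-3)


def test_forward_select_finds_true_variable():
    """When selection proceeds, the causal column is picked first."""
    first_picks, nonempty = 0, 0
    for rep in range(25):
        rs = np.random.default_rng(rep)
        X = pd.DataFrame(
            rs.standard_normal((40, 11)), columns=[f"v{i}" for i in range(11)]
        )
        Y = np.outer(X["v0"], rs.standard_normal(5)) + 1.5 * rs.standard_normal((40, 5))
        sel = forward_select(Y, X, n_permutations=99, seed=rep)
        if sel.selected:
            nonempty += 1
            first_picks += sel.selected[0] == "v0"
    assert nonempty >= 5
    assert first_picks == nonempty


def test_forward_select_null_mostly_empty():
    empty = 0
    for rep in range(30):
        rs = np.random.default_rng(1000 + rep)
        X = pd.DataFrame(
            rs.standard_normal((40, 8)), columns=[f"v{i}" for i in range(8)]
        )
        Y = rs.standard_normal((40, 5))
        sel = forward_select(Y, X, n_permutations=99, seed=rep)
        empty += not sel.selected
    assert empty >= 27  # >= 90% at alpha = 0.05


def test_forward_select_alpha_one_no_cap_selects_all(rng):
    X = pd.DataFrame(rng.standard_normal((20, 4)), columns=list("abcd"))
    Y = rng.standard_normal((20, 3))
    sel = forward_select(Y, X, alpha=1.0, adjr2_cap=False, n_permutations=9, seed=0)
    assert sorted(sel.selected) == list("abcd")


def test_forward_select_monotone_in_alpha(rng):
    X = pd.DataFrame(rng.standard_normal((30, 6)), columns=[f"v{i}" for i in range(6)])
    Y = np.outer(X["v1"], rng.standard_normal(4)) + 2.0 * rng.standard_normal((30, 4))
    loose = forward_select(Y, X, alpha=0.5, n_permutations=99, seed=3)
    strict = forward_select(Y, X, alpha=0.05, n_permutations=99, seed=3)
    assert set(strict.selected) <= set(loose.selected)


def test_forward_select_duplicate_names_error(rng):
    X = pd.DataFrame(rng.standard_normal((10, 2)), columns=["a", "a"])
    with pytest.raises(ValueError, match="duplicate"):
        ForwardSelector(n_permutations=9).fit(X, rng.standard_normal((10, 2)))


def test_selection_result_invariants(rng):
    X = pd.DataFrame(rng.standard_normal((30, 5)), columns=[f"v{i}" for i in range(5)])
    Y = np.outer(X["v0"], rng.standard_normal(3)) + 1.5 * rng.standard_normal((30, 3))
    sel = forward_select(Y, X, alpha=0.2, n_permutations=99, seed=1)
    for p, cum in zip(sel.p_values, sel.cumulative_adj_r2):
        assert p <= 0.2
        assert cum <= sel.global_adj_r2 + 1e-9
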