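import numpy as np
import pytest

from soilsubcomm import (
    NicheSimConfig,
    OtuTable,
    anosim,
    bray_curtis,
    distance_decay_fit,
    environmental_distance,
    mantel,
    simulate_niche,
)
from soilsubcomm.io import DistanceMatrix


def _dm(values, ids=None):
    values = np.asarray(values, dtype=float)
    ids = ids or [str(i) for i in range(values.shape[0])]
    return DistanceMatrix(ids, values)


def _random_dm(rng, n, k=8):
    from scipy.spatial.distance import pdist, squareform

    return _dm(squareform(pdist(rng.random((n, k)))))


def test_bray_curtis_hand_values():
    t = OtuTable(["a", "b", "c"], ["x", "y"], np.array([[1, 1], [1, 0], [1, 1]]))
    d = bray_curtis(t, on="counts")
    assert d.values[0, 2] == pytest.approx(0.0)
    assert d.values[0, 1] == pytest.approx(1 / 3)
    t2 = OtuTable(["a", "b"], ["x", "y"], np.array([[3, 0], [0, 7]]))
    assert bray_curtis(t2).values[0, 1] == pytest.approx(1.0)


def test_bray_curtis_depth_invariance(random_table):
    doubled = OtuTable(
        random_table.sample_ids, random_table.otu_ids, random_table.counts * 3
    )
    assert np.allclose(
        bray_curtis(random_table).values, bray_curtis(doubled).values
    )


def test_environmental_distance_hand_value(meta46):
    two = meta46.select_samples(meta46.sample_ids[:2])
    d = environmental_distance(two, ["pH"])
    # two samples, one variable: z-scores are +-1, distance 2
    assert d.values[0, 1] == pytest.approx(2.0)
    # unit change leaves z-scores alone
    two.env["pH"] *= 10
    assert environmental_distance(two, ["pH"]).values[0, 1] == pytest.approx(2.0)


def test_environmental_distance_constant_variable(meta46):
    meta46.env["TP"] = 1.0
    with pytest.raises(ValueError, match="TP"):
        environmental_distance(meta46, ["TP", "pH"])


def test_mantel_identity_and_monotone_invariance(rng):
    d = _random_dm(rng, 12)
    res = mantel(d, d, n_permutations=99, seed=0)
    assert res.r == pytest.approx(1.0)
    assert res.p_value == pytest.approx(1 / 100)
    # spearman is invariant to monotone transforms
    expd = _dm(np.exp(d.values) - 1)
    assert mantel(d, expd, n_permutations=99, seed=0).r == pytest.approx(1.0)
    # pearson identity too
    assert mantel(d, d, method="pearson", n_permutations=99, seed=0).r == pytest.approx(1.0)


def test_mantel_agrees_with_skbio(rng):
    skbio = pytest.importorskip("skbio")
    from skbio.stats.distance import mantel as sk_mantel

    d1, d2 = _random_dm(rng, 15), _random_dm(rng, 15)
    ours = mantel(d1, d2, method="spearman", n_permutations=0, seed=0)
    theirs = sk_mantel(
        skbio.DistanceMatrix(d1.values, d1.ids),
        skbio.DistanceMatrix(d2.values, d2.ids),
        method="spearman",
        permutations=0,
    )[0]
    assert ours.r == pytest.approx(theirs, abs=1e-12)


def test_anosim_perfect_separation_and_skbio_agreement(rng):
    skbio = pytest.importorskip("skbio")
    from skbio.stats.distance import anosim as sk_anosim

    # two tight clusters far apart: R = 1
    pts = np.vstack([rng.normal(0, 0.01, (4, 2)), rng.normal(10, 0.01, (4, 2))])
    from scipy.spatial.distance import pdist, squareform

    d = _dm(squareform(pdist(pts)))
    labels = ["a"] * 4 + ["b"] * 4
    res = anosim(d, labels, n_permutations=999, seed=0)
    assert res.R == pytest.approx(1.0)
    assert res.p_value < 0.05

    # statistic agreement with scikit-bio on unstructured data
    d2 = _random_dm(rng, 12)
    labels2 = ["a", "b", "c"] * 4
    ours = anosim(d2, labels2, n_permutations=99, seed=0)
    theirs = sk_anosim(
        skbio.DistanceMatrix(d2.values, d2.ids), grouping=labels2, permutations=0
    )
    assert ours.R == pytest.approx(theirs["test statistic"], abs=1e-12)


def test_anosim_null_mean_near_zero(rng):
    rs = []
    for rep in range(60):
        local = np.random.default_rng(rep)
        d = _random_dm(local, 16)
        labels = local.permutation(["a"] * 8 + ["b"] * 8)
        rs.append(anosim(d, labels, n_permutations=19, seed=rep).R)
    assert abs(np.mean(rs)) < 0.05


def test_anosim_group_of_one_errors(rng):
    d = _random_dm(rng, 5)
    with pytest.raises(ValueError, match="size 1"):
        anosim(d, ["a", "a", "a", "a", "b"], n_permutations=9, seed=0)


def test_distance_decay_exact_linear(rng):
    dist = _random_dm(rng, 10)
    sim_vals = 1.0 - 0.3 * dist.values
    np.fill_diagonal(sim_vals, 1.0)
    sim = DistanceMatrix(dist.ids, sim_vals, "similarity")
    fit = distance_decay_fit(sim, dist, n_permutations=49, seed=0)
    assert fit.slope == pytest.approx(-0.3, abs=1e-12)
    assert fit.intercept == pytest.approx(1.0, abs=1e-12)


def test_distance_decay_under_strong_filtering():
    """Communities filtered along env gradients lose similarity with env
    distance: negative slope, significant Mantel correlation."""
    table, meta = simulate_niche(
        NicheSimConfig(n_samples=46, n_otus=600, reads_per_sample=3000,
                       sigma_niche=0.5, seed=5)
    )
    fit = distance_decay_fit(
        bray_curtis(table), environmental_distance(meta),
        n_permutations=999, seed=1,
    )
    assert fit.slope < 0
    assert fit.mantel.r > 0.2
    assert fit.mantel.p_value <= 0.001 + 1e-9


def test_mantel_size_mismatch(rng):
    with pytest.raises(ValueError):
        mantel(_random_dm(rng, 6), _random_dm(rng, 7), n_permutations=9, seed=0)
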