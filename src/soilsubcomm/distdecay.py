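"""Community/environmental distances, Mantel tests, ANOSIM and
distance-decay regression.

Sign convention: the Mantel statistic is always computed between two
*dissimilarity* matrices (similarity inputs are converted, with a log
note).  Distance-decay plots conventionally show community *similarity*
(1 - Bray-Curtis) against environmental distance; :func:`distance_decay_fit`
regresses similarity on distance while the accompanying Mantel test runs on
dissimilarities.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata

from .io import DistanceMatrix, OtuTable, SampleMetadata
from .subcomm import relative_abundance

logger = logging.getLogger(__name__)


@dataclass
class MantelResult:
    r: float
    p_value: float
    n_permutations: int
    method: str
    seed: int | None = None


@dataclass
class AnosimResult:
    R: float
    p_value: float
    n_permutations: int
    grouping: str = ""


@dataclass
class DistanceDecayFit:
    slope: float
    intercept: float
    r_squared: float
    mantel: MantelResult


def bray_curtis(table: OtuTable, on: str = "proportions") -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarity between samples.

    ``on='proportions'`` (default) makes the result depth-invariant; at even
    rarefied depth counts and proportions give identical distances.
    """
    if on not in ("counts", "proportions"):
        raise ValueError(f"unknown basis {on!r}")
    if table.n_samples < 2:
        raise ValueError("need at least 2 samples")
    if np.any(table.sample_totals() == 0):
        raise ValueError("zero-total sample; rarefy/filter first")
    X = table.counts.astype(float)
    if on == "proportions":
        X = relative_abundance(X)
    d = squareform(pdist(X, metric="braycurtis"))
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(table.sample_ids, d, "dissimilarity")


def environmental_distance(
    meta: SampleMetadata, variables: list | None = None
) -> DistanceMatrix:
    """Euclidean distance between samples on z-scored environmental variables.

    Each variable is standardised to mean 0 and (population) sd 1 so that
    all variables carry equal weight regardless of measurement units.
    """
    variables = list(variables) if variables is not None else list(meta.env.columns)
    X = meta.env.loc[:, variables].to_numpy(dtype=float)
    sd = X.std(axis=0, ddof=0)
    constant = [v for v, s in zip(variables, sd) if s == 0]
    if constant:
        raise ValueError(f"constant environmental variable(s): {constant}")
    Z = (X - X.mean(axis=0)) / sd
    d = squareform(pdist(Z, metric="euclidean"))
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(meta.sample_ids, d, "dissimilarity")


def _lower(values: np.ndarray) -> np.ndarray:
    i, j = np.tril_indices(values.shape[0], -1)
    return values[i, j]


def _corr(x: np.ndarray, y: np.ndarray) -> float:
    x = x - x.mean()
    y = y - y.mean()
    denom = np.sqrt((x @ x) * (y @ y))
    if denom == 0:
        return 0.0
    return float((x @ y) / denom)


def mantel(
    d1: DistanceMatrix,
    d2: DistanceMatrix,
    method: str = "spearman",
    n_permutations: int = 999,
    seed=None,
) -> MantelResult:
    """Mantel test between two distance matrices.

    The statistic is the Spearman (default) or Pearson correlation of the
    strictly-lower triangles; the one-sided p-value permutes the row/column
    labels of ``d2`` jointly and uses the +1 correction, so it can never be
    exactly zero.
    """
    if method not in ("spearman", "pearson"):
        raise ValueError(f"unknown method {method!r}")
    if d1.ids != d2.ids:
        if len(d1.ids) != len(d2.ids):
            raise ValueError("distance matrices have different sizes")
        raise ValueError("distance matrices have different id orderings")
    d1 = d1.to_dissimilarity()
    d2 = d2.to_dissimilarity()
    n = d1.n
    if n < 3:
        raise ValueError("need at least 3 samples for a Mantel test")
    v1 = _lower(d1.values)
    if method == "spearman":
        v1 = rankdata(v1)
    il, jl = np.tril_indices(n, -1)
    v2_full = d2.values

    def stat(mat):
        v2 = mat[il, jl]
        if method == "spearman":
            v2 = rankdata(v2)
        return _corr(v1, v2)

    r_obs = stat(v2_full)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        if stat(v2_full[np.ix_(perm, perm)]) >= r_obs:
            hits += 1
    p = (1.0 + hits) / (1.0 + n_permutations)
    return MantelResult(r_obs, p, n_permutations, method, seed)


def anosim(
    d: DistanceMatrix, grouping, n_permutations: int = 999, seed=None,
    grouping_name: str = "",
) -> AnosimResult:
    """Analysis of similarities on a dissimilarity matrix.

    R = (mean between-group rank - mean within-group rank) / (M/2) with
    M = n(n-1)/2 ranks of all pairwise dissimilarities; p by permuting the
    group labels.
    """
    d = d.to_dissimilarity()
    labels = np.asarray(grouping)
    if len(labels) != d.n:
        raise ValueError("grouping length does not match matrix size")
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("need at least 2 groups")
    if counts.min() < 2:
        small = uniq[counts < 2].tolist()
        raise ValueError(f"group(s) of size 1: {small}")
    il, jl = np.tril_indices(d.n, -1)
    ranks = rankdata(d.values[il, jl])
    M = len(ranks)

    codes = np.searchsorted(uniq, labels)

    def r_stat(c):
        within = c[il] == c[jl]
        return (ranks[~within].mean() - ranks[within].mean()) / (M / 2.0)

    R_obs = r_stat(codes)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        if r_stat(rng.permutation(codes)) >= R_obs:
            hits += 1
    p = (1.0 + hits) / (1.0 + n_permutations)
    return AnosimResult(R_obs, p, n_permutations, grouping_name)


def distance_decay_fit(
    similarity: DistanceMatrix,
    distance: DistanceMatrix,
    method: str = "spearman",
    n_permutations: int = 999,
    seed=None,
) -> DistanceDecayFit:
    """OLS of community similarity on environmental distance plus the
    accompanying Mantel test (run on dissimilarities)."""
    if similarity.ids != distance.ids:
        raise ValueError("mismatched sample ids")
    if similarity.n < 3:
        raise ValueError("need at least 3 sites")
    y = _lower(similarity.to_similarity().values)
    x = _lower(distance.to_dissimilarity().values)
    from scipy.stats import linregress

    fit = linregress(x, y)
    mt = mantel(
        similarity.to_dissimilarity(),
        distance,
        method=method,
        n_permutations=n_permutations,
        seed=seed,
    )
    return DistanceDecayFit(float(fit.slope), float(fit.intercept), float(fit.rvalue**2), mt)
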