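"""Spatial eigenvectors (PCNM) and forward selection of predictors.

PCNM (principal coordinates of neighbour matrices) turns site coordinates
into orthogonal spatial basis vectors: the geographic distance matrix is
truncated at the longest minimum-spanning-tree edge (distances beyond it
set to four times the threshold), double-centred, and eigendecomposed;
positive-eigenvalue eigenvectors are the spatial predictors, ordered from
broad to fine scale.

Forward selection follows the double stopping rule: candidates are only
considered if the global model (all candidates) is significant, and
selection stops as soon as the best remaining candidate is non-significant
or the cumulative adjusted R2 would exceed the global model's.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial.distance import pdist, squareform
from sklearn.base import BaseEstimator, TransformerMixin

from .io import SampleMetadata
from .vpa import _as_matrix, _fit_r2, _orth, adjusted_r2

EARTH_RADIUS_KM = 6371.0


def haversine_distances(lon, lat) -> np.ndarray:
    """Great-circle distances (km) between sites given in decimal degrees."""
    lon = np.radians(np.asarray(lon, dtype=float))
    lat = np.radians(np.asarray(lat, dtype=float))
    dlon = lon[:, None] - lon[None, :]
    dlat = lat[:, None] - lat[None, :]
    h = np.sin(dlat / 2) ** 2 + np.cos(lat)[:, None] * np.cos(lat)[None, :] * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0, 1)))


@dataclass
class PcnmBasis:
    ids: list
    eigenvectors: np.ndarray
    eigenvalues: np.ndarray
    truncation_threshold: float

    @property
    def names(self) -> list:
        return [f"PCNM{i + 1}" for i in range(self.eigenvectors.shape[1])]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.eigenvectors, index=self.ids, columns=self.names)


class PCNM(BaseEstimator, TransformerMixin):
    """Compute PCNM spatial eigenvectors from site coordinates.

    Parameters
    ----------
    distance_mode : {'great_circle', 'euclidean_on_degrees'}
        Geographic distance used; great-circle suits lon/lat over a real
        landscape, euclidean suits synthetic planar coordinates.

    Attributes
    ----------
    eigenvectors_ : ndarray (n_samples, k), unit-norm columns by
        decreasing eigenvalue.
    eigenvalues_ : positive eigenvalues.
    threshold_ : truncation distance (longest MST edge).
    """

    def __init__(self, distance_mode: str = "great_circle"):
        self.distance_mode = distance_mode

    def fit(self, X, y=None):
        coords = np.asarray(X, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 2:
            raise ValueError("X must be (n_samples, 2) lon/lat columns")
        n = coords.shape[0]
        if n < 3:
            raise ValueError("need at least 3 sites")
        if self.distance_mode == "great_circle":
            D = haversine_distances(coords[:, 0], coords[:, 1])
        elif self.distance_mode == "euclidean_on_degrees":
            D = squareform(pdist(coords))
        else:
            raise ValueError(f"unknown distance_mode {self.distance_mode!r}")
        if D.max() == 0:
            raise ValueError("all sites are collocated")
        mst = minimum_spanning_tree(D).toarray()
        t = float(mst.max())
        Dt = np.where(D > t, 4.0 * t, D)
        np.fill_diagonal(Dt, 0.0)
        # principal coordinates of the truncated matrix
        G = -0.5 * Dt**2
        J = np.eye(n) - np.ones((n, n)) / n
        G = J @ G @ J
        G = (G + G.T) / 2.0
        vals, vecs = np.linalg.eigh(G)
        order = np.argsort(vals)[::-1]
        vals, vecs = vals[order], vecs[:, order]
        keep = vals > 1e-10
        vecs = vecs[:, keep]
        vecs = vecs / np.linalg.norm(vecs, axis=0, keepdims=True)
        # deterministic sign: largest-magnitude entry positive
        for j in range(vecs.shape[1]):
            k = np.argmax(np.abs(vecs[:, j]))
            if vecs[k, j] < 0:
                vecs[:, j] *= -1
        self.eigenvalues_ = vals[keep]
        self.eigenvectors_ = vecs
        self.threshold_ = t
        return self

    def transform(self, X=None):
        return self.eigenvectors_


def pcnm(meta_or_coords, distance_mode: str = "great_circle") -> PcnmBasis:
    """PCNM basis from a :class:`SampleMetadata` (lon/lat) or an
    (n, 2) coordinate array."""
    if isinstance(meta_or_coords, SampleMetadata):
        ids = meta_or_coords.sample_ids
        coords = np.column_stack([meta_or_coords.lon, meta_or_coords.lat])
    else:
        coords = np.asarray(meta_or_coords, dtype=float)
        ids = [str(i) for i in range(coords.shape[0])]
    est = PCNM(distance_mode=distance_mode).fit(coords)
    return PcnmBasis(ids, est.eigenvectors_, est.eigenvalues_, est.threshold_)


@dataclass
class SelectionResult:
    selected: list
    p_values: list
    cumulative_adj_r2: list
    global_adj_r2: float
    global_p: float
    alpha: float
    n_permutations: int

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "variable": self.selected,
                "p_value": self.p_values,
                "cum_adj_r2": self.cumulative_adj_r2,
            }
        )


class ForwardSelector(BaseEstimator):
    """Greedy forward selection of RDA predictors with the double stopping
    rule (per-step permutation test at ``alpha`` plus the global adjusted-R2
    cap).

    Attributes
    ----------
    selected_ : list of chosen column names, in selection order.
    result_ : :class:`SelectionResult` with per-step p and cumulative
        adjusted R2.
    """

    def __init__(
        self,
        alpha: float = 0.05,
        n_permutations: int = 999,
        adjr2_cap: bool = True,
        seed: int | None = None,
    ):
        self.alpha = alpha
        self.n_permutations = n_permutations
        self.adjr2_cap = adjr2_cap
        self.seed = seed

    def fit(self, X, Y):
        X, names = _as_matrix(X)
        if len(set(names)) != len(names):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate candidate column names: {dup}")
        Y = np.asarray(Y, dtype=float)
        n = Y.shape[0]
        if X.shape[0] != n:
            raise ValueError("X and Y row counts differ")
        Yc = Y - Y.mean(axis=0)
        ss_total = float((Yc**2).sum())
        Xc = X - X.mean(axis=0)
        rng = np.random.default_rng(self.seed)

        # global test: all candidates at once
        r2_g, _ = _fit_r2(Yc, Xc, ss_total)
        rank_g = int(np.linalg.matrix_rank(Xc))
        adj_global = adjusted_r2(r2_g, n, rank_g)
        Q_g = _orth(Xc)
        hits = 0
        for _ in range(self.n_permutations):
            Yp = Yc[rng.permutation(n)]
            if ((Q_g.T @ Yp) ** 2).sum() / ss_total >= r2_g:
                hits += 1
        p_global = (1.0 + hits) / (1.0 + self.n_permutations)

        selected: list = []
        p_values: list = []
        cum_adj: list = []
        if p_global <= self.alpha:
            remaining = list(range(len(names)))
            current: list = []
            while remaining:
                r2_cur, fit_cur = _fit_r2(Yc, Xc[:, current], ss_total)
                # greedy step: candidate with the largest R2 gain
                best_j, best_r2 = None, -np.inf
                for j in remaining:
                    r2_j, _ = _fit_r2(Yc, Xc[:, current + [j]], ss_total)
                    if r2_j > best_r2:
                        best_j, best_r2 = j, r2_j
                gain = best_r2 - r2_cur
                # Freedman-Lane test of the addition given current set
                resid = Yc - fit_cur
                Q_cur = _orth(Xc[:, current])
                Q_new = _orth(Xc[:, current + [best_j]])
                hits = 0
                for _ in range(self.n_permutations):
                    Yp = fit_cur + resid[rng.permutation(n)]
                    Yp = Yp - Yp.mean(axis=0)
                    ssp = float((Yp**2).sum())
                    r2c = ((Q_cur.T @ Yp) ** 2).sum() / ssp
                    r2f = ((Q_new.T @ Yp) ** 2).sum() / ssp
                    if r2f - r2c >= gain:
                        hits += 1
                p_step = (1.0 + hits) / (1.0 + self.n_permutations)
                if p_step > self.alpha:
                    break
                adj_step = adjusted_r2(best_r2, n, len(current) + 1)
                if self.adjr2_cap and adj_step > adj_global + 1e-9:
                    break
                current.append(best_j)
                remaining.remove(best_j)
                selected.append(names[best_j])
                p_values.append(p_step)
                cum_adj.append(adj_step)
        self.selected_ = selected
        self.result_ = SelectionResult(
            selected, p_values, cum_adj, adj_global, p_global,
            self.alpha, self.n_permutations,
        )
        return self


def forward_select(
    Y, X, alpha: float = 0.05, n_permutations: int = 999,
    adjr2_cap: bool = True, seed=None,
) -> SelectionResult:
    """Functional wrapper over :class:`ForwardSelector` (Y-then-X order)."""
    sel = ForwardSelector(
        alpha=alpha, n_permutations=n_permutations, adjr2_cap=adjr2_cap, seed=seed
    ).fit(X, Y)
    return sel.result_
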