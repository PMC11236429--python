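"""Redundancy analysis and adjusted-R2 variation partitioning.

RDA is the PCA of the fitted values of a multivariate least-squares
regression of the (column-centred) community matrix on the predictors;
R2 is the share of total community variance captured by the fit and is
bias-corrected with the Ezekiel formula before partitioning.  Variation
partitioning splits the adjusted R2 of a community matrix into a unique
environmental fraction (a), a spatially structured environmental fraction
shared by both predictor blocks (b), a unique spatial fraction (c) and the
residual (d = 1 - a - b - c).  a and c can be slightly negative — an
expected artifact of the adjustment, not an error.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .io import OtuTable


def hellinger(table_or_counts) -> np.ndarray:
    """Hellinger transform: square root of per-sample proportions.

    Rows of the result have unit sum of squares; the transform makes
    community data suitable for linear (Euclidean) ordination by damping
    the influence of double zeros and dominant taxa.
    """
    counts = (
        table_or_counts.counts
        if isinstance(table_or_counts, OtuTable)
        else np.asarray(table_or_counts, dtype=float)
    )
    totals = counts.sum(axis=1, keepdims=True)
    if np.any(totals <= 0):
        raise ValueError("zero-total sample; cannot Hellinger-transform")
    return np.sqrt(counts / totals)


def adjusted_r2(r2: float, n: int, p: int) -> float:
    """Ezekiel adjustment: 1 - (1 - R2) (n - 1) / (n - p - 1)."""
    if p == 0:
        return float(r2)
    if n <= p + 1:
        raise ValueError(f"need n > p + 1 (n={n}, p={p})")
    return float(1.0 - (1.0 - r2) * (n - 1) / (n - p - 1))


def _as_matrix(X, prefix: str = "x") -> tuple[np.ndarray, list]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), [str(c) for c in X.columns]
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    return X, [f"{prefix}{i}" for i in range(X.shape[1])]


def _orth(Xc: np.ndarray) -> np.ndarray:
    """Orthonormal basis of the column space of ``Xc`` (rank-safe)."""
    if Xc.shape[1] == 0:
        return np.zeros((Xc.shape[0], 0))
    u, s, _ = np.linalg.svd(Xc, full_matrices=False)
    k = int(np.sum(s > max(s[0], 1e-300) * 1e-12))
    return u[:, :k]


def _fit_r2(Yc: np.ndarray, Xc: np.ndarray, ss_total: float) -> tuple[float, np.ndarray]:
    """R2 of multivariate least squares of centred Y on centred X."""
    if Xc.shape[1] == 0:
        return 0.0, np.zeros_like(Yc)
    Q = _orth(Xc)
    fitted = Q @ (Q.T @ Yc)
    return float((fitted**2).sum() / ss_total), fitted


@dataclass
class RdaResult:
    r_squared: float
    adj_r_squared: float
    p_value: float | None
    eigenvalues: np.ndarray
    site_scores: np.ndarray
    species_scores: np.ndarray
    biplot_scores: np.ndarray
    predictor_names: list


class RDA(BaseEstimator):
    """Redundancy analysis (constrained linear ordination).

    Parameters
    ----------
    n_permutations : int
        Permutations for the overall-model test (0 disables it).
    seed : int or None
        Permutation stream seed.

    Attributes (after ``fit(X, Y)``)
    --------------------------------
    r_squared_, adj_r_squared_ : float
    p_value_ : float or None
    site_scores_, species_scores_, biplot_scores_ : ndarray
        Triplot coordinates on the constrained axes.
    """

    def __init__(self, n_permutations: int = 999, seed: int | None = None):
        self.n_permutations = n_permutations
        self.seed = seed

    def fit(self, X, Y):
        X, names = _as_matrix(X)
        Y = np.asarray(Y, dtype=float)
        n, p = X.shape
        if n != Y.shape[0]:
            raise ValueError("X and Y row counts differ")
        if n <= p + 1:
            raise ValueError(f"need n_samples > n_predictors + 1 (n={n}, p={p})")
        Xc = X - X.mean(axis=0)
        if np.linalg.matrix_rank(Xc) < p:
            # identify offending columns by greedy rank growth
            bad, keep = [], []
            for j in range(p):
                trial = Xc[:, keep + [j]]
                if np.linalg.matrix_rank(trial) == len(keep) + 1:
                    keep.append(j)
                else:
                    bad.append(names[j])
            raise ValueError(f"rank-deficient predictors; collinear columns: {bad}")
        Yc = Y - Y.mean(axis=0)
        ss_total = float((Yc**2).sum())
        if ss_total == 0:
            raise ValueError("response matrix has zero variance")
        r2, fitted = _fit_r2(Yc, Xc, ss_total)
        self.r_squared_ = r2
        self.adj_r_squared_ = adjusted_r2(r2, n, p)
        u, s, vt = np.linalg.svd(fitted, full_matrices=False)
        k = int(np.sum(s > 1e-10 * max(s[0], 1e-300)))
        k = min(k, p)
        self.eigenvalues_ = (s[:k] ** 2) / (n - 1)
        self.site_scores_ = u[:, :k] * s[:k]
        self.species_scores_ = vt[:k].T
        # predictor correlations with the constrained axes
        with np.errstate(invalid="ignore", divide="ignore"):
            bip = np.corrcoef(Xc, self.site_scores_, rowvar=False)[:p, p:]
        self.biplot_scores_ = np.nan_to_num(bip)
        self.predictor_names_ = names
        self.p_value_ = None
        if self.n_permutations:
            rng = np.random.default_rng(self.seed)
            Q = _orth(Xc)
            hits = 0
            for _ in range(self.n_permutations):
                Yp = Yc[rng.permutation(n)]
                if ((Q.T @ Yp) ** 2).sum() / ss_total >= r2:
                    hits += 1
            self.p_value_ = (1.0 + hits) / (1.0 + self.n_permutations)
        return self

    def result_(self) -> RdaResult:
        return RdaResult(
            self.r_squared_, self.adj_r_squared_, self.p_value_,
            self.eigenvalues_, self.site_scores_, self.species_scores_,
            self.biplot_scores_, self.predictor_names_,
        )


def rda(Y, X, n_permutations: int = 999, seed=None) -> RdaResult:
    """Functional wrapper over :class:`RDA` (note Y-then-X argument order,
    matching the community-ecology convention Y ~ X)."""
    return RDA(n_permutations=n_permutations, seed=seed).fit(X, Y).result_()


@dataclass
class VpaResult:
    """Adjusted-R2 fractions: a env-only, b shared, c space-only, d residual."""

    a: float
    b: float
    c: float
    d: float
    env_names: list
    spat_names: list
    p_env: float | None = None
    p_spat: float | None = None

    def fractions(self) -> dict:
        return {"a": self.a, "b": self.b, "c": self.c, "d": self.d}

    def display_fractions(self) -> dict:
        """Figure-style display: negative unique fractions shown as 0,
        percentages rounded to integers."""
        return {
            k: int(round(100 * max(v, 0.0)))
            for k, v in self.fractions().items()
        }


def _partial_rda_p(Yc, Xc_test, Xc_cov, ss_total, n_permutations, rng) -> float:
    """Permutation p for the unique contribution of one predictor block.

    Freedman-Lane: residuals of Y on the covariate block are permuted,
    re-added to the covariate fit, and the semipartial R2 recomputed.
    """
    n = Yc.shape[0]
    Q_cov = _orth(Xc_cov)
    Q_all = _orth(np.hstack([Xc_cov, Xc_test]))
    fit_cov = Q_cov @ (Q_cov.T @ Yc)
    r2_cov = float((fit_cov**2).sum() / ss_total)
    r2_full = float(((Q_all.T @ Yc) ** 2).sum() / ss_total)
    stat_obs = r2_full - r2_cov
    resid = Yc - fit_cov
    hits = 0
    for _ in range(n_permutations):
        Yp = fit_cov + resid[rng.permutation(n)]
        Yp = Yp - Yp.mean(axis=0)
        ssp = float((Yp**2).sum())
        r2c = float(((Q_cov.T @ Yp) ** 2).sum() / ssp)
        r2f = float(((Q_all.T @ Yp) ** 2).sum() / ssp)
        if r2f - r2c >= stat_obs:
            hits += 1
    return (1.0 + hits) / (1.0 + n_permutations)


def variation_partition(
    Y, X_env=None, X_spat=None, n_permutations: int = 199, seed=None
) -> VpaResult:
    """Partition community variance between two predictor blocks.

    With A = adjR2(Y | env), B = adjR2(Y | space), C = adjR2(Y | both):
    a = C - B, c = C - A, b = A + B - C, d = 1 - C.  The testable unique
    fractions a and c get partial-RDA permutation p-values when
    ``n_permutations`` > 0.
    """
    import logging

    log = logging.getLogger(__name__)
    Y = np.asarray(Y, dtype=float)
    n = Y.shape[0]
    Xe, env_names = _as_matrix(X_env, "env") if X_env is not None else (np.empty((n, 0)), [])
    Xs, spat_names = _as_matrix(X_spat, "spat") if X_spat is not None else (np.empty((n, 0)), [])
    if not env_names:
        log.info("empty environmental block; its fractions are 0")
    if not spat_names:
        log.info("empty spatial block; its fractions are 0")
    overlap = set(env_names) & set(spat_names)
    if overlap:
        raise ValueError(f"predictor blocks share column names: {sorted(overlap)}")
    Yc = Y - Y.mean(axis=0)
    ss_total = float((Yc**2).sum())
    Xe_c = Xe - Xe.mean(axis=0) if Xe.shape[1] else Xe
    Xs_c = Xs - Xs.mean(axis=0) if Xs.shape[1] else Xs
    # canonical column order makes the combined fit — and hence the a/c
    # fractions — exactly symmetric under swapping the two blocks
    Xb_c = np.hstack([Xe_c, Xs_c])
    order = sorted(range(Xb_c.shape[1]), key=lambda j: tuple(Xb_c[:, j]))
    Xb_c = Xb_c[:, order]

    def adj(Xc):
        if Xc.shape[1] == 0:
            return 0.0
        r2, _ = _fit_r2(Yc, Xc, ss_total)
        # rank, not column count: duplicated columns must not inflate the df
        p_eff = int(np.linalg.matrix_rank(Xc))
        if n <= p_eff + 1:
            raise ValueError(
                f"too many predictors (rank {p_eff}) for {n} samples; "
                "forward-select a smaller set first"
            )
        return adjusted_r2(r2, n, p_eff)

    A, B, C = adj(Xe_c), adj(Xs_c), adj(Xb_c)
    a, c = C - B, C - A
    b = A + B - C
    d = 1.0 - C
    p_env = p_spat = None
    if n_permutations:
        rng = np.random.default_rng(seed)
        if Xe.shape[1] and Xs.shape[1]:
            p_env = _partial_rda_p(Yc, Xe_c, Xs_c, ss_total, n_permutations, rng)
            p_spat = _partial_rda_p(Yc, Xs_c, Xe_c, ss_total, n_permutations, rng)
    return VpaResult(a, b, c, d, env_names, spat_names, p_env, p_spat)


class VariationPartitioning(BaseEstimator):
    """Estimator facade over :func:`variation_partition`.

    ``fit(Y)`` with the two predictor blocks given at construction; the
    fractions land in ``result_``.
    """

    def __init__(self, n_permutations: int = 199, seed: int | None = None):
        self.n_permutations = n_permutations
        self.seed = seed

    def fit(self, Y, X_env=None, X_spat=None):
        self.result_ = variation_partition(
            Y, X_env, X_spat, n_permutations=self.n_permutations, seed=self.seed
        )
        return self
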