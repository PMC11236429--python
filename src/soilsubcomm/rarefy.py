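"""Rarefaction to even depth and analytic rarefaction curves.

Subsampling is uniform WITHOUT replacement (multivariate hypergeometric),
which is what the analytic expected-richness curve describes.  Samples
below the target depth are dropped with a warning rather than padded:
downstream neutral-model fitting assumes one common depth because its
detection limit is one read out of N.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln
from sklearn.base import BaseEstimator, TransformerMixin

from .io import OtuTable

logger = logging.getLogger(__name__)


def expected_richness(counts, n: int) -> float:
    """Expected number of OTUs observed in a uniform subsample of ``n`` reads.

    For a sample with counts ``c_i`` summing to ``Ntot`` the expectation is
    ``sum_i 1 - C(Ntot - c_i, n) / C(Ntot, n)`` (hypergeometric absence
    probability), evaluated in log space.
    """
    c = np.asarray(counts, dtype=np.int64)
    c = c[c > 0]
    ntot = int(c.sum())
    if n < 0:
        raise ValueError("subsample size must be >= 0")
    if n > ntot:
        raise ValueError(f"subsample size {n} exceeds sample total {ntot}")
    if n == 0:
        return 0.0

    def logchoose(a, b):
        return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)

    rem = ntot - c
    absent = np.where(
        rem >= n,
        np.exp(logchoose(rem, n) - logchoose(ntot, n)),
        0.0,
    )
    return float(np.sum(1.0 - absent))


def rarefaction_curve(counts, depths=None) -> tuple[np.ndarray, np.ndarray]:
    """Analytic rarefaction curve for one sample.

    Returns ``(depths, expected_richness)``; default depths are 20 points
    evenly spaced up to the sample total.
    """
    c = np.asarray(counts, dtype=np.int64)
    ntot = int(c.sum())
    if depths is None:
        depths = np.unique(np.linspace(0, ntot, 21).astype(int))
    depths = np.asarray(depths, dtype=int)
    rich = np.array([expected_richness(c, int(d)) for d in depths])
    return depths, rich


class Rarefier(BaseEstimator, TransformerMixin):
    """Subsample every row of a count matrix to an even depth.

    Parameters
    ----------
    depth : int or None
        Target reads per sample; ``None`` uses the minimum row total seen
        at transform time.
    seed : int or None
        Seed for the subsampling stream.
    """

    def __init__(self, depth: int | None = None, seed: int | None = None):
        self.depth = depth
        self.seed = seed

    def fit(self, X, y=None):
        X = np.asarray(X)
        self.depth_ = int(X.sum(axis=1).min()) if self.depth is None else int(self.depth)
        if self.depth_ <= 0:
            raise ValueError("rarefaction depth must be > 0")
        return self

    def transform(self, X):
        """Return (rarefied counts, boolean mask of retained rows)."""
        X = np.asarray(X, dtype=np.int64)
        if not hasattr(self, "depth_"):
            self.fit(X)
        rng = np.random.default_rng(self.seed)
        totals = X.sum(axis=1)
        keep = totals >= self.depth_
        out = np.empty((int(keep.sum()), X.shape[1]), dtype=np.int64)
        r = 0
        for i in range(X.shape[0]):
            if keep[i]:
                out[r] = rng.multivariate_hypergeometric(X[i], self.depth_)
                r += 1
        return out, keep


def rarefy_table(table: OtuTable, depth: int | None = None, seed=None) -> OtuTable:
    """Rarefy an :class:`OtuTable` to even depth.

    Samples shallower than ``depth`` are dropped (warning logged); OTUs
    left with zero total across all retained samples are removed.
    """
    r = Rarefier(depth=depth, seed=seed).fit(table.counts)
    counts, keep = r.transform(table.counts)
    dropped = [s for s, k in zip(table.sample_ids, keep) if not k]
    if dropped:
        logger.warning(
            "rarefy dropped %d sample(s) below depth %d: %s",
            len(dropped), r.depth_, dropped,
        )
    samples = [s for s, k in zip(table.sample_ids, keep) if k]
    if not samples:
        raise ValueError("no sample reaches the rarefaction depth")
    nonzero = counts.sum(axis=0) > 0
    otus = [o for o, k in zip(table.otu_ids, nonzero) if k]
    tax = None
    if table.taxonomy is not None:
        tax = {o: table.taxonomy[o] for o in otus if o in table.taxonomy}
    return OtuTable(samples, otus, counts[:, nonzero], tax)
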