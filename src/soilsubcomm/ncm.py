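"""Sloan neutral community model: occurrence frequency vs mean abundance.

Under neutral assembly with immigration, the probability that a taxon of
metacommunity relative abundance ``p`` is detected in a local sample of
``N`` reads is

    F(p) = 1 - I_d(N m p, N m (1 - p))

where ``I_d`` is the regularised incomplete beta function (the beta CDF)
evaluated at the detection limit ``d = 1/N`` (one read), and ``m`` is the
immigration probability.  Fitting ``m`` by nonlinear least squares of the
observed occurrence frequencies on this curve, and reporting the
generalised R2 of the fit, quantifies how much of the occupancy-abundance
relationship a purely stochastic model explains.  R2 can be negative when
the community predicts occupancy worse than a flat line — evidence against
neutrality.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.stats import beta as beta_dist
from sklearn.base import BaseEstimator
from statsmodels.stats.proportion import proportion_confint

from .io import OtuTable

#: Multi-start grid for the 1-D immigration estimate (the SSE in m can be
#: multi-modal at small community sizes).
M_GRID = (1e-4, 1e-3, 1e-2, 1e-1, 0.5)

M_BOUNDS = (1e-6, 1.0)


def occurrence_stats(table: OtuTable, otu_ids=None) -> pd.DataFrame:
    """Per-OTU mean relative abundance ``p`` and occurrence frequency.

    Requires an even-depth (rarefied) table: the detection limit and the
    binomial sample size of the model are only well defined at one common
    depth.  OTUs absent everywhere are dropped.

    When fitting one subcommunity, pass the full rarefied table plus the
    subcommunity's OTU ids as ``otu_ids``: relative abundance and the
    detection limit refer to the whole community's read depth even though
    only the subset is fitted.
    """
    totals = table.sample_totals()
    if np.any(totals == 0):
        raise ValueError("zero-total sample; rarefy first")
    if len(set(totals.tolist())) != 1:
        raise ValueError(
            f"uneven sample depths {sorted(set(totals.tolist()))[:4]}...; "
            "rarefy to a common depth first"
        )
    N = int(totals[0])
    rel = table.counts / N
    p = rel.mean(axis=0)
    freq = (table.counts > 0).mean(axis=0)
    df = pd.DataFrame({"p": p, "freq": freq}, index=table.otu_ids)
    df.attrs["N"] = N
    df.attrs["n_samples"] = table.n_samples
    if otu_ids is not None:
        missing = set(otu_ids) - set(table.otu_ids)
        if missing:
            raise ValueError(f"otu_ids not in table: {sorted(missing)[:5]}...")
        df = df.loc[list(otu_ids)]
    return df[df["p"] > 0]


def sloan_expected_frequency(p, Nm: float, d: float):
    """Expected occurrence frequency for mean abundance ``p`` under the
    neutral model with parameter ``Nm`` and detection limit ``d``."""
    p = np.asarray(p, dtype=float)
    if Nm <= 0:
        raise ValueError("Nm must be > 0")
    if not 0 < d < 1:
        raise ValueError("detection limit d must be in (0, 1)")
    if np.any(p <= 0) or np.any(p >= 1):
        raise ValueError("p must lie strictly in (0, 1)")
    out = 1.0 - beta_dist.cdf(d, Nm * p, Nm * (1.0 - p))
    return out if out.ndim else float(out)


@dataclass
class NcmFit:
    N: int
    m: float
    Nm: float
    r_squared: float
    detection_limit: float
    n_otus_used: int
    n_samples: int
    stats: pd.DataFrame  # per-OTU: p, freq, predicted, lower, upper, status

    def summary(self) -> dict:
        return {
            "N": self.N,
            "m": self.m,
            "Nm": self.Nm,
            "R2": self.r_squared,
            "detection_limit": self.detection_limit,
            "n_otus_used": self.n_otus_used,
        }


class NeutralCommunityModel(BaseEstimator):
    """Fit the Sloan neutral model to an even-depth OTU table.

    Parameters
    ----------
    min_otus : int
        Minimum OTUs (after dropping all-zero ones) needed for a fit.

    Attributes
    ----------
    m_, Nm_, r_squared_, N_ : fitted immigration rate, Nm, generalised R2
        and the common read depth.
    stats_ : per-OTU DataFrame with observed/predicted frequencies, the
        Wilson 95% bounds around the prediction, and each OTU's envelope
        status (above / within / below).
    """

    def __init__(self, min_otus: int = 50):
        self.min_otus = min_otus

    def fit(self, table: OtuTable, y=None, otu_ids=None):
        stats = occurrence_stats(table, otu_ids=otu_ids)
        if len(stats) < self.min_otus:
            raise ValueError(
                f"only {len(stats)} OTUs with nonzero abundance; "
                f"need at least {self.min_otus}"
            )
        N = stats.attrs["N"]
        S = stats.attrs["n_samples"]
        d = 1.0 / N
        p = stats["p"].to_numpy()
        f_obs = stats["freq"].to_numpy()

        def sse(m):
            pred = 1.0 - beta_dist.cdf(d, N * m * p, N * m * (1.0 - p))
            return float(((f_obs - pred) ** 2).sum())

        best = None
        lo, hi = M_BOUNDS
        grid = sorted(set(M_GRID) | {lo, hi})
        for i, start in enumerate(grid):
            left = grid[i - 1] if i > 0 else lo
            right = grid[i + 1] if i + 1 < len(grid) else hi
            if right <= left:
                continue
            res = minimize_scalar(
                sse, bounds=(left, right), method="bounded",
                options={"xatol": 1e-10},
            )
            if best is None or res.fun < best.fun:
                best = res
        if best is None or not np.isfinite(best.fun):
            raise RuntimeError(
                f"neutral-model fit failed to converge; starts tried: {grid}"
            )
        m = float(np.clip(best.x, lo, hi))
        pred = 1.0 - beta_dist.cdf(d, N * m * p, N * m * (1.0 - p))
        sst = float(((f_obs - f_obs.mean()) ** 2).sum())
        r2 = 1.0 - best.fun / sst if sst > 0 else np.nan
        lower, upper = proportion_confint(pred * S, S, alpha=0.05, method="wilson")
        status = np.where(f_obs > upper, "above", np.where(f_obs < lower, "below", "within"))
        out = stats.copy()
        out["predicted"] = pred
        out["lower"] = lower
        out["upper"] = upper
        out["status"] = status
        self.N_ = N
        self.m_ = m
        self.Nm_ = N * m
        self.r_squared_ = float(r2)
        self.detection_limit_ = d
        self.stats_ = out
        self.n_samples_ = S
        return self

    def predict(self, p):
        """Expected occurrence frequency at mean abundance ``p``."""
        return sloan_expected_frequency(p, self.Nm_, self.detection_limit_)

    def result_(self) -> NcmFit:
        return NcmFit(
            self.N_, self.m_, self.Nm_, self.r_squared_, self.detection_limit_,
            len(self.stats_), self.n_samples_, self.stats_,
        )


def fit_ncm(table: OtuTable, min_otus: int = 50, otu_ids=None) -> NcmFit:
    """Fit the neutral model; see :class:`NeutralCommunityModel`."""
    return NeutralCommunityModel(min_otus=min_otus).fit(table, otu_ids=otu_ids).result_()


def envelope_partition(fit: NcmFit) -> dict:
    """Counts of OTUs above / within / below the 95% envelope."""
    counts = fit.stats["status"].value_counts()
    return {k: int(counts.get(k, 0)) for k in ("above", "within", "below")}
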