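"""Abundance-based subcommunity classification of OTUs.

Every OTU is assigned to exactly one of six categories from the minimum and
maximum of its per-sample relative abundance, against a rare cutoff ``t_r``
(default 0.01%) and an abundant cutoff ``t_a`` (default 1%):

========  =====================================================
AAT       always abundant: min >= t_a
RT        always rare: max <= t_r
MT        moderate: strictly between cutoffs in every sample
CAT       conditionally abundant: abundant somewhere, never rare
CRT       conditionally rare: rare somewhere, never abundant
CRAT      conditionally rare AND abundant: both extremes occur
========  =====================================================

Zeros count as rare ("rare" is <= t_r, "abundant" is >= t_a).  The rules
are mutually exclusive and exhaustive over (min, max).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .io import OtuTable

CATEGORIES = ["AAT", "CAT", "MT", "CRT", "CRAT", "RT"]

#: Downstream grouping presets: the usual study design merges CRAT with CAT
#: and analyses CRT and RT separately; MT is reported but not analysed.
GROUPINGS = {
    "merged": {"CRAT-CAT": ("CRAT", "CAT"), "CRT": ("CRT",), "RT": ("RT",)},
    "six": {c: (c,) for c in CATEGORIES},
}


@dataclass
class ClassificationThresholds:
    """Relative-abundance cutoffs; defaults 0.01% rare / 1% abundant."""

    rare_cutoff: float = 1e-4
    abundant_cutoff: float = 1e-2

    def __post_init__(self):
        if not 0 < self.rare_cutoff < self.abundant_cutoff < 1:
            raise ValueError("need 0 < rare_cutoff < abundant_cutoff < 1")


@dataclass
class SubcommunityPartition:
    """OTU id -> category mapping plus the thresholds that produced it."""

    categories: dict
    thresholds: ClassificationThresholds
    grouping: str = "six"

    def otus_in(self, cats) -> list:
        cats = set(cats)
        return [o for o, c in self.categories.items() if c in cats]

    def to_series(self) -> pd.Series:
        return pd.Series(self.categories, name="category")


def relative_abundance(table_or_counts) -> np.ndarray:
    """Per-sample proportions; rows sum to 1."""
    counts = (
        table_or_counts.counts
        if isinstance(table_or_counts, OtuTable)
        else np.asarray(table_or_counts)
    )
    totals = counts.sum(axis=1, keepdims=True)
    if np.any(totals == 0):
        bad = np.nonzero(totals.ravel() == 0)[0].tolist()
        raise ValueError(f"zero-total sample(s) at row index {bad}")
    return counts / totals


class SubcommunityClassifier(BaseEstimator):
    """Classify OTUs (columns) of a count or proportion matrix.

    Parameters
    ----------
    rare_cutoff, abundant_cutoff : float
        Relative-abundance thresholds t_r, t_a.

    Attributes
    ----------
    labels_ : ndarray of str, shape (n_otus,)
        Category per column.
    min_, max_ : ndarray
        Per-column min/max relative abundance the rules were applied to.
    """

    def __init__(self, rare_cutoff: float = 1e-4, abundant_cutoff: float = 1e-2):
        self.rare_cutoff = rare_cutoff
        self.abundant_cutoff = abundant_cutoff

    def fit(self, X, y=None):
        thr = ClassificationThresholds(self.rare_cutoff, self.abundant_cutoff)
        X = np.asarray(X, dtype=float)
        rowsum = X.sum(axis=1)
        if not np.allclose(rowsum, 1.0, atol=1e-6):
            X = relative_abundance(X)  # counts given; normalise
        mn = X.min(axis=0)
        mx = X.max(axis=0)
        t_r, t_a = thr.rare_cutoff, thr.abundant_cutoff
        labels = np.empty(X.shape[1], dtype=object)
        rare_somewhere = mn <= t_r
        abundant_somewhere = mx >= t_a
        labels[rare_somewhere & (mx <= t_r)] = "RT"
        labels[rare_somewhere & ~abundant_somewhere & (mx > t_r)] = "CRT"
        labels[rare_somewhere & abundant_somewhere] = "CRAT"
        labels[~rare_somewhere & ~abundant_somewhere] = "MT"
        labels[~rare_somewhere & abundant_somewhere & (mn < t_a)] = "CAT"
        labels[mn >= t_a] = "AAT"
        self.labels_ = labels.astype(str)
        self.min_, self.max_ = mn, mx
        self.thresholds_ = thr
        return self

    def predict(self, X):
        return self.fit(X).labels_


def classify_taxa(
    relabund, thresholds: ClassificationThresholds | None = None,
    otu_ids=None, grouping: str = "six",
) -> SubcommunityPartition:
    """Classify every OTU of a relative-abundance (or count) matrix."""
    thr = thresholds or ClassificationThresholds()
    if isinstance(relabund, OtuTable):
        otu_ids = relabund.otu_ids
        relabund = relative_abundance(relabund)
    clf = SubcommunityClassifier(thr.rare_cutoff, thr.abundant_cutoff).fit(relabund)
    if otu_ids is None:
        otu_ids = [str(i) for i in range(len(clf.labels_))]
    if grouping not in GROUPINGS:
        raise ValueError(f"unknown grouping {grouping!r}")
    return SubcommunityPartition(dict(zip(otu_ids, clf.labels_)), thr, grouping)


def partition_summary(partition: SubcommunityPartition, table: OtuTable) -> pd.DataFrame:
    """Per-category OTU and read counts with percentage shares.

    Always reports all six categories (zero rows included), so tables are
    comparable across domains even when a category is empty.
    """
    missing = [o for o in table.otu_ids if o not in partition.categories]
    if missing:
        raise ValueError(f"partition does not cover OTUs: {missing[:5]}...")
    labels = np.array([partition.categories[o] for o in table.otu_ids])
    reads = table.counts.sum(axis=0)
    rows = []
    total_reads = reads.sum()
    for cat in CATEGORIES:
        mask = labels == cat
        rows.append(
            {
                "category": cat,
                "n_otus": int(mask.sum()),
                "pct_otus": 100.0 * mask.sum() / table.n_otus,
                "n_reads": int(reads[mask].sum()),
                "pct_reads": 100.0 * reads[mask].sum() / total_reads,
            }
        )
    return pd.DataFrame(rows).set_index("category")


def subset_by_category(
    table: OtuTable, partition: SubcommunityPartition, categories
) -> OtuTable:
    """Restrict a table to the OTUs whose category is in ``categories``."""
    if not categories:
        raise ValueError("categories must be non-empty")
    unknown = set(categories) - set(CATEGORIES)
    if unknown:
        raise ValueError(f"unknown categories: {sorted(unknown)}")
    keep = partition.otus_in(categories)
    keep = [o for o in table.otu_ids if o in set(keep)]
    if not keep:
        raise ValueError(f"no OTUs in categories {sorted(categories)}")
    sub = table.select_otus(keep)
    empty = [s for s, t in zip(sub.sample_ids, sub.sample_totals()) if t == 0]
    if empty:
        import logging

        logging.getLogger(__name__).warning(
            "subset leaves %d sample(s) with zero reads: %s", len(empty), empty
        )
    return sub
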