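import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from soilsubcomm import (
    CATEGORIES,
    ClassificationThresholds,
    OtuTable,
    classify_taxa,
    partition_summary,
    relative_abundance,
    subset_by_category,
)

T_R, T_A = 1e-4, 1e-2


def brute_force_category(col, t_r=T_R, t_a=T_A):
    """Independent re-statement of the six min/max rules, one OTU at a time."""
    mn, mx = min(col), max(col)
    rare_somewhere = mn <= t_r
    abundant_somewhere = mx >= t_a
    if rare_somewhere and abundant_somewhere:
        return "CRAT"
    if rare_somewhere:
        return "RT" if mx <= t_r else "CRT"
    if abundant_somewhere:
        return "AAT" if mn >= t_a else "CAT"
    return "MT"


def _from_rows(rows):
    rel = np.asarray(rows, dtype=float)
    return rel / rel.sum(axis=1, keepdims=True)


def test_relative_abundance_rows_sum_to_one(random_table):
    rel = relative_abundance(random_table)
    assert np.allclose(rel.sum(axis=1), 1.0, atol=1e-9)
    assert np.all((rel == 0) == (random_table.counts == 0))


def test_relative_abundance_zero_sample_errors():
    t = OtuTable(["a", "b"], ["x"], np.array([[1], [0]]))
    with pytest.raises(ValueError, match="zero-total"):
        relative_abundance(t)


@pytest.mark.parametrize(
    "abunds,expected",
    [
        ((5e-5, 2e-5), "RT"),
        ((2e-2, 1.5e-2), "AAT"),
        ((5e-4, 5e-3), "MT"),
        ((5e-5, 5e-3), "CRT"),
        ((5e-4, 2e-2), "CAT"),
        ((5e-5, 2e-2), "CRAT"),
    ],
)
def test_classify_each_branch(abunds, expected):
    """One OTU per branch of the six-way rule, with a filler OTU."""
    rel = np.zeros((2, 2))
    rel[:, 0] = abunds
    rel[:, 1] = 1.0 - rel[:, 0]
    part = classify_taxa(rel, otu_ids=["target", "filler"])
    assert part.categories["target"] == expected


def test_classifier_matches_bruteforce_oracle(rng):
    rel = rng.dirichlet(np.full(300, 0.03), size=15)
    part = classify_taxa(rel, otu_ids=[str(j) for j in range(300)])
    for j in range(300):
        assert part.categories[str(j)] == brute_force_category(rel[:, j]), j


def test_classification_depth_invariance(rng):
    """Scaling one sample's counts leaves every label unchanged."""
    counts = rng.integers(0, 2000, size=(8, 120)) + 1
    t1 = OtuTable([f"s{i}" for i in range(8)], [f"o{j}" for j in range(120)], counts)
    counts2 = counts.copy()
    counts2[3] *= 17
    t2 = OtuTable(t1.sample_ids, t1.otu_ids, counts2)
    assert classify_taxa(t1).categories == classify_taxa(t2).categories


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_raising_abundant_cutoff_never_creates_rt(seed):
    rel = np.random.default_rng(seed).dirichlet(np.full(60, 0.05), size=6)
    ids = [str(j) for j in range(60)]
    low = classify_taxa(rel, ClassificationThresholds(T_R, 5e-3), otu_ids=ids)
    high = classify_taxa(rel, ClassificationThresholds(T_R, 5e-2), otu_ids=ids)
    for j in ids:
        if low.categories[j] in ("AAT", "CAT", "CRAT"):
            assert high.categories[j] != "RT"


def test_all_between_cutoffs_is_mt():
    rel = np.full((4, 500), 1 / 500)  # 0.2% each: strictly between cutoffs
    part = classify_taxa(rel, otu_ids=[str(j) for j in range(500)])
    assert set(part.categories.values()) == {"MT"}


def test_partition_summary_shares(random_table):
    part = classify_taxa(random_table)
    summary = partition_summary(part, random_table)
    assert list(summary.index) == CATEGORIES
    assert summary["pct_otus"].sum() == pytest.approx(100.0, abs=1e-6)
    assert summary["pct_reads"].sum() == pytest.approx(100.0, abs=1e-6)
    assert summary["n_otus"].sum() == random_table.n_otus


def test_partition_summary_known_construction():
    # 2 OTUs always abundant, 3 always rare, at depth 10000
    counts = np.zeros((2, 5), dtype=int)
    counts[:, 0] = 4999
    counts[:, 1] = 4998
    counts[:, 2:] = 1
    t = OtuTable(["a", "b"], [f"o{j}" for j in range(5)], counts)
    summary = partition_summary(classify_taxa(t), t)
    assert summary.loc["AAT", "n_otus"] == 2
    assert summary.loc["RT", "n_otus"] == 3
    assert summary.loc["RT", "pct_otus"] == pytest.approx(60.0)
    assert summary.loc["RT", "n_reads"] == 6


def test_subset_by_category(random_table):
    part = classify_taxa(random_table)
    full = subset_by_category(random_table, part, set(CATEGORIES))
    assert full.otu_ids == random_table.otu_ids
    with pytest.raises(ValueError, match="non-empty"):
        subset_by_category(random_table, part, set())
    some = [c for c in CATEGORIES if part.otus_in([c])][0]
    sub = subset_by_category(random_table, part, {some})
    assert set(sub.otu_ids) == set(part.otus_in([some]))
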