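import numpy as np
import pytest
from scipy.integrate import quad
from scipy.stats import beta as beta_dist

from soilsubcomm import (
    NeutralCommunityModel,
    NeutralSimConfig,
    OtuTable,
    envelope_partition,
    fit_ncm,
    occurrence_stats,
    simulate_neutral,
    sloan_expected_frequency,
)


def test_occurrence_stats_definitions():
    counts = np.array([[1, 0, 5], [0, 0, 5], [0, 1, 4]])
    t = OtuTable(["a", "b", "c"], ["x", "y", "z"], counts)
    with pytest.raises(ValueError, match="uneven"):
        occurrence_stats(t)
    counts = np.array([[1, 0, 5], [0, 1, 5], [0, 1, 5]])
    t = OtuTable(["a", "b", "c"], ["x", "y", "z"], counts)
    st = occurrence_stats(t)
    assert st.loc["x", "freq"] == pytest.approx(1 / 3)
    assert st.loc["x", "p"] == pytest.approx(1 / (3 * 6))
    assert st.loc["z", "freq"] == 1.0


def test_sloan_frequency_limits_and_quadrature_oracle():
    assert sloan_expected_frequency(1 - 1e-9, 1000.0, 5e-5) > 1 - 1e-6
    assert sloan_expected_frequency(1e-9, 1000.0, 5e-5) < 1e-5
    # numerical integral of the beta density over [0, d]
    p, Nm, d = 0.001, 1000.0, 5e-5
    dens = beta_dist(Nm * p, Nm * (1 - p)).pdf
    below, _ = quad(dens, 0, d)
    assert sloan_expected_frequency(p, Nm, d) == pytest.approx(1 - below, abs=1e-6)
    with pytest.raises(ValueError):
        sloan_expected_frequency(0.5, -1.0, 1e-4)
    with pytest.raises(ValueError):
        sloan_expected_frequency(1.5, 10.0, 1e-4)


@pytest.mark.parametrize("Nm,d", [(50.0, 1e-3), (2000.0, 1e-4)])
def test_sloan_frequency_monotone_in_p(Nm, d):
    grid = np.logspace(-6, -0.5, 60)
    vals = sloan_expected_frequency(grid, Nm, d)
    assert np.all(np.diff(vals) >= -1e-12)
    assert np.all((vals >= 0) & (vals <= 1))


def test_fit_recovers_constructed_perfect_data(monkeypatch):
    """Frequencies placed exactly on the curve are refit with R2 = 1."""
    import pandas as pd

    import soilsubcomm.ncm as ncm_mod

    N, m, S = 5000, 0.07, 40
    p = np.logspace(-5.5, -2, 300)
    freq = sloan_expected_frequency(p, N * m, 1.0 / N)
    stats = pd.DataFrame({"p": p, "freq": freq}, index=[f"o{i}" for i in range(300)])
    stats.attrs["N"] = N
    stats.attrs["n_samples"] = S
    monkeypatch.setattr(ncm_mod, "occurrence_stats", lambda table, otu_ids=None: stats)
    model = NeutralCommunityModel(min_otus=10)
    model.fit(OtuTable(["s"], ["o"], np.array([[1]])))
    assert model.m_ == pytest.approx(m, rel=1e-4)
    assert model.r_squared_ == pytest.approx(1.0, abs=1e-9)


def test_negative_r2_when_anticorrelated():
    """Occupancy anticorrelated with abundance fits worse than a constant."""
    N, S = 2000, 30
    n = 200
    rng = np.random.default_rng(0)
    counts = np.zeros((S, n), dtype=int)
    # abundant OTUs concentrated in one sample (low occupancy), rare OTUs
    # spread thin across all samples (high occupancy)
    for j in range(n // 2):
        counts[j % S, j] = 60
    for j in range(n // 2, n):
        counts[:, j] = 1
    deficit = N - counts.sum(axis=1)
    counts[:, 0] += deficit
    t = OtuTable([f"s{i}" for i in range(S)], [f"o{j}" for j in range(n)], counts)
    fit = fit_ncm(t, min_otus=10)
    assert fit.r_squared < 0


def test_parameter_recovery_from_generator():
    """The fitter recovers the generating Nm from its own sampling dual."""
    cfg = NeutralSimConfig(
        n_samples=46, n_otus=5000, reads_per_sample=10000, m=0.1, seed=8
    )
    fit = fit_ncm(simulate_neutral(cfg))
    true_nm = 10000 * 0.1
    assert abs(fit.Nm - true_nm) / true_nm < 0.10
    assert fit.r_squared > 0.8


def test_fit_invariant_to_otu_ordering(rng):
    cfg = NeutralSimConfig(
        n_samples=20, n_otus=400, reads_per_sample=2000, m=0.2, seed=3
    )
    t = simulate_neutral(cfg)
    perm = rng.permutation(t.n_otus)
    t2 = OtuTable(
        t.sample_ids, [t.otu_ids[j] for j in perm], t.counts[:, perm]
    )
    assert fit_ncm(t).Nm == pytest.approx(fit_ncm(t2).Nm, rel=1e-6)


def test_envelope_partition_counts_and_coverage():
    cfg = NeutralSimConfig(
        n_samples=46, n_otus=2000, reads_per_sample=5000, m=0.15, seed=4
    )
    fit = fit_ncm(simulate_neutral(cfg))
    env = envelope_partition(fit)
    assert sum(env.values()) == fit.n_otus_used
    assert env["within"] / fit.n_otus_used >= 0.8


def test_min_otus_floor():
    t = OtuTable(
        ["a", "b"], [f"o{j}" for j in range(5)], np.full((2, 5), 2, dtype=int)
    )
    with pytest.raises(ValueError, match="at least"):
        fit_ncm(t, min_otus=50)


def test_subset_fit_uses_full_depth():
    cfg = NeutralSimConfig(
        n_samples=30, n_otus=1000, reads_per_sample=4000, m=0.1, seed=9
    )
    t = simulate_neutral(cfg)
    subset = [o for o, tot in zip(t.otu_ids, t.counts.sum(0)) if 0 < tot < 200]
    fit = fit_ncm(t, min_otus=10, otu_ids=subset)
    assert fit.N == 4000
    assert fit.n_otus_used == len(
        [o for o in subset if t.counts[:, t.otu_ids.index(o)].sum() > 0]
    )
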