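"""Synthetic community and study-design generators.

Two generative models bracket the assembly processes the analysis is meant
to distinguish:

* a **neutral** generator following the Sloan sampling form — each local
  community is a finite sample whose per-taxon relative abundance is drawn
  from a beta distribution parameterised by the immigration-scaled
  parameter ``N*m`` and the metacommunity relative abundance ``p_i``;

* a **niche** generator in which expected abundances follow Gaussian
  response curves along spatially autocorrelated environmental gradients
  (environmental filtering).

A study-design generator emulates the field layout the pipeline assumes:
46 sites in a bounded urban area spanning 7 land-use types with unequal
replication (8/8/8/8/6/4/4) and six soil variables with land-use-specific
means.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ENV_VARIABLES, OtuTable, SampleMetadata

#: Replicate counts used when 46 sites / 7 land uses are requested,
#: mirroring a typical urban sampling design.
DESIGN_46_7 = (8, 8, 8, 8, 6, 4, 4)

_LANDUSE_NAMES = [
    "forest", "greenbelt", "park", "residential", "industrial", "farmland", "hospital",
]

# Realistic (low, high) ranges for land-use-specific means of the six soil
# variables: moisture %, pH, total P / C / N (g per kg), C:N ratio.
_ENV_RANGES = {
    "moisture": (10.0, 40.0),
    "pH": (4.5, 8.5),
    "TP": (0.2, 1.5),
    "TC": (5.0, 50.0),
    "TN": (0.5, 5.0),
    "CN": (8.0, 20.0),
}

# Bounding box roughly the size of a coastal city.
_LON_BOX = (121.4, 121.9)
_LAT_BOX = (29.65, 29.95)


def lognormal_metacommunity(n_otus: int, sigma: float = 2.0, seed=None) -> np.ndarray:
    """Lognormal rank-abundance distribution normalised to a simplex.

    The standard null for soil species-abundance distributions; ``sigma``
    controls evenness (larger -> steeper dominance, longer rare tail).
    """
    rng = np.random.default_rng(seed)
    ab = rng.lognormal(mean=0.0, sigma=sigma, size=n_otus)
    return ab / ab.sum()


@dataclass
class NeutralSimConfig:
    """Parameters of the neutral (beta-binomial) community generator.

    ``m`` is the immigration probability: the chance that a death in the
    local community is replaced from the metacommunity rather than by local
    reproduction.  ``reads_per_sample`` (N) is both the community size in
    the sampling model and the even sequencing depth of the output.
    """

    n_samples: int = 46
    n_otus: int = 5000
    reads_per_sample: int = 16000
    m: float = 0.1
    metacommunity: np.ndarray | None = None
    lognormal_sigma: float = 2.0
    seed: int | None = None

    def __post_init__(self):
        if self.reads_per_sample < 1:
            raise ValueError("reads_per_sample must be >= 1")
        if not 0 < self.m <= 1:
            raise ValueError("immigration m must be in (0, 1]")
        if self.metacommunity is not None:
            p = np.asarray(self.metacommunity, dtype=float)
            if p.shape != (self.n_otus,):
                raise ValueError("metacommunity length must equal n_otus")
            if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
                raise ValueError("metacommunity must be a simplex vector (sum 1)")
            if not np.any(p > 0):
                raise ValueError("metacommunity has no positive entries")
            self.metacommunity = p


@dataclass
class NicheSimConfig:
    """Parameters of the niche (environmental-filtering) generator.

    Each OTU has an optimum on each gradient; expected abundance decays as a
    Gaussian of niche breadth ``sigma_niche`` around it.  Gradients are
    spatially autocorrelated Gaussian-process fields over the generated
    site coordinates (exponential kernel, range ``spatial_range`` in the
    coordinate units), which induces the env-space collinearity variation
    partitioning must untangle.
    """

    n_samples: int = 46
    n_otus: int = 1000
    reads_per_sample: int = 10000
    n_gradients: int = 2
    sigma_niche: float = 0.5
    noise_sd: float = 0.2
    spatial_range: float = 0.1
    seed: int | None = None

    def __post_init__(self):
        if self.sigma_niche <= 0:
            raise ValueError("sigma_niche must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_gradients > len(ENV_VARIABLES):
            raise ValueError(
                f"n_gradients > {len(ENV_VARIABLES)}: only "
                f"{len(ENV_VARIABLES)} metadata slots exist"
            )
        if self.n_gradients < 1:
            raise ValueError("n_gradients must be >= 1")


def _sample_ids(n: int) -> list:
    return [f"S{i + 1:03d}" for i in range(n)]


def _otu_ids(n: int) -> list:
    return [f"OTU{i + 1:05d}" for i in range(n)]


def _exact_depth(rng: np.random.Generator, counts: np.ndarray, n: int) -> np.ndarray:
    """Adjust an integer count vector to sum exactly to ``n`` reads.

    Excess reads are removed by uniform subsampling without replacement;
    missing reads are added multinomially in proportion to the current
    counts (or uniformly if the vector is all zero).
    """
    total = int(counts.sum())
    if total == n:
        return counts
    if total > n:
        return rng.multivariate_hypergeometric(counts, n)
    probs = counts / total if total > 0 else np.full(len(counts), 1.0 / len(counts))
    return counts + rng.multinomial(n - total, probs)


def simulate_neutral(config: NeutralSimConfig) -> OtuTable:
    """Draw an OTU table from the Sloan neutral sampling model.

    Each sample is a local community of N individuals whose per-taxon
    relative abundance follows the model's stationary beta law,
    ``x_i ~ Beta(N*m*p_i, N*m*(1 - p_i))``.  Counts are the finite-
    community discretisation of that law: a taxon below the one-individual
    detection limit (``x < 1/N``) is absent, otherwise its count is
    ``N*x_i`` stochastically rounded; each sample is then renormalised to
    exactly N reads.  This makes the generator the exact sampling dual of
    the occupancy curve the neutral-model fitter estimates (detection
    limit ``d = 1/N``).
    """
    rng = np.random.default_rng(config.seed)
    N = config.reads_per_sample
    p = config.metacommunity
    if p is None:
        p = lognormal_metacommunity(config.n_otus, config.lognormal_sigma, rng)
    Nm = N * config.m
    a = Nm * p
    b = Nm * (1.0 - p)
    if not np.all(np.isfinite(a)) or not np.all(np.isfinite(b)):
        raise OverflowError(
            "beta parameters overflow; use a smaller reads_per_sample * m"
        )
    counts = np.empty((config.n_samples, config.n_otus), dtype=np.int64)
    for s in range(config.n_samples):
        x = rng.beta(a, b)
        # beta draws of exactly 0/1 break downstream arithmetic; clamp
        np.clip(x, 1e-12, 1.0 - 1e-12, out=x)
        nx = N * x
        base = np.floor(nx)
        row = np.where(
            nx >= 1.0, base + (rng.random(config.n_otus) < (nx - base)), 0
        ).astype(np.int64)
        counts[s] = _exact_depth(rng, row, N)
    return OtuTable(_sample_ids(config.n_samples), _otu_ids(config.n_otus), counts)


def _landuse_counts(n_samples: int, n_landuse: int) -> list:
    if n_landuse > n_samples:
        raise ValueError("n_landuse cannot exceed n_samples")
    if n_samples == 46 and n_landuse == 7:
        return list(DESIGN_46_7)
    base, extra = divmod(n_samples, n_landuse)
    return [base + (1 if i < extra else 0) for i in range(n_landuse)]


def simulate_metadata(n_samples: int = 46, n_landuse: int = 7, seed=None) -> SampleMetadata:
    """Emulate the study design: coordinates in a bounded box, land-use
    groups with unequal replication, and soil variables with land-use-
    specific means."""
    rng = np.random.default_rng(seed)
    counts = _landuse_counts(n_samples, n_landuse)
    names = [
        _LANDUSE_NAMES[i] if i < len(_LANDUSE_NAMES) else f"landuse{i + 1}"
        for i in range(n_landuse)
    ]
    land_use = np.repeat(names, counts)
    lon = rng.uniform(*_LON_BOX, size=n_samples)
    lat = rng.uniform(*_LAT_BOX, size=n_samples)
    env = {}
    for var in ENV_VARIABLES:
        lo, hi = _ENV_RANGES[var]
        group_means = rng.uniform(lo, hi, size=n_landuse)
        within_sd = 0.1 * (hi - lo)
        vals = np.repeat(group_means, counts) + rng.normal(0, within_sd, n_samples)
        env[var] = np.clip(vals, lo * 0.5, hi * 1.5)
    return SampleMetadata(
        _sample_ids(n_samples), land_use, lon, lat, pd.DataFrame(env)
    )


def _gp_field(rng, coords: np.ndarray, length_scale: float) -> np.ndarray:
    """One draw of a zero-mean unit-variance GP with exponential kernel."""
    d = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1))
    K = np.exp(-d / length_scale) + 1e-8 * np.eye(len(coords))
    L = np.linalg.cholesky(K)
    return L @ rng.standard_normal(len(coords))


def simulate_niche(config: NicheSimConfig) -> tuple[OtuTable, SampleMetadata]:
    """Draw an OTU table shaped by Gaussian responses to spatially
    autocorrelated environmental gradients, plus matching metadata.

    The generating gradients are mapped (affinely) onto the first
    ``n_gradients`` named soil variables of the metadata; the remaining
    slots carry uncorrelated noise so every metadata column exists.
    """
    rng = np.random.default_rng(config.seed)
    n, k = config.n_samples, config.n_gradients
    meta = simulate_metadata(n, 7 if n >= 7 else 1, seed=rng.integers(2**31))
    coords = np.column_stack([meta.lon, meta.lat])
    gradients = np.column_stack(
        [_gp_field(rng, coords, config.spatial_range) for _ in range(k)]
    )
    optima = rng.uniform(-2.0, 2.0, size=(config.n_otus, k))
    base = lognormal_metacommunity(config.n_otus, 1.0, rng)
    # log expected abundance: Gaussian response summed over gradients
    sq = ((gradients[:, None, :] - optima[None, :, :]) ** 2).sum(-1)
    log_lambda = np.log(base)[None, :] - sq / (2.0 * config.sigma_niche**2)
    if config.noise_sd > 0:
        log_lambda = log_lambda + rng.normal(0, config.noise_sd, log_lambda.shape)
    lam = np.exp(log_lambda - log_lambda.max(axis=1, keepdims=True))
    probs = lam / lam.sum(axis=1, keepdims=True)
    counts = np.empty((n, config.n_otus), dtype=np.int64)
    for s in range(n):
        counts[s] = rng.multinomial(config.reads_per_sample, probs[s])
    table = OtuTable(_sample_ids(n), _otu_ids(config.n_otus), counts)
    # overwrite the first k soil variables with affine images of the gradients
    env = meta.env.copy()
    for g in range(k):
        var = ENV_VARIABLES[g]
        lo, hi = _ENV_RANGES[var]
        z = gradients[:, g]
        span = z.max() - z.min()
        if span == 0:
            span = 1.0
        env[var] = lo + (z - z.min()) / span * (hi - lo)
    meta = SampleMetadata(meta.sample_ids, meta.land_use, meta.lon, meta.lat, env)
    return table, meta
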