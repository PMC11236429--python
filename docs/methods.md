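# Methods

This note documents the models implemented in `soilsubcomm`, the defaults
and why they were chosen, what the synthetic generators do and do not
emulate, and the numerical conventions that make results reproducible.

## Subcommunity classification

Classification operates on per-sample relative abundances, so it is
invariant to sequencing depth. With `min_i`/`max_i` the extremes of OTU
*i* across samples, a rare cutoff `t_r` and an abundant cutoff `t_a`
(defaults 10⁻⁴ and 10⁻², i.e. 0.01% and 1%):

| category | rule |
|----------|------|
| RT   | `max ≤ t_r` |
| CRT  | `min ≤ t_r` and `t_r < max < t_a` |
| CRAT | `min ≤ t_r` and `max ≥ t_a` |
| MT   | `t_r < min` and `max < t_a` |
| CAT  | `min > t_r` and `max ≥ t_a` and `min < t_a` |
| AAT  | `min ≥ t_a` |

The rules are mutually exclusive and exhaustive over (min, max); zeros
count as rare ("rare" is inclusive `≤ t_r`, "abundant" inclusive
`≥ t_a`). Inclusive boundaries are stated explicitly because published
descriptions of this scheme often lose the inequality symbols in
typesetting; any boundary convention is defensible, but an undocumented
one is irreproducible. Both cutoffs are parameters. The `paper` grouping
preset merges CRAT with CAT and carries RT and CRT separately (MT and AAT
are always reported in summaries even when empty), matching how these
subcommunities are usually analysed; the `six` preset keeps all
categories distinct.

## Rarefaction

Subsampling is uniform without replacement (multivariate hypergeometric),
the convention matched by the analytic expectation
`E[S(n)] = Σ_i [1 − C(N−c_i, n)/C(N, n)]`, computed with log-gamma to
avoid overflow. Samples below the target depth are dropped with a
warning, never padded: the neutral model's detection limit (one read out
of N) is only meaningful at a single common depth.

## Distance decay and permutation tests

Community distance is Bray–Curtis on relative abundances (identical to
counts at even depth). Environmental distance is Euclidean on z-scored
variables; standardisation uses the population standard deviation
(ddof = 0) so "mean 0, sd 1 across samples" holds exactly at any n.
Mantel statistics are Spearman by default and always computed between
dissimilarities; a similarity matrix passed in is converted with a logged
note. Distance-decay figures conventionally plot similarity (1 − BC)
against environmental distance, so the regression slope is reported on
that scale while the test statistic is computed on dissimilarities — the
sign convention is fixed and documented rather than configurable
silently, because similarity-vs-distance and dissimilarity-vs-distance
correlations have opposite signs. One-sided permutation p-values use the
+1 correction, `p = (1 + #{r* ≥ r}) / (1 + n_perm)`, so p can never be 0
and is bounded below by `1/(n_perm + 1)`. ANOSIM follows the rank
definition `R = (r̄_between − r̄_within)/(M/2)` with label permutation.

## PCNM spatial eigenvectors

Geographic distances default to great-circle (haversine, km) on lon/lat,
since study extents are real landscapes; planar Euclidean distance is
available for synthetic coordinates. The classical construction is used:
truncation at the longest minimum-spanning-tree edge `t`, replacement of
larger distances by `4t`, double-centring of `−D²/2`, eigendecomposition,
and retention of eigenvectors with eigenvalue > 10⁻¹⁰ scaled to unit
norm. Eigenvector signs are fixed (largest-magnitude entry positive) so
results are deterministic. Negative-eigenvalue structure is out of scope.

## Forward selection and variation partitioning

Forward selection implements the double stopping rule: candidates are
considered only if the global model passes a permutation test at `alpha`;
each greedy addition is tested by Freedman–Lane permutation of
reduced-model residuals; selection stops when the best candidate's p
exceeds `alpha` or the cumulative adjusted R² would exceed the global
model's. The cap makes the procedure conservative by design: when a
single predictor alone explains as much (adjusted) variance as the full
candidate set, selection can legitimately return nothing.

RDA is the PCA of fitted values from multivariate least squares of the
column-centred, Hellinger-transformed community matrix on the predictors.
The Hellinger transform (square root of relative abundances) is applied
because linear ordination of raw counts is dominated by double zeros and
a few abundant taxa; this is the standard remedy. Variation partitioning
uses adjusted R² (Ezekiel) with the rank of the predictor block, not its
column count, as the degrees of freedom — duplicated or collinear columns
therefore cannot inflate a fraction. With A = adjR²(Y|env),
B = adjR²(Y|space), C = adjR²(Y|both): `a = C − B`, `c = C − A`,
`b = A + B − C`, `d = 1 − C`. Slightly negative `a` or `c` are legitimate
adjustment artifacts and are reported as-is in JSON (displayed as 0 in
percentage summaries). The combined block is assembled in a canonical
column order so that swapping the env and space blocks swaps `a` and `c`
bit-exactly. Unique fractions are tested by partial-RDA permutation
(Freedman–Lane under the covariate block).

## Sloan neutral community model

The model predicts the probability that a taxon with metacommunity
relative abundance `p` is detected in a local community of `N`
individuals, given immigration `m`:

    F(p) = 1 − I_d(N·m·p, N·m·(1 − p)),   d = 1/N,

with `I_d` the regularised incomplete beta function. `m` is estimated by
bounded least squares of observed occurrence frequencies on this curve;
because the 1-D objective can be multi-modal at small problem sizes, the
optimiser is restarted over the bracket grid
{10⁻⁴, 10⁻³, 10⁻², 10⁻¹, 0.5} with convergence tolerance 10⁻¹⁰ on `m`.
The generalised `R² = 1 − SSE/SST` is reported even when negative — a
negative value means the neutral curve predicts occupancy worse than a
flat line, evidence against neutrality. Envelopes are Wilson 95% score
intervals around each predicted frequency with n = number of samples
(Wilson rather than Wald, since predicted frequencies sit near 0 or 1 for
most of the abundance range). Fitting is on untransformed `p`; the log₁₀
axis is presentation only. When a subcommunity is fitted, `p` and the
detection limit still refer to the full community's even depth; only the
subset's OTUs enter the objective (`otu_ids=` argument) — a subcommunity
is a slice of the community, not a community with fewer reads.

## Synthetic generators

The generators exist so that every downstream stage has data of known
provenance at the scale of a real study: 46 samples, thousands of OTUs,
rarefied depths of 10³–10⁴ reads, 7 land-use groups with 8/8/8/8/6/4/4
replication, six soil variables with land-use-specific means drawn from
ranges typical of urban soils (moisture 10–40%, pH 4.5–8.5, TP
0.2–1.5 g/kg, TC 5–50 g/kg, TN 0.5–5 g/kg, C:N 8–20). Read depth after
rarefaction is a free parameter throughout, since it varies between
studies and domains.

**Neutral generator.** Metacommunity abundances default to a lognormal
rank-abundance distribution (σ = 2) normalised to a simplex — the
standard null for soil communities, with a realistic rare tail. Each
sample's latent relative abundances are independent draws
`x_i ~ Beta(N·m·p_i, N·m·(1 − p_i))`, the stationary law of the model.
Counts are the finite-community discretisation of that law: a taxon whose
latent abundance is below the one-individual detection limit (`x < 1/N`)
is absent; otherwise its count is `N·x` stochastically rounded; each
sample is then adjusted to exactly `N` reads (excess removed by uniform
subsampling, deficit added multinomially in proportion to counts, which
creates no spurious detections). This makes the generator the exact
sampling dual of the occupancy curve the fitter estimates: detection
happens precisely at the advertised limit `d = 1/N`. An alternative —
drawing reads binomially from the latent abundance — adds a second
sampling layer that detects taxa below `d` and systematically inflates
the fitted `Nm` by 35–45% at moderate-to-high immigration; it was
rejected for that reason. Beta draws of exactly 0 or 1 are clamped to
[10⁻¹², 1 − 10⁻¹²] for numerical safety.

**Estimator accuracy.** Even with the exact sampling dual, the standard
least-squares fit is not uniformly consistent at 46 samples: the per-OTU
mean abundance axis is itself estimated from the same noisy draws. At
small `Nm` (≈ 10–100) the latent beta noise is enormous relative to `p`
and this errors-in-variables effect biases the fitted `Nm` low by
15–35%; at large `Nm` with `N = 10⁴` (transition region at ~1 read) the
censoring of sub-detection-limit mass biases it high by ~20%. In the
mid-range that real soil fits occupy (`Nm` ≈ 10²–3·10³ at
`N ≈ 10³–2·10⁴`) recovery is accurate to a few percent. The test suite
asserts recovery where the estimator is consistent and exercises the full
grid so the failure modes stay visible rather than hidden.

**Niche generator.** Environmental gradients are zero-mean Gaussian
processes with exponential kernel over the generated site coordinates
(range parameter in coordinate units), which induces the env–space
collinearity that variation partitioning must disentangle. Expected OTU
abundance is a lognormal baseline times Gaussian response curves
`exp(−(env − optimum)²/2σ²_niche)` summed over gradients, with optional
lognormal noise; counts are multinomial per sample. The generating
gradients are written onto the first `n_gradients` named soil variables
of the metadata (affine map into realistic ranges) so that
`environmental_distance` sees them. As `σ_niche → ∞` the composition
becomes gradient-independent and all environmental diagnostics go null.

**What the generators do not emulate:** sequence-level artifacts
(chimeras, quality loss), taxonomy, temporal dynamics, species
interactions, and phylogenetic structure. Passing tests therefore show
that the statistical machinery behaves correctly under its own
assumptions, not that any particular real community is neutral or
niche-structured.

## Pipeline and determinism

`run_pipeline` executes rarefy → classify → per-subcommunity distance
decay and ANOSIM → PCNM + forward selection → variation partitioning →
neutral-model fit for each configured domain, writing stage TSVs and one
JSON report. Per-stage seeds are derived from a single master seed via
`numpy.random.SeedSequence.spawn`, so a config fully determines every
number; the report's provenance block carries a config hash and the
package version but no wall-clock timestamps, making identical runs
byte-identical. Subcommunities smaller than the neutral-model floor
(default 50 OTUs) are reported as "not fitted" rather than failing the
run; empty categories are reported as empty. When forward selection
returns no variables for a block, variation partitioning falls back to
the full block and the report records the (empty) selection.

## Problem sizes in tests

The suite runs at the study's native sample size (46) with OTU counts
from a few hundred (unit tests) to 5,000 (parameter-recovery and
acceptance checks), 999 permutations where a p-value's resolution
matters and 49–199 where only calibration or determinism is being
exercised. The complete suite finishes in a few minutes on one core.
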