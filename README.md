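# soilsubcomm

Abundance-based subcommunity analysis of microbial OTU tables, built for
studies that ask *which assembly processes — environmental selection or
stochastic dispersal and drift — structure the rare, abundant and
transient fractions of soil bacterial, fungal and protist communities.*

Amplicon surveys of soils routinely recover thousands of OTUs whose
abundances span five orders of magnitude. Collapsing them into one
"community" hides that the always-abundant taxa, the conditionally rare
taxa (CRT), and the permanently rare tail can be governed by different
ecology. `soilsubcomm` implements the full subcommunity workflow as a
tested Python package:

1. **Rarefaction** to even depth, with analytic (hypergeometric)
   rarefaction curves as the sequencing-sufficiency check.
2. **Six-category classification** of every OTU from the minimum and
   maximum of its per-sample relative abundance against a rare cutoff
   `t_r` (default 0.01%) and an abundant cutoff `t_a` (default 1%):
   AAT (always abundant, min ≥ t_a), RT (always rare, max ≤ t_r),
   MT (moderate), CAT (conditionally abundant), CRT (conditionally rare,
   never abundant), CRAT (both extremes). A grouping preset merges
   CRAT+CAT for downstream analysis, mirroring common practice.
3. **Distance decay**: Bray–Curtis dissimilarity vs z-scored Euclidean
   environmental distance, with Spearman Mantel tests (999 permutations),
   ANOSIM over land-use groups, and the similarity-vs-distance OLS slope.
4. **Spatial structure**: PCNM eigenvectors (minimum-spanning-tree
   truncation, distances beyond the threshold set to 4t, positive
   eigenvalues only) and Blanchet-style forward selection with the double
   stopping rule (per-step permutation test plus global adjusted-R² cap).
5. **Variation partitioning**: Hellinger-transformed community matrices
   partitioned by (partial) RDA into unique environmental (a), shared (b),
   unique spatial (c) and residual (d) adjusted-R² fractions, with
   Ezekiel's correction `adjR² = 1 − (1 − R²)(n − 1)/(n − p − 1)`.
6. **Sloan neutral community model**: occurrence frequency vs mean
   relative abundance fitted by bounded least squares of
   `F(p) = 1 − I_d(Nm·p, Nm·(1 − p))` (beta CDF at the one-read detection
   limit `d = 1/N`), reporting the immigration rate `m`, `Nm`, the
   generalised R² (negative when the neutral curve predicts worse than a
   constant), and per-OTU Wilson 95% envelopes.
7. **Synthetic generators** for both endpoints of the assembly spectrum —
   a neutral (beta-distributed local abundances at parameter `N·m`) and a
   niche generator (Gaussian responses along spatially autocorrelated
   environmental gradients) plus a study-design generator (46 sites,
   7 land-use types with 8/8/8/8/6/4/4 replication, six soil variables) —
   so every stage is testable without any sequencing data.

Most stages are exposed both as functions and as scikit-learn-style
estimators (`SubcommunityClassifier`, `Rarefier`, `PCNM`, `RDA`,
`ForwardSelector`, `VariationPartitioning`, `NeutralCommunityModel`) that
compose with sklearn pipelines and carry fitted attributes
(`labels_`, `Nm_`, `eigenvalues_`, ...).

## Worked example

Simulate a neutral community at the scale of one rarefied soil domain,
classify it, and ask the pipeline which process built it:

```python
import soilsubcomm as ssc

table = ssc.simulate_neutral(ssc.NeutralSimConfig(
    n_samples=46, n_otus=3000, reads_per_sample=8000, m=0.12, seed=42))
meta = ssc.simulate_metadata(46, 7, seed=43)
table = ssc.rarefy_table(table, seed=0)

part = ssc.classify_taxa(table)
print(ssc.partition_summary(part, table).round(2))

crt = ssc.subset_by_category(table, part, {"CRT"})
fit = ssc.fit_ncm(table, otu_ids=crt.otu_ids)
print(f"NCM (CRT): m = {fit.m:.4f}, Nm = {fit.Nm:.0f}, R2 = {fit.r_squared:.2f}")

mt = ssc.mantel(ssc.bray_curtis(crt), ssc.environmental_distance(meta),
                n_permutations=999, seed=1)
print(f"Mantel (CRT vs env): r = {mt.r:.3f}, p = {mt.p_value:.3f}")
```

Output:

```
          n_otus  pct_otus  n_reads  pct_reads
category
AAT            3      0.13    25488       6.93
CAT           42      1.78   118503      32.20
MT            58      2.46    58233      15.82
CRT         2249     95.54   164753      44.77
CRAT           2      0.08     1023       0.28
RT             0      0.00        0       0.00

NCM (CRT): m = 0.1214, Nm = 971, R2 = 0.96
Mantel (CRT vs env): r = -0.056, p = 0.867
```

Read: most OTUs are conditionally rare; the neutral fit recovers the
generating immigration parameter (true `N·m` = 8000 × 0.12 = 960) with a
tight fit (R² = 0.96), and community turnover shows no relationship with
the (causally unrelated) soil variables — exactly what a
dispersal-and-drift community should look like. Running the same script
on a niche-simulated table flips every diagnostic: strong positive Mantel
r, a large unique environmental fraction in the VPA, and a poor neutral
fit.

The same workflow runs from the shell:

```bash
soilsubcomm simulate --model neutral --n-samples 46 --n-otus 3000 \
    --depth 8000 --m 0.12 --seed 42 --out-prefix demo
soilsubcomm classify --otu-table demo_otu.tsv --out-prefix demo
soilsubcomm ncm --otu-table demo_otu.tsv
soilsubcomm run-all --config pipeline.yaml   # full multi-domain study
```

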