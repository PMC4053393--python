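# antnet

Analysis of **individual-based ant–plant interaction networks**: bipartite
networks in which one node class is the individual plants of a single
extrafloral-nectary (EFN)-bearing plant species and the other is the ant
species collecting nectar on them. The package is aimed at community
ecologists who sample such interactions in the field over the day–night
cycle and want the standard structural descriptor battery, null-model
significance, and the species–area analysis, reproducibly and from plain
CSV inputs.

## What it computes

From long-format interaction records (plant individual, ant species,
period ∈ {diurnal, nocturnal}, count) the package builds three weighted
ant × plant matrices **A** (diurnal, nocturnal, whole-day) with
`a_ij` = number of interaction events, and computes:

- **Nestedness, NODF** (0–100): mean paired overlap
  `100·|shared 1s|/fill(sparser)` over all row pairs and column pairs with
  strictly decreasing fill.
- **Specialization, H2'** (0–1): `H2' = (H2max − H2)/(H2max − H2min)` with
  `H2 = −Σ p_ij ln p_ij`, `H2max` from the margin-product distribution and
  `H2min` from a greedy integer concentration of the margins.
- **Modularity, M** (0–1): Barber bipartite modularity
  `Q = (1/m) Σ_ij [a_ij − k_i d_j/m] δ(g_i, g_j)`, maximized by seeded
  simulated annealing (best-of-5 restarts), with an exhaustive oracle for
  ≤10-node instances and a unipartite Newman projection as a sensitivity
  variant.
- **Null Model II (CE) significance**: each cell occupied with probability
  `(P_i + P_j)/2` (mean of row and column fill proportions); empirical
  upper-tail p with add-one correction and z-score, default 1000 draws.
- **Generalist core, Gc**: `Gc_i = (k_i − k_mean)/σ_k` on binary degrees;
  species with Gc > 1 form the core. Day/night **core turnover**
  `1 − |core_D ∩ core_N|/|core_D ∪ core_N|` and assemblage **Jaccard
  similarity** `|D ∩ N|/|D ∪ N|`.
- **Species–area analysis**: per-plant EFN totals estimated from branch
  samples (mean branch count × total branches, or the per-leaf variant),
  OLS regression of per-plant ant richness on EFN totals, and a one-sample
  t-test of the EFN counts against an explicit reference.

A seeded synthetic-community generator (`antnet.synthdata`) produces
record/attribute datasets with the assumed structure — nested degree decay,
period-specific generalist cores, lognormal EFN totals — so the whole chain
is testable without field data. See `docs/methods.md` for the model and its
assumptions.

## Worked example

Simulate a community and analyse it (50 null draws for speed; use the
default 1000 for real analyses):

```bash
antnet simulate --seed 1 --out-dir demo
antnet analyze --records demo/records.csv --attributes demo/attributes.csv \
               --seed 1 --n-random 50 --out-prefix demo/report
```

Output (`demo/report.txt`, also written as machine-readable JSON):

```
Individual-based ant-plant network analysis
============================================
seed=1  n_random=50  objective=barber_bipartite  config=2c23207accf76590

[diurnal]
  plants=30  ants=9  richness/plant=3.27+-1.05
  H2'=0.382  NODF=61.30 (p=0.0196)  M=0.277 (p=0.4706)
  generalist core (2): ant_01, ant_02

[nocturnal]
  plants=29  ants=6  richness/plant=1.93+-0.88
  H2'=0.580  NODF=54.94 (p=0.0196)  M=0.347 (p=0.3922)
  generalist core (1): ant_03

[whole_day]
  plants=30  ants=10  richness/plant=4.10+-1.09
  H2'=0.309  NODF=67.59 (p=0.0196)  M=0.213 (p=0.8627)
  generalist core (3): ant_01, ant_02, ant_03

[day vs night]
  Jaccard similarity = 0.500
  core turnover = 1.000

[species-area]
  richness ~ EFNs: slope=-0.000438  R2=0.028  p=0.3755  n=30
  EFN one-sample t vs 0: t=6.053  p=1.378e-06
```

Reading it: all three networks are significantly **nested** (NODF p < 0.05
against Null Model II) and none is significantly **modular** (M p > 0.05);
the diurnal generalist core ({ant_01, ant_02}) is completely replaced at
night ({ant_03}) — core turnover 1.0 — even though half the species pool is
shared between periods; and plants with more EFNs do **not** host more ant
species (regression p = 0.38) although EFN counts themselves vary strongly
(t-test vs 0). Pooling day and night raises per-plant richness and lowers
H2', as expected when each period contributes its own generalists.

The same machinery is available as a library:

```python
import antnet as an
records, attrs, truth = an.generate_community(an.SyntheticConfig(seed=1))
net = an.build_network(records, "whole_day")
print(an.nodf(an.binarize(net)), an.gc_scores(net).core)
```

`antnet build` exports matrices in the plain-text `"rows cols"` + integer
rows exchange format used by the classic nestedness/modularity programs,
and `antnet report` re-renders a saved JSON report.

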