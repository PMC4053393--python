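# Methods

## Scope and data model

`antnet` analyses *individual-based* ant–plant interaction networks: bipartite
networks whose one node class is the individual plants of a single
EFN-bearing (extrafloral-nectary) plant species and whose other class is the
ant species foraging on them. The raw input is a long-format table of
interaction records — (plant individual, ant species, sampling period,
count) — plus a per-plant attribute table (height in m, estimated total EFN
count). From the records three networks are built per dataset: diurnal,
nocturnal, and whole-day (both periods pooled, counts summed). Rows of the
adjacency matrix **A** are ant species, columns are plant individuals, and
`a_ij` is the number of interaction events. Plants or ants with no
interactions in a period are simply absent from that period's network, so
the diurnal and nocturnal networks of one dataset may differ in both
dimensions. Duplicate (ant, plant, period) rows are summed rather than
rejected, since field sheets commonly repeat observations. Labels are
ordered lexicographically so every matrix, report and export is
byte-reproducible.

## Network statistics

**Nestedness (NODF).** For every pair of rows, and every pair of columns,
with *strictly* decreasing marginal fill, the paired overlap is
`100 × |shared presences| / (fill of the sparser line)`; equal-fill pairs
contribute 0, as do pairs whose sparser line is empty. NODF is the mean over
all `C(r,2) + C(c,2)` pairs, ranging from 0 (non-nested) to 100 (perfectly
nested). Because the decreasing-fill condition is applied to ordered pairs,
the statistic is invariant to row/column order; it agrees to 1e-8 with the
R `vegan::nestednodf(order = TRUE)` reference, which one test verifies
directly. Note that NODF is confounded with matrix fill: denser matrices
score higher for reasons unrelated to structure, which is why significance
is always judged against a null model conditioned on the observed fills
(below).

**Specialization (H2').** With `p_ij = a_ij / m` (m the total count),
`H2 = −Σ p_ij ln p_ij`. The maximum entropy under the observed margins is
taken as the entropy of the margin-product distribution `p_i· q_·j`, i.e.
`H2max = H(rows) + H(cols)` — the real-valued rather than
integer-constrained maximum, a deliberate dialect chosen because it is
deterministic, cheap, and always an upper bound on the observed entropy.
The minimum entropy `H2min` uses a greedy integer concentration of the
margins: repeatedly allocate `min(remaining row total, remaining column
total)` to the cell where that allocation is largest, ties broken by lowest
row then lowest column index. `H2' = (H2max − H2)/(H2max − H2min)`, clamped
to [0, 1] with a logged warning if the greedy heuristic is undershot;
degenerate margins (`H2max = H2min`) return 0. H2' is 0 for extreme
generalization (observed = margin product) and 1 for extreme specialization
(one-to-one networks). A test checks the greedy H2min against exhaustive
enumeration of all 2×2 integer matrices with fixed margins.

**Generalist core (Gc).** `Gc_i = (k_i − k_mean)/σ_k`, where `k_i` is the
*binary* degree of ant i (number of distinct plant individuals visited).
Binary degree is used because a per-species scalar "mean number of links"
is only well defined as the partner count. σ_k defaults to the sample
(n−1) standard deviation, with a population-SD switch; the classification
(Gc strictly > 1 → generalist core, otherwise peripheral) is insensitive to
the choice on all cases we exercise, and `Gc = 1` exactly is peripheral.
All degrees equal (σ_k = 0) is reported as a degenerate-degree error — no
core is distinguishable.

**Core turnover and composition similarity.** Jaccard similarity
`|A∩B| / |A∪B|` compares the full day and night ant assemblages; core
turnover `1 − |core_day ∩ core_night| / |core_day ∪ core_night|` compares
only the generalist cores (1.0 = complete replacement, the "night-shift"
pattern). Both are symmetric; both are undefined (an error, not 0) when
both inputs are empty.

**Modularity (M/Q).** The default objective is Barber's bipartite
modularity `Q = (1/m) Σ_ij [a_ij − k_i d_j/m] δ(g_i, g_j)` on the binarized
matrix; a unipartite Newman projection is available for sensitivity
analysis only. Both objectives are reduced to a symmetric node-pair benefit
matrix W plus a constant, so `Q = Σ_{same-module pairs} W + offset`; moves,
merges and splits then have exact O(1)–O(n) deltas. Optimization is
simulated annealing: singleton start, initial temperature scaled to twice
the standard deviation of sampled initial move deltas (fallback 0.05),
geometric cooling (factor 0.95 down to 1e-3 of T0), and per temperature
step `c·n²` single-node reassignments plus `c·n` merge/split proposals
(default c = 1) under Metropolis acceptance. A deterministic
best-improvement descent polishes the best state found, the all-in-one
baseline (Q = 0 exactly) is always evaluated so results are never negative,
and everything is deterministic given the seed. Reported values use
best-of-5 restarts by default. An exhaustive oracle enumerates all set
partitions for instances of ≤ 10 nodes; best-of-5 annealing matches it on
100 random instances in the acceptance suite.

## Null Model II (CE) and significance

Each cell (i, j) is occupied independently with probability
`(P_i + P_j)/2`, where `P_i = k_i / n_cols` and `P_j = d_j / n_rows` are
the row and column fill proportions. The expected fill of a draw equals the
observed fill exactly (`Σ_ij (P_i + P_j)/2 = F`, an algebraic identity the
tests verify both symbolically-by-summation and by Monte Carlo). Rows or
columns that come out empty are *kept*: discarding them would bias the
ensemble toward higher fill, and empty lines contribute 0 to NODF by the
metric's own rule. Significance is the upper-tail empirical p with the
add-one (Davison–Hinkley) correction, `p = (1 + #{null ≥ obs})/(n + 1)`, so
p is never exactly 0; `z = (obs − mean)/sd` is reported alongside. Null
draws on which a metric is undefined are scored 0 and logged. Calibration:
on data drawn *from* the null itself the NODF test rejects at close to the
nominal 5% (slightly conservatively, as expected when the null margins are
re-estimated from each observation); the acceptance suite checks the
rejection count over 200 replicates against a ±3-SD binomial band.

## Species–area analysis

Total EFNs per plant are estimated from branch samples: mean of (typically
three) branch counts × total branch count, or, for plants with many small
per-leaf nectaries, mean per-leaf count × leaves per branch × total
branches. The species–area hypothesis is an OLS regression of per-plant ant
richness (binary degree, by default from the whole-day network; the period
is configurable) on estimated EFN totals, reporting slope, R², and the
two-sided t-test for slope = 0. A constant response returns slope 0,
R² = 0, p = 1 rather than NaN. The companion one-sample t-test requires an
explicit reference value (default 0 in the pipeline): testing a sample
against its own mean is vacuous (t ≡ 0), so the reference must be supplied
deliberately.

## Synthetic community generator

Because interaction matrices of this kind are rarely deposited, the
generator produces communities with the structure the analysis assumes, at
the scale of the savanna study systems it emulates. Defaults: 30 plant
individuals (study range 24–41), a 13-species ant pool (per-network
richness then lands around 8–13), a 2-species diurnal core and 1-species
nocturnal core with zero overlap, activity mix (0.1 diurnal-only, 0.1
nocturnal-only, 0.8 both), lognormal EFN totals (log-mean 5.9, log-SD 0.77 ≈
mean 500, SD 450) and heights (log-mean 0.78, log-SD 0.33 ≈ 2.3 ± 0.8 m).

Presence of ant i on plant j in a period is Bernoulli with
`p_ij = logistic(α_i + β_j + efn_effect·(ln EFN_j − efn_log_mean))`. The
period's designated core species get α = 2.0 (presence ≈ 0.88); the other
active species decay from α = −0.5 at `nestedness_strength` (default 0.5)
per rank, giving the graded, nested degree distribution. Plant effects β_j
are N(0, 0.25). Counts given presence are zero-truncated Poisson(2).
Core species are always active in both periods (so they appear, but as
peripherals, at the "wrong" time — which is what makes complete core
turnover compatible with high day/night Jaccard similarity);
`efn_effect = 0` (the default) reproduces the no-species-area-effect
condition. Plants empty in both periods are redrawn with bounded retries so
the pooled network keeps all n_plants individuals; ant species may drop out
naturally, which is how per-network richness varies.

What the generator does **not** emulate: spatial structure and plant
neighborhood effects, behavioural interference between ant species
(presences are independent given the intercepts), within-period temporal
autocorrelation, and detection failure of rare species beyond simple
Bernoulli thinning. Passing recovery tests therefore show the *analysis
chain* behaves correctly under the assumed generating structure, not that
real communities follow that structure.

One property deserves a note: median *raw* NODF is not monotone in
`nestedness_strength`, because a steeper decay also lowers matrix fill and
NODF rises with fill — a well-known property of the metric. The
fill-controlled readout, the null-model z-score of NODF, is monotone over
the tested strength grid, and that is what the monotonicity property test
asserts.

## Problem sizes and numerical choices

The test and acceptance suites scale the simulations to what the method
needs rather than to the field scale: oracle equivalence uses 100 random
instances of 4–10 nodes (exhaustive enumeration beyond 10 nodes is
intractable — Bell(10) = 115,975 partitions); calibration and recovery use
200 and 100 replicate communities with 199-draw null ensembles; pipeline
examples use 50-draw ensembles. For real analyses the CLI default is the
conventional 1000 randomizations. Ties in the H2min greedy break by
row-then-column index; annealing improvement tolerance is 1e-12; the final
reported Q is re-evaluated from the partition, not from incremental deltas.
Degenerate inputs are errors, not silent zeros, except where the descriptor
battery catches the equal-degree case (core_size 0, logged) so that a
report can still be assembled.

## Known limitations

- The annealer is tuned for the ≤ 50-node networks this problem produces;
  very large networks would need a cheaper proposal mix.
- H2max uses the real-valued margin-product bound, so H2' here is a
  dialect: values are comparable within this package, and the integer-
  constrained variant would shift the scale slightly.
- The modularity significance test is expensive (each null draw runs the
  annealer); use a reduced `n_random` for exploration and the full 1000
  for final numbers.
- Empirical p-values are bounded below by 1/(n_random + 1).
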