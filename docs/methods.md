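# Methods

## Problem

Case-control genome-wide association data consist of `L` individuals typed
at `N` biallelic SNPs, coded by minor-allele count (0/1/2), with a binary
phenotype. A *two-locus disease model* is a pair of SNPs whose joint
genotype distribution differs between cases and controls — interactions
(epistasis) that single-marker scans miss. Scanning all `C(N,2)` pairs is
quadratic in `N`; the package screens this space with a guided stochastic
search and then subjects the shortlist to a formal test.

## Screening stage

Every candidate pair is summarized by its 9×2 contingency table: rows index
the joint genotype combination (`3·g_first + g_second`, lower-index SNP
first), columns the phenotype. Two fitness functions grade the table:

* **K2 score** — the Bayesian-network marginal likelihood of "genotype
  combination → phenotype",
  `K2 = ∏_i [(J−1)!/(n_i+J−1)!] ∏_j n_ij!`. The raw product underflows for
  realistic `L`, so it is held as `−ln K2 = Σ_i [lnΓ(n_i+J) − lnΓ(J) −
  Σ_j lnΓ(n_ij+1)]`, computed with `scipy.special.gammaln`. Smaller is
  better.
* **Gini score** — the weighted impurity
  `Σ_i (n_i/L)(1 − Σ_j (n_ij/n_i)²)`; 0 for a perfectly separating
  partition, 0.5 at maximal impurity for two classes. Smaller is better.

Both orientations are fixed by the single constant
`scoring.LOWER_IS_BETTER`; empty genotype rows contribute 0 to both scores
by continuity. The two criteria are complementary (they rank different
model families differently), so the search keeps **two harmony memories**:
HM1 ordered by K2, HM2 by Gini; the candidate set handed to the testing
stage is their union.

### Harmony search

Each iteration *improvises* a pair, one locus dimension at a time: with
probability HMCR (default 0.9) the dimension is copied from a uniformly
chosen harmony in HM1 ∪ HM2, then with probability PAR (default 0.35) it is
pitch-adjusted by `(rand − 0.5)·|best_dim − random_harmony_dim|` of the
source memory; otherwise it is uniform over `1..N`. The continuous result is
rounded to the nearest integer, clamped to `[1, N]`, repaired on duplicate
loci by redrawing the second, and canonicalized ascending. A scored
candidate replaces the worst entry of each memory whose criterion it
strictly improves (strictness avoids churn on ties).

### Tabu registry

A registry over all `C(N,2)` pairs guarantees **no pair is ever scored
twice**. Pairs map to linear indices `1..C(N,2)` by the row-major
triangular rule `k = N(i−1) − i(i−1)/2 + (j−i)` (a bijection; the inverse
solves the quadratic and corrects by ±1). Unvisited indices form a
circular doubly linked list held as two integer arrays (O(C(N,2)) memory,
O(1) unlinking). When an improvised pair was already visited, a *local
search* walks `BW = ⌊min(10, max(u·#E, 1))⌋` hops (`u ~ U(0,1)`, `#E` the
unvisited count) from its position along the live list, in a fair-coin
direction, wrapping at the ends; a walk entering at a visited index first
follows the stale successor pointers (with path compression) to the live
list. The step size shrinks toward 1 as the table empties.

Memory initialization also draws through the registry, and every initial
model is offered to *both* memories: since a pair can never be re-evaluated,
a model seen only while filling HM1 must still be able to enter HM2 for the
budget-equals-`C(N,2)` run to be exhaustive under both criteria. That
guarantee — at full budget the best entry of each memory equals the
corresponding global optimum — is asserted by test and recomputed by the
acceptance script.

Model evaluations (MEs) count scored pairs; both scores of one pair are one
evaluation. The run stops at the budget MMEs (default 4500 for 100-SNP
data), on registry exhaustion, or — as an opt-in benchmark-harness mode
used for evaluation-count statistics against a known truth — as soon as the
known causal pair enters a memory.

## Testing stage

Shortlisted pairs get a likelihood-ratio goodness-of-fit test
`G = 2 Σ_ij O_ij ln(O_ij/E_ij)` against expected counts from the
independence model `E_ij = n_i·n_·j/L` (a Hardy-Weinberg-margin variant is
available behind `expected_mode="hwe"`; independence is the default because
HWE expecteds for a joint two-locus table are underdetermined). Two
small-sample modifications: zero-observed cells contribute 0, and the
degrees of freedom (base `(I−1)(J−1) = 8`) drop by one for every genotype
row whose total is below ε (default 5, the classic small-count rule of
thumb; configurable). If df reaches 0 the table is untestable and p = 1.
P-values are continuous chi-square upper tails, no continuity correction.
Significance uses the Bonferroni level `α = α0/C(N,2)` (α0 default 0.01).

A single-locus version of the same test (3×2 table, base df 2, same ε
rule) drives the prefilter for dense real datasets. Its threshold
convention is *keep* loci with p below the cutoff — under a mostly-null
genome this retains roughly the cutoff fraction of loci, which is the
arithmetic that makes sense of reported prefilter sizes; the literal
remove-if-small alternative is available behind `keep_small_p=False`.

## Simulator

A `PenetranceModel` is a pair of MAFs plus a 3×3 table `f(g_a, g_b)` of
disease probabilities. Derived descriptors: prevalence
`K = Σ P(g_a)P(g_b) f(a,b)` under Hardy-Weinberg proportions, and
broad-sense heritability `H² = Var(f)/(K(1−K))` with the
genotype-frequency-weighted variance — the standard difficulty grade for
simulated epistasis models; the detector never sees either.

Datasets are drawn **retrospectively** (fixed case/control counts, the
benchmark design): causal genotype pairs from `P(g|case) ∝ P(g_a)P(g_b)f`
and `P(g|control) ∝ P(g_a)P(g_b)(1−f)`; background SNPs as independent
HWE draws with MAFs uniform in `[0.05, 0.5]` (the background distribution
is a package choice; benchmark generators do not pin it down). The causal
pair is placed by a pure column permutation of a canonical layout, so
un-permuting recovers the canonical dataset exactly. A prospective mode
(sample genotypes, then Bernoulli(f) phenotype) exists solely to verify the
sampler against the analytic prevalence. Linkage disequilibrium, missing
genotypes, covariates and quantitative traits are out of scope.

Three parameterized families mirror the standard benchmark classes:
multiplicative (`f = base·(1+θ)^(g_a+g_b)`), threshold (risk jumps once the
total disease-allele count reaches a cutoff) — both with marginal effects —
and an XOR-like pure interaction (risk depends on the parity of
`g_a + g_b`), which has no marginal effect at MAF 0.5 and only a weak one
elsewhere. Defaults: the pure-interaction family at MAF 0.4 with
penetrances 0.02/0.6 gives H² ≈ 0.39 (a strong signal); the threshold
family at MAF 0.4 with 0.05/0.3 gives H² ≈ 0.11.

## Evaluation harness

`run_power_experiment` simulates `#T` datasets (seeds derived from one
master seed and recorded per replicate), runs both stages on each, and
aggregates: screening power = fraction of datasets whose true pair entered
HM1 ∪ HM2; testing power = fraction whose true pair also passed the
G-test; TP/FN/FP/TN counted per screened candidate against the known truth
(so TPR/SPC/PPV/ACC measure the *testing* stage's precision on the
shortlist, and `power_test ≤ power_screen` always); and mean MEs.

### What the search can and cannot do

Screening power decomposes into coverage (was the causal pair evaluated at
all?) and certainty of entry (a strong pair always enters memory once
scored). For models **with** marginal effects, pairs containing one causal
locus score above average, the memories accumulate them, and recombination
finds the causal pair after a few hundred evaluations — the threshold-model
benchmark at `N = 100` saturates at 100% screening power with mean MEs
≈ 470 of the exhaustive 4950. For **pure** interactions there is no
marginal trail: causal-containing pairs rank near average under both
criteria, improvisation steers almost nothing, and screening power at
budget MMEs is capped near `MMEs/C(N,2)` (≈ 91% at 4500/4950) plus weak
Gini steering — measured 85–95% across master seeds at 20 replicates.
This is an intrinsic property of marginal-blind screening, not an
implementation artifact; the budget-equals-`C(N,2)` setting removes the cap
at the price of exhaustiveness.

## Problem sizes used by tests and the acceptance script

Unit and property tests run at `N ≤ 50` with hundreds of individuals;
score oracles use 1000 random 9×2 tables against exact big-integer
arithmetic (1e−9 relative for K2, 1e−12 absolute for Gini). The oracle
equivalence check runs `N ∈ {10, 20, 30}` × 10 seeds at full budget; the
power runs use 20 replicates of 400+400 × 100 SNPs at MMEs 4500. These
sizes make the whole suite run in well under a minute while exercising
every code path at the benchmark's per-dataset scale.

## Known limitations

* Pair order `k = 2` only; the linearization and registry generalize but
  memory grows as `C(N,k)`.
* The registry costs O(C(N,2)) memory (two int64 link arrays + a flag);
  at `N = 10^5` that is ≈ 80 GB — the design targets post-prefilter sizes
  (tens of thousands of loci would need the int32/bit-packed variant).
* Retrospective sampling assumes a single causal pair per dataset.
* The balance between type I errors (models with strong marginal effects
  dragging passenger loci through the test) and type II errors (weak-signal
  models failing the Bonferroni threshold) is inherited from the two-stage
  design; the harness's PPV column makes the first effect visible.
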