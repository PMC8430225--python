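# Methods

This note documents the models, parameter choices and numerical decisions
behind `lncnet`, and what the synthetic-data tests do and do not establish
about real cohorts.

## ceRNA pair calling

**Model.** A lncRNA and a TF mRNA are candidate competing endogenous RNAs
when their miRNA target sets overlap more than chance predicts and their
expression is positively correlated. With `m` miRNAs in the study universe,
`n` targeting the lncRNA, `t` targeting the TF and `r` targeting both, the
overlap p-value is the hypergeometric upper tail `P(X ≥ r)`. The
implementation sums the upper tail directly in log space (log-gamma
binomial coefficients + log-sum-exp), which is numerically identical to the
`1 − Σ_{i<r}` form but keeps small tails accurate and supports miRNA
universes of 10⁵+ without overflow. Terms with `n − i > m − t` are
impossible draws and contribute zero. Whether the draw size is taken as `n`
or `t` is irrelevant — the hypergeometric tail is symmetric in the two
marginals — so only one convention is implemented.

**Thresholds.** Significance requires all three of: hypergeometric
`p < hyper_p_cutoff` (default 0.05 — the conventional level; exposed in
`RunConfig` because the analysis convention does not pin it),
`PCC > 0.6` *signed* (a strongly anti-correlated pair is not a ceRNA pair
under this model), and correlation `p < 0.01` from the exact t-transform
`t = r·√((n−2)/(1−r²))` on `n − 2` degrees of freedom. No multiple-testing
correction enters the call, mirroring the fixed-threshold convention; a
Benjamini–Hochberg q over the hypergeometric p-values is emitted as an
informational column only (the hypergeometric test is the pair-calling
test; the correlation acts as a filter).

**Filtering.** Genes whose fraction of zero expression values strictly
exceeds 0.7 are removed before pairing ("more than 70 %" is a strict
inequality: a gene with exactly 70 % zeros stays). Constant-expression
genes are skipped with a logged reason — their correlation is undefined.

## Network topology

The lncRNA–TF network merges significant ceRNA pairs with TF–TF PPI edges
into one simple undirected graph; a parallel ceRNA + PPI edge between the
same endpoints collapses into one edge carrying both labels. Isolated
nodes never occur (the node set is the union of edge endpoints).

- **Power-law fit.** `P(k)` over distinct degrees `k ≥ 1` (unbinned), OLS
  of `log10 P(k)` on `log10 k`; `alpha` is the negated slope, `r2` the
  coefficient of determination. Unbinned distinct-degree OLS matches the
  R²-style readout this analysis style reports; logarithmic binning is
  available (`binned=True`) and a discrete maximum-likelihood exponent is
  provided as a secondary diagnostic, but the headline numbers come from
  the unbinned fit.
- **Clustering coefficient.** Mean local clustering with degree-< 2 nodes
  counted as 0. The alternative convention (excluding them) changes the
  value, so the choice is fixed and stated.
- **Average shortest path.** Computed on the largest connected component
  (a disconnected graph has no finite all-pairs mean); the component
  choice is logged.
- **Permutation nulls.** Default scheme `gnm`: uniform random simple
  graphs with the observed node and edge counts. Rationale: degree-
  preserving rewiring partially preserves clustering and would weaken the
  clustering-coefficient contrast; both schemes are provided and the
  rewiring scheme (double-edge swaps, 10·|E| accepted swaps) asserts
  degree-sequence preservation on every draw. The empirical p-value is the
  add-one estimator `(#{null ≥ obs} + 1)/(n_perm + 1)` (mirrored for the
  "less" alternative), bounded below by `1/(n_perm + 1)`.
- **Hubs.** `k = ceil(0.10 · |V|)` highest-degree nodes; ties at the
  cutoff break by node id for determinism. On a 524-node network this
  yields exactly 53 hubs.

## MCODE module detection

Re-implemented from the published molecular-complex-detection procedure,
with the plug-in's documented defaults (degree cutoff 2, node score cutoff
0.2, k-core 2, haircut on, fluff off):

1. vertex weight = `k · density` of the highest k-core of the closed
   neighbourhood `N[v]` (0 when that core has < 2 nodes);
2. complexes grow breadth-first from the highest-weight unassigned vertex,
   admitting neighbours with weight ≥ `(1 − 0.2) ·` seed weight, each
   vertex joining at most one complex;
3. complexes without a 2-core are dropped; haircut trims each complex to
   its 2-core (if trimming disconnects the complex, the seed's component
   is kept); optional fluff adds boundary vertices whose closed-
   neighbourhood density exceeds a cutoff.

The degree cutoff applies at the seeding stage (low-degree vertices cannot
seed a complex) rather than inside the vertex weight, so the weight of a
leaf in a star is 1, as the core-clustering definition gives. Module score
is `density × size`; ties in seed order and output order break by node id,
making results independent of input insertion order.

## Motif scanning and feedback loops

**Regions.** Promoters are `[TSS − 2000, TSS + 2000)` (0-based half-open,
clipped at zero). Enhancers are assigned to every lncRNA whose TSS is more
than 2,000 bp and at most `enhancer_max_dist` from the enhancer's nearest
edge. The upper bound is not part of the original definition ("more than
±2,000 bp" has no stated maximum); the default of 100 kb is this package's
documented choice, configurable.

**PWM model.** Count matrices get a pseudocount of 0.1 per cell (the
standard scanner default) before normalising; scores are bits,
`log2(freq/background)`. Ambiguous bases (N) score 0 bits.

**Exact p-values.** The p-value of a window score is the probability that
an i.i.d. background word of the motif width scores at least as high. It
is computed by dynamic programming over per-column score distributions,
merging bitwise-equal partial sums — exact for widths ≤ 12 (the widths
this pipeline uses), because the discrete score distribution has atoms of
mass ≥ (min background)^width, far larger than any useful approximation
tolerance. For wider motifs a lattice DP (columns floor-rounded at a
granularity of 1/1000 of the score range) takes over; floor-rounding plus
a lookup slack of `width × granularity` makes the lattice p-value a
guaranteed upper bound on the exact one. Both strands are scanned (the
minus strand scores the reverse-complemented matrix); hit offsets are
plus-strand leftmost coordinates.

**Loops.** A positive feedback loop is a pair that is simultaneously a
significant ceRNA pair and supported by ≥ 1 motif hit (`p < 1e−4`) of that
TF in a promoter or enhancer owned by the lncRNA. The per-role hit counts
are reported for the motif-count readout.

## Survival analysis

Univariate Cox fits maximise the Breslow partial likelihood by
Newton–Raphson from β = 0 (score tolerance 1e−8, ≤ 50 iterations, step
halving so the likelihood never decreases); ties use the Breslow
approximation throughout (Efron is out of scope). The standard error comes
from the observed information, the p-value from a two-sided Wald z. A
|β| > 50 iterate is flagged non-converged (monotone likelihood); note that
fully separated data can also stall earlier with a numerically zero score,
in which case the reported β is the saturation point of the likelihood.

`RiskScore = Σ_i r_i · Exp(i)` with `r_i` the per-gene Cox coefficients;
patients split at the *mean* score, with the boundary rule value = mean →
"low" fixed for determinism. The two groups are compared by the log-rank
statistic `(O1 − E1)²/V` with the hypergeometric variance summed over
distinct event times (p from χ² on 1 df) and the Mantel–Cox hazard ratio
`(O1/E1)/(O2/E2)` (group "high" in the numerator); a Cox-on-indicator HR
is emitted alongside. A group with zero events leaves the HR not
estimable (NaN) while the χ² is still reported. Samples with missing
time/event are dropped with a logged count.

## m6A and immune modules

The lncRNA–m6A network keeps pairs with `|PCC| > 0.6` by default
(absolute mode): the analysis convention states the signed form in one
place and the absolute form in another, and the absolute form subsumes
the signed one; signed mode is available. The network is strictly
bipartite. Key genes have degree strictly greater than 2. Immune
correlations default to Pearson for consistency with the rest of the
pipeline (Spearman available, since the estimator is not pinned by
convention), with a BH q over the full lncRNA × cell-type grid — the raw p
is always reported too. Constant profiles yield flagged rows rather than
errors.

## Synthetic data: what it emulates, and what it does not

Each generator plants exactly the structure one stage detects, with the
planted truth returned alongside:

- **Interactions** (default universe 386 miRNAs, 200 lncRNAs, 50 TFs,
  background target rate 0.02): planted pairs share a dedicated block of
  10 miRNAs on top of i.i.d. background, so unplanted pairs share
  `Binomial(m, rate²)` miRNAs in expectation.
- **Expression** (default 300 samples, unit scale): planted pairs are
  built from a shared standard-normal latent factor
  (`x = √ρ·z + √(1−ρ)·ε`), so the population correlation is exactly ρ
  (default 0.75). Expression is Gaussian on a log-like scale; no
  non-negativity is imposed because the downstream statistics (PCC, Cox)
  do not require it, and the cohort matrix is treated as already
  log-scaled.
- **Survival**: exponential event times with hazard
  `0.1 · exp(Σ β·Exp)` (planted β = 0.5) and exponential censoring at
  rate 0.05 (≈ one third of subjects censored).
- **Module graph**: ER(100, 0.03) background plus vertex-disjoint planted
  cliques (K5, K6), each tied in by a single bridge edge.
- **Sequences**: i.i.d. background bases with PWM-sampled sites planted
  at recorded offsets and strands (reverse-complemented on '−').

One global seed feeds a named substream per generator, so adding a
generator never changes another's output, and every CLI stage is a pure
function of (inputs, config, seed) — reruns are byte-identical.

These fixtures deliberately do **not** model library-size effects, batch
structure, count-distribution marginals, linkage between miRNA families,
motif clustering or covariate-dependent censoring. Passing tests therefore
establish the correctness and calibration of the algorithms — not that any
particular biological cohort satisfies the model assumptions.

## Problem sizes used in tests and the acceptance script

Oracle checks enumerate all hypergeometric configurations with `m ≤ 25`
(~44,000 cases) and all `4^w` words for 100 random PWMs of width ≤ 6.
Recovery and calibration checks use 50 planted-clique fixtures, a
200 × 50-gene ceRNA universe at 300 samples, 200 Cox replicates at
n = 1000, 5,000 log-rank null replicates at n = 200, and 1,000-draw
permutation tests on 500-node graphs — sizes at which the binomial /
Monte-Carlo error of each check is far below its acceptance margin.

## Known limitations

- Only univariate Cox models; no multivariate fits, time-dependent
  covariates or proportional-hazards diagnostics.
- The log-rank χ² uses the large-sample approximation; exact or permuted
  variants are not provided.
- MCODE complexes depend on local density; sparse-boundary modules are
  invisible to the weighting by construction.
- The PWM null model is a zero-order background; dinucleotide backgrounds
  and motif q-values across scans are not implemented.
- WGCNA-style alternative co-expression networks and miRNA-target
  prediction itself are out of scope: interaction lists are inputs.
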