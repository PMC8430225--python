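# lncnet

Network analysis of long non-coding RNA (lncRNA) regulation in tumour
expression cohorts, built around the competing-endogenous-RNA (ceRNA)
hypothesis: lncRNAs and transcription-factor (TF) mRNAs that share miRNA
partners buffer each other's repression, so their expression is coupled.
`lncnet` turns that idea into a tested pipeline:

1. **ceRNA pair inference** — for each lncRNA–TF pair with `m` miRNAs in the
   study, `n` targeting the lncRNA, `t` targeting the TF and `r` targeting
   both, the shared-target enrichment p-value is the hypergeometric upper
   tail

   `p = 1 − Σ_{i=0}^{r−1} C(t, i)·C(m−t, n−i) / C(m, n) = P(X ≥ r)`,

   combined with Pearson co-expression: a pair is significant when
   `p_hyper < 0.05`, `PCC > 0.6` and `p_PCC < 0.01`.
2. **Network topology** — the graph merging significant ceRNA pairs with
   TF–TF protein-interaction edges is profiled by its degree-distribution
   power-law fit (log–log OLS, α and R²), mean clustering coefficient and
   average shortest path length, each contrasted with 1,000 permutation
   networks (matched-size random graphs or degree-preserving rewirings).
   Hubs are the top 10 % of nodes by degree (ceiling rule).
3. **Module detection** — a from-scratch MCODE implementation (vertex
   weighting by the density of the highest k-core of each closed
   neighbourhood, seeded greedy expansion, 2-core haircut) locates dense
   lncRNA–TF modules.
4. **Feedback loops** — lncRNA promoters (TSS ± 2,000 bp) and assigned
   enhancers are scanned with TF position-weight matrices; window p-values
   are exact (dynamic programming over the null score distribution), hits
   require `p < 1e−4`, and a TF–lncRNA pair that is both a significant ceRNA
   pair and motif-bound is reported as a positive feedback loop.
5. **Survival** — per-gene univariate Cox coefficients `r_i` define
   `RiskScore = Σ_i r_i · Exp(i)`; patients split at the mean score are
   compared by Kaplan–Meier curves, the log-rank test and the Mantel–Cox
   hazard ratio.
6. **m6A and immune readouts** — lncRNA–m6A-regulator co-expression network
   (|PCC| > 0.6), key genes by degree, and lncRNA × immune-infiltration
   correlation tables with BH correction.

Because the original cohort inputs (expression, interaction snapshots,
annotations) are external resources, the package ships a synthetic-data
module that generates every input with planted, machine-readable ground
truth — planted shared-miRNA overlaps, exact planted correlations, planted
hazards, planted cliques and planted motif sites — so every stage is
testable end to end.

## Worked example

```python
import numpy as np
import lncnet as L
from lncnet import simulate as sim

lncs = [f"LNC{i+1:03d}" for i in range(40)]
tfs = [f"TF{i+1:03d}" for i in range(15)]
planted = [("LNC001", "TF001"), ("LNC002", "TF002"), ("LNC003", "TF003")]
iset, _ = sim.simulate_interactions(n_mirna=386, n_lnc=40, n_tf=15,
                                    planted=planted, seed=1)
expr, _ = sim.simulate_expression(lncs + tfs, [(l, t, 0.75) for l, t in planted],
                                  n_samples=300, seed=2)
pairs = L.call_cerna_pairs(iset, expr)
print(pairs.head(4).to_string(index=False))
```

```
lnc_id tf_id  r_shared      hyper_p       pcc        pcc_p         bh_q  significant
LNC001 TF001        10 3.263526e-12  0.744061 3.950585e-54 1.958116e-09         True
LNC003 TF003        10 4.121762e-11  0.772805 8.498775e-61 1.236529e-08         True
LNC002 TF002        10 1.680742e-10  0.750954 1.206235e-55 3.361484e-08         True
LNC016 TF014         3 2.378416e-03 -0.005356 9.264004e-01 3.567624e-01        False
```

The three planted pairs (10 dedicated shared miRNAs, population correlation
0.75) head the table and are the only significant calls; the fourth row
shows a chance 3-miRNA overlap rejected by the correlation filter. The
survival stage on the same cohort, with a hazard planted on two TFs:

```python
clinical, _ = sim.simulate_survival(expr, {"TF001": 0.5, "TF002": 0.5}, seed=3)
model, cox = L.RiskModel.from_univariate_cox(expr, clinical, ["TF001", "TF002"])
labels = L.stratify_by_mean(L.risk_score(expr, model))
cmp_ = L.km_logrank(labels, clinical["time"].values, clinical["event"].values)
print(f"log-rank chi2 = {cmp_.chi2:.2f}, p = {cmp_.p:.3g}, HR = {cmp_.hr:.2f}")
```

```
log-rank chi2 = 42.05, p = 8.89e-11, HR (Mantel-Cox) = 2.48
```

High-risk patients (risk score above the mean) die about 2.5× faster, as
planted.

## Command line

Every stage is also a `lncnet` subcommand (`simulate`, `filter`, `cerna`,
`network`, `topology`, `mcode`, `scan`, `feedback`, `survival`, `m6a`,
`immune`); all stochastic stages take `--seed` and reruns are
byte-identical:

```sh
lncnet simulate --outdir fixtures --seed 7
lncnet cerna --interactions fixtures/interactions.tsv \
             --expr fixtures/expression.tsv --out pairs.tsv
lncnet network --pairs pairs.tsv --out net.graphml
lncnet topology --network net.graphml --out-report topology.json --seed 7
```

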