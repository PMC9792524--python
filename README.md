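# noapipe

Statistical toolkit for recessive-variant discovery in non-obstructive
azoospermia (NOA) cohorts — the severest form of male infertility, where
spermatogenesis fails and causal genes are scattered across hundreds of
loci, most seen in a single patient each.

The package is aimed at statistical geneticists designing or analyzing
rare-disease exome studies with extreme locus heterogeneity. It provides,
as a tested library with a thin CLI:

* the **prioritization cascade** for recessive candidate genotypes
  (PSAP-style genotype p-values, popmax allele frequency, genotype
  recurrence and compound-het phase rules, inheritance-mode-aware
  aggregation by gene annotation, case/control gene subtraction), with a
  complete per-finding audit trail;
* **gene-pool size estimation**: with `n` gene hits drawn uniformly from a
  pool of `p` genes, the recurrence rate
  `r = (# genes hit >= 2x) / (# distinct genes hit)` has closed form
  `r = (1 - P0 - P1) / (1 - P0)` with `P0 = (1-1/p)^n`,
  `P1 = (n/p)(1-1/p)^(n-1)`, and is strictly decreasing in `p` — so the
  observed recurrence identifies the pool size by Monte Carlo grid search;
  plus false-discovery brackets and cohort-size projections;
* exact **carrier-burden tests** (Fisher 2x2, two-stage Bonferroni
  threshold `alpha / 20000 = 2.5e-6`, exact binomial comparisons);
* **molecular-subform statistics** over single-cell expression components:
  tissue-specificity classification (5-fold enriched/group/enhanced
  rules), top-loading gene sets, count profiles, Pearson–Filon Z for
  dependent correlations, hypergeometric component enrichment;
* **piRNA maturity** statistics (spike-in normalization, mature fraction
  below 32 nt, exact case/control comparison);
* **consanguinity** from runs of homozygosity: five-component Gaussian
  mixture on log segment length, FROH from the longest class with
  hemizygous-region exclusion, threshold labelling;
* a **synthetic-data module** that generates every input with planted
  ground truth (cohorts, findings, ROH segments, loadings, piRNA
  histograms, tissue matrices), so the whole pipeline is testable without
  any patient data.

See `docs/methods.md` for the models, assumptions, numerical choices and
limitations.

## Worked example

```python
import numpy as np
from noapipe import architecture, burden

# Detection-rate contrast: 55/72 consanguineous vs 127/852 outbred cases
table = burden.ContingencyTable(a=55, b=17, c=127, d=725)
p = burden.fisher_exact(table, "two_sided")
print(f"consanguineous vs outbred detection: OR={table.odds_ratio():.1f}, P={p:.2e}")

# Pool size from recurrence: 9.4% of 123 non-consanguineous gene hits recur
est = architecture.estimate_pool_size(r_obs=0.094, n_draws=123, reps=1000, seed=0)
print(f"estimated monogenic gene pool: {est.p_hat} genes (grid 1..1000)")

# How many cases until half the pool is seen in >= 2 patients?
for d in (0.15, 0.76):
    proj = architecture.project_cohort_size(625, d, coverage_target=0.5,
                                            recurrence_k=2, reps=1000, seed=0)
    print(f"cases needed at discovery rate {d:.0%}: {proj.n_required}")
```

Output:

```
consanguineous vs outbred detection: OR=18.5, P=8.31e-28
estimated monogenic gene pool: 630 genes (grid 1..1000)
cases needed at discovery rate 15%: 6991
cases needed at discovery rate 76%: 1379
```

Reading: consanguineous men are ~18x more likely to receive a genetic
diagnosis, the recurrence pattern implies a pool of roughly 600-650
monogenic azoospermia genes, and seeing half of that pool recurrently
takes ~7000 outbred cases — but only ~1400 consanguineous ones, whose
higher discovery rate makes them far more informative per sample.

An end-to-end synthetic run (simulate → prioritize → burden →
architecture → piRNA → FROH, with a checksummed manifest):

```sh
noapipe run-all --seed 1 --out run1
cat run1/summary.json
```

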