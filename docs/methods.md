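# Methods

`noapipe` re-implements, as a tested library, the statistical machinery of a
whole-exome study design for non-obstructive azoospermia (NOA): recessive
variant prioritization in unrelated cases, estimation of the size of the
monogenic gene pool from recurrence, exact carrier-burden testing,
expression-component ("molecular subform") profiling, piRNA maturity
statistics, and consanguinity classification from runs of homozygosity.
Everything runs on synthetic cohorts with planted truth; no patient data is
used or required.

## Genetic model and prioritization cascade

The disease model is monogenic-recessive with extreme locus heterogeneity:
each affected man carries at most one causal genotype, drawn from a large
pool of genes in which biallelic (or hemizygous) disruption abolishes
spermatogenesis. Candidate genotypes arrive annotated with a
population-sampling-probability (PSAP-style) p-value — how unusual the
genotype is given population variation — a popmax allele frequency, a
consequence class, and, for compound-heterozygous pairs, phase and
intra-pair distance.

Stage 1 removes findings on variant-level evidence. Defaults: genotype
p <= 1e-3; popmax MAF <= 0.01; identical homozygous/hemizygous genotypes in
more than 3 individuals; identical compound-het pairs in more than 1 case;
pairs in cis; optionally pairs closer than 10 bp (a replication-cohort
matching rule, off by default); and genes in which more than 3 distinct
individuals carry at least two distinct ultra-rare qualifying variants
(p < 1e-4, MAF < 0.01) — a platform-artifact guard. The enrichment rule
needs a convention the source procedure does not fully specify; we require
distinct variants so it stays disjoint from the identical-genotype rule.

Every rule is evaluated as a predicate on the input table. Consequences:
the surviving set is independent of rule order (the audit trail attributes
each dropped finding to the first matching rule in a documented order);
filtering is idempotent; and the audit partitions the input exactly.
Compound-het findings without phase evidence are retained as
phase-unknown — only demonstrated cis pairs are removed.

Stage 2 aggregates by inheritance mode and gene annotation. Autosomal
findings must be LoF, in a known-infertility gene (human or mouse
evidence), or in a gene with elevated testis expression; X-linked findings
need elevated testis expression *and* LoF-or-known-infertility; Y-linked
findings need LoF only. Kept findings in genes without elevated testis
expression additionally require premeiotic single-cell expression above
0.5 normalized TPM. Y-linked findings are exempt from that backstop: the
Y criterion is LoF alone, and unclassified Y genes would otherwise be
un-discoverable. Finally, genes with surviving findings in both the case
and control cohorts are subtracted from both (conservative against
platform artifacts); the two output gene sets are disjoint by construction.

A caveat the tests make explicit: the recurrence-based rules bound the
regime in which the cascade is lossless. When a synthetic pool is so small
relative to the cohort that single genes accumulate more than 3 carriers,
the enrichment rule removes genuinely causal genes — exactly as the
published filter would. The no-false-rejection property therefore holds
(and is asserted) in the heterogeneous regime the study observed, where no
gene recurred more than 3 times.

## Pool-size estimation from recurrence

With `n` gene hits drawn uniformly with replacement from a pool of `p`
genes, the per-gene hit count is Binomial(n, 1/p), giving

    E[distinct]  = p * P(X >= 1) = p (1 - (1-1/p)^n)
    E[recurrent] = p * P(X >= 2) = p (1 - (1-1/p)^n - (n/p)(1-1/p)^(n-1))

and the recurrence rate r = recurrent/distinct (default; recurrent/draws is
available). The closed form uses `scipy.stats.binom.sf` because the naive
`1 - P0 - P1` cancels catastrophically for large p. r (recurrent/distinct)
is strictly decreasing in p, so the observed recurrence identifies the
pool. Note the second definition is *not* monotone below p ~ n: in the
saturated regime almost every extra pool gene becomes another recurrent
gene, so E[recurrent] grows like p. The estimator's identifiable regime is
pools larger than the hit count.

The estimator mirrors the original Monte Carlo procedure: grid-search
p = 1..1000 (step 1 by default), simulate 1000 replicates of n draws per
grid point, and minimize |mean r - r_obs| (ties toward the smaller pool;
estimates pinned to a grid end are flagged). The simulation estimates
E[recurrent/distinct] — a mean of ratios — which sits slightly above the
ratio of expectations (Jensen gap ~ +0.001 at p ~ 625, n ~ 123, up to
+0.01 at very small pools). The oracle-equivalence tests therefore compare
the simulation against an independently coded per-replicate tally, and
against the closed form with the measured gap allowed.

Headline calibration: r_obs = 9.4% among non-consanguineous solved cases
with n = 123 hits (178 SNV/INDEL findings minus the 55 in consanguineous
men) puts the minimum near p = 625. Taking the study's literal 221 draws
instead is inconsistent with a 9.4% expected recurrence under either r
definition (closed form: r(625, 221) = 16.6%); both n values are exposed
as plain parameters and the 123-draw calibration is the one that
reproduces the published estimate.

### False discoveries

A fraction `fdr` of hits may be false positives. Two placement models
bracket their effect on expected recurrence:

* never-recur (lower bound): FPs land on unique background genes — the
  distinct denominator keeps n*fdr extra genes while true hits drop to
  n(1-fdr);
* same-pool (upper bound): FPs are drawn from the pool itself and are
  indistinguishable from true hits, leaving r unchanged.

At p = 625, n = 221, fdr = 0.30 the bracket is [8.0%, 16.6%]. The
FDR-adjusted pool estimate re-runs the grid search under the never-recur
model; because that model's expected r rises to a mode near the true-hit
count before falling, the objective has two zeros and the argmin is
restricted to the decreasing branch (p at or above the closed-form mode),
the only regime compatible with a pool larger than the hit count. This
thinning construction is one consistent reading of an under-specified
adjustment; it reproduces the qualitative direction (the adjusted pool is
smaller) but not any particular published magnitude, so only monotonicity
is asserted.

## Cohort projections

For design, each case carries a discoverable cause with probability `d`
(the per-stratum detection rate), its gene uniform over the pool. The
projection simulates cohorts of size n (1000 replicates), measures the
mean fraction of pool genes seen in >= k cases, and bisects for the
minimal n reaching a coverage target, with a +-5 linear scan guarding
Monte Carlo noise at the crossing. Each candidate n is evaluated with a
seed derived from (base seed, n), so the search path cannot change a
point's value. The Poisson oracle — solve P(Pois(lambda) >= k) = target
with lambda = n d / p — gives n = p*lambda*/d; at p = 625, target 0.5,
k = 2: lambda* = 1.678, hence ~1049 cases at d = 1, ~6993 at d = 0.15
(outbred) and ~1380 at d = 0.76 (consanguineous). n*d is approximately
invariant in d, which the tests assert as a scaling law. Coverage targets
of 1 are rejected: a finite pool is never fully covered with certainty.

## Burden testing

Carrier proportions are compared with Fisher's exact test; the two-sided
p-value follows the minimum-likelihood convention (sum of point
probabilities no larger than the observed table's), the dominant
convention in scientific software. The independent oracle in the tests is
a from-scratch enumeration over margin-fixed tables. The odds ratio is the
sample OR with infinity for zero cells (Haldane 0.5-correction behind a
flag). Two-stage significance uses alpha divided by the number of genes
effectively screened in the discovery stage; 20,000 genes at alpha = 0.05
gives the strict threshold p < 2.5e-6. Compound-heterozygous carriers are
excluded from burden inputs by design (control-side pair phasing is
unavailable in the fertile-parent cohort this mirrors). A generic exact
lower-tail binomial test covers observed-vs-expected count comparisons
such as novel predicted knockouts among controls.

## Expression statistics

Tissue specificity follows the five-fold rules used for bulk tissue
panels, with precedence tissue-enriched (top tissue >= 5x every other
tissue) > group-enriched (mean of a group of 2-7 tissues >= 5x every
remaining tissue) > tissue-enhanced (top tissue >= 5x the grand mean).
The group search scans rank-contiguous top-k sets only: any group
achieving the fold criterion against the maximum of the remaining tissues
can be improved by swapping a member for a higher-ranked outsider, so the
optimal group is always rank-contiguous and the exponential subset search
is unnecessary. Classes are mutually exclusive, exhaustive, and invariant
to rescaling the matrix.

"Genes loading on a component" is operationalized as membership in the
component's top-250 genes per side (positive and negative loadings taken
separately, union by default), the same convention the original analysis
used for component gene-set enrichment; a threshold-on-magnitude mode is
available. Query sets are profiled as per-component membership counts;
profiles are compared by Pearson correlation. Whether a reference profile
(e.g. disease genes) resembles one comparison set more than another is
tested with the Pearson-Filon Z for two dependent overlapping
correlations in the Fisher-z (ZPF) form: the difference of z-transformed
correlations scaled by its null standard error with the Pearson-Filon
covariance term at the pooled correlation. ZPF is used for its better
finite-n calibration; the tests verify a 4-6% rejection rate at
alpha = 0.05 under a trivariate-normal null (n = 70, 1e4 replicates) and
agreement with an exact column-swap permutation oracle at n = 300 (at
n = 70 the asymptotic and exact answers can differ by a few hundredths
around p ~ 0.1 — inherent to any asymptotic test, not a defect the
calibration test would miss). Component enrichment of a query set is the
upper-tail hypergeometric probability of the observed overlap.

## piRNA maturity

Histograms cover the 25-45 nt piRNA window; the maturity statistic is the
fraction of reads strictly below 32 nt. Spike-in normalization (division
by the spike-in count) supports cross-library visualization and leaves
the mature fraction unchanged, which is why the case/control comparison —
a one-sided hypergeometric (Fisher) test on the 2x2 of mature/immature by
case/control — runs on raw read counts: an exact count-based test is only
valid on counts. One boundary fact worth knowing: for identical case and
control histograms the one-sided exact p equals 1 only when a margin is
degenerate (e.g. all reads mature); a generic identical pair gives a
non-significant p above 0.5, not exactly 1.

## ROH and consanguinity

Autosomal ROH segment lengths are fit on the natural-log scale with a
five-component Gaussian mixture — plain EM, k-means++-style
initialization, 10 restarts keeping the best log-likelihood, component
collapse (sd below 1e-6) retried with fresh starts up to a 2x budget. The
contract is "five-component 1-D Gaussian mixture", not bit-compatibility
with any particular package; an sklearn GaussianMixture fit serves as the
independent cross-check in tests, and the per-iteration log-likelihood
trace is exposed so monotone EM convergence is asserted directly. The
longest-mean component (class 5) captures recent inbreeding; FROH is its
total length — after subtracting overlap with hemizygous (CNV-deleted)
regions, merged intervals, 0-based half-open arithmetic — divided by the
autosomal length (default 2.88e9 bp). Samples are labelled consanguineous
above FROH 0.03 (roughly second-cousin offspring); the threshold is
configurable since the source analysis does not print one.

## Synthetic data: what it emulates, and what it does not

The generators produce every input with planted, recoverable truth:

* Gene universe: unique ids; chromosomes 1-22/X/Y with configurable
  weights (~6.6% X, ~1% Y by default); testis specificity classes with
  configurable proportions (~11% elevated by default); 5% known
  infertility genes; log-normal premeiotic expression.
* Cohorts: all-male (the phenotype is male infertility; `sex` kept for
  schema clarity). Per-stratum discovery rates default to the study's
  76.4% (consanguineous) and 14.9% (outbred). False positives pass every
  filter and land outside the causal pool (uniformly at random) unless
  the within-pool switch is set; the default per-individual FP rate is
  6%, the background rate seen in non-reproductive controls. Sex
  chromosomes carry only hemizygous models — no male heterozygous X/Y
  calls are emitted. Causal pools drawn from `aggregation_ready_genes`
  guarantee planted truth survives the cascade.
* ROH: five log-normal length classes at ~50 kb/150 kb/400 kb/1.5 Mb/8 Mb
  (log-sd 0.25, adjacent means > 3.9 sd apart, so classes are separable
  by construction); lengths are generated on the log scale because real
  ROH length distributions are heavy-tailed. Consanguineous individuals
  receive class-5 segments until their planted FROH exceeds 1.5x the
  labelling threshold. Intervals are 0-based half-open, non-overlapping
  per (sample, chromosome).
* Loadings: planted modules get high positive loadings over zero-mean
  Gaussian background.
* piRNA: mature lengths peak at 29-30 nt, immature reads decay over
  32-45 nt; each read is mature with the planted probability.
* Tissue matrices: 37 tissues by default (the panel size of the atlas the
  rules come from); profiles are constructed so the classifier provably
  recovers the planted class, with 2% jitter inside every rule margin.
  Planting tissue-enhanced needs at least 10 tissues: with the 5-fold
  rules, a tissue at 5x the grand mean in an 8-tissue panel is forced to
  be tissue- or group-enriched (the binding inequality chain caps
  max/mean at ~4.7), so the generator rejects that request.

None of this emulates sequence content, linkage disequilibrium, realistic
site-frequency spectra, read-level noise, or per-gene mutation-rate
heterogeneity (the pool model assumes exchangeable genes). Passing tests
show the statistics behave correctly under the stated model — not that
the model captures every property of real exome cohorts.

## Problem sizes and numerical choices

Test and script problem sizes are chosen to make Monte Carlo noise small
relative to the tolerances they assert: 1000 replicates per grid point for
the headline pool estimate (matching the original procedure), 2000 for
parameter recovery, 1e4 for oracle-equivalence and type-I calibration.
Parameter recovery averages the recurrence tally over six independent
synthetic cohorts per pool: a single cohort's observed recurrence carries
an identifiability floor of ~10% relative error at a 100-gene pool (noise
in r_obs divided by the curve slope), which no estimator can beat; the
averaging isolates what the test is about — estimator accuracy. Recovery
grids use steps of 2-5 genes, far inside the +-10% tolerance. Ties in all
argmins break deterministically (smallest pool; lexicographic gene ids in
top-N extraction). Degenerate inputs are rejected loudly: empty gene
universes, invalid simplex weights, non-positive mixture sds, zero spike
counts, all-zero contingency tables (p = 1 with a warning), zero-variance
profiles (NaN with a warning), |r| = 1 in the dependent-correlation test.

## Orchestration

`run_pipeline` wires the stages on one synthetic cohort and writes TSV
tables, a `summary.json` of scalar results, and a `manifest.json` with all
parameters, the seed, and SHA-256 checksums of every output;
`verify_run` re-hashes the outputs so tampered intermediates fail fast.
Runs are byte-identical given the same config and seed. The `noapipe` CLI
exposes `simulate`, `prioritize`, `burden`, `architecture`, `expression`,
`pirna`, `froh` and `run-all` as thin wrappers over the library.

## Known limitations

* The FDR-adjusted pool estimate is one construction of an
  under-specified adjustment; alternative FP-placement mechanisms give
  different magnitudes.
* The gene-enrichment filter's exact statistical definition is a stated
  convention (distinct-individual count), not a published procedure.
* The ZPF test is asymptotic; below n ~ 100 its p-values can differ from
  exact permutation answers by a few hundredths.
* PSAP p-values, component loadings and ROH segments are consumed as
  inputs; their upstream inference is out of scope.
* Burden testing covers single-variant carriers only, by design.
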