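# Methods

This note documents the statistical procedures `mirsubpath` implements, the
defaults it ships with, what the synthetic-data generator does and does not
emulate, and the choices made where the design was genuinely open.

## Subpathway construction

A pathway is an undirected, unlabeled gene graph. KGML input keeps only
gene-type entries; relation subtypes and edge direction are collapsed,
because nothing downstream uses topology beyond shortest-path distance —
the subpathway statistic is a pure membership test. Entries naming several
genes are expanded to all members with a clique among them (the members are
interchangeable in the pathway's wiring), and a relation incident to such
an entry connects every member.

A *subpathway* is a maximal set of genes with pairwise shortest-path
distance ≤ k, with distances measured in the **full parent pathway graph**:
two genes joined by a short path through non-member genes still count as
close. This is exactly the clique structure of the k-th graph power, so
extraction runs Bron–Kerbosch (networkx `find_cliques`) on `nx.power(G, k)`
— exact and comfortably fast for pathway-scale graphs (≲ few hundred
nodes). The default k = 3. Region indices (`<pathway>_1, _2, …`) are
assigned after sorting maximal sets by (size descending, lexicographic gene
list); the numbering is a determinism contract, not a biological claim.

miRNA embedding uses the plain membership rule: a miRNA joins a region when
at least one curated interaction (by default restricted to the
low-throughput-verified evidence class) targets a member gene, and only
edges to member genes are recorded. Embedding is idempotent. Regions with
fewer than 3 genes or fewer than 1 miRNA are discarded.

## Survival screening

* Samples with observed time < 1 month are excluded (configurable); the
  boundary value 1.0 is kept.
* Good/poor strata: below the median observed time → poor, otherwise good.
  Censored samples are classified by their censored time — the simplest
  reproducible rule; it is isolated in `median_survival_strata` so an
  alternative policy is a one-function change.
* The stratified train/test split allocates `train_frac` of each stratum by
  largest-remainder rounding (default 76/112, the shape of a ~112-patient
  cohort split 76/36). Training subsets are independent stratified halves,
  ⌈0.5·n⌉ samples each, drawn without replacement within a subset; subset j
  uses the seed substream `[seed, 13, j]`, so any subset can be regenerated
  in isolation.
* Expression enters every Cox fit as z-scored log2(FPKM+1). The transform
  stabilizes heavy-tailed FPKM values and puts all coefficients on a
  per-standard-deviation scale, which the risk score later reuses; it is a
  package decision, recorded here because the upstream convention varies
  between studies.
* The univariate Cox solver is a 1-D Newton iteration per feature on the
  Efron partial likelihood, vectorized across features (the pipeline refits
  hundreds of features on each of 100 subsets, so per-feature model objects
  would dominate runtime). Efron's correction is exact when event times are
  distinct. Degenerate (zero-variance, or event-free-cohort) covariates are
  flagged and given p = 1 by convention; fits whose coefficient runs beyond
  |β| = 10 per SD are flagged nonconverged — that regime is a monotone
  partial likelihood whose MLE is infinite, and the Wald statistic is
  meaningless there. The solver is cross-checked in the test suite against
  a direct grid search on the partial likelihood and against lifelines.
* Screening keeps converged fits with Wald P < 0.05, miRNAs and genes
  separately. **No multiplicity correction is applied at this step** — the
  raw per-feature threshold is deliberate: the screen feeds an enrichment
  statistic, and its operating characteristics (≈5% of null features) are
  exactly what the hypergeometric urn assumes.

## The pooled hypergeometric statistic

Genes and miRNAs are pooled into one urn of N = m_g + m_mir measured
features; a subpathway contributes K = t_g + t_mir members, the screen
draws n = n_g + n_mir survival features, r = r_g + r_mir land inside. The
reported p-value is the exact upper tail P(X ≥ r) for
X ~ Hypergeom(N, K, n), computed with scipy's survival function (log-space
internally) and clamped to [0, 1].

Decisions:

* The universe is the **measured** feature set (rows of the expression
  matrices), and subpathway member counts are restricted to measured
  features — otherwise the urn would contain balls that can never be drawn.
* r = 0, K = 0 or n = 0 returns P = 1: no evidence is never significant.
* Genes and miRNAs share one urn rather than being tested separately; a
  stratified variant (e.g. Fisher's combination of two tails) is out of
  scope.
* Subpathway calls use raw p < 0.05; a Benjamini–Hochberg column is written
  for information only.

## Robustness ranking

The screen + hypergeometric call runs on each of the 100 training subsets;
a subpathway's count is the number of subsets where it reached P < 0.05.
Ranks are dense on count (ties share a rank), with mean p-value over all
subsets, then id, breaking ordering ties deterministically. Selection
supports both `top_n` (dense rank ≤ n; default 3) and `min_count`
(count ≥ c) because a published threshold phrased as "rank value > 43" can
be read either way; the default follows the top-ranks reading. Per-subset
results are cached one TSV per subset, so an interrupted sweep resumes.

## Risk scores and evaluation

A subpathway's risk model weights **all** measured members — significant or
not — by their univariate Cox coefficients refit on the full training set
(the screen's subset-level coefficients are resampling artifacts; the model
is a training-set object). Component covariates reuse the screening
transform with training-set means/SDs frozen into the model, so held-out
samples are scored on the training scale. Degenerate components get weight
0 and are flagged; a model with no usable component is an error.

Groups are high if score > cutoff, low otherwise (ties to low). The cutoff
is the training-set median **also on the testing set** — using the test
set's own median would leak the evaluation data into the classifier; the
variant is available behind a flag in the CLI-facing evaluation. KM curves
come from lifelines' product-limit estimator; the two-group log-rank test
uses the standard hypergeometric-variance form, p-values floored at 1e-300
(a printed 0 would be underflow, not a claim).

The combined model Cox-weights the single-subpathway training scores (raw,
unstandardized — the combined score stays a literal linear combination of
risk scores) and applies its own training median.

## Synthetic scenarios

The generator emulates the statistical skeleton the pipeline assumes:

* **Pathways**: Erdős–Rényi gene graphs (default 20 pathways × 12 genes,
  edge probability 0.25), repaired to connectivity by bridging components
  with one random edge each — at edge probability 0 this yields a random
  tree. Gene ids are globally unique.
* **Interactions**: each (miRNA, gene) pair independently with probability
  0.02 over 60 miRNAs (≈6–8 miRNAs per typical 5-gene region, a scaled-down
  analogue of curated interaction densities); 80% of rows are tagged
  low-throughput, the rest high-throughput, so the evidence filter is
  exercised.
* **Expression**: log-normal, feature-specific location/scale — FPKM-like,
  non-negative, right-skewed, no missing values.
* **Planted modules and survival**: each planted subpathway s has a latent
  per-sample activity a_s; its member features load on that factor with
  within-module correlation ρ = 0.5 on the log scale, and the hazard is
  proportional-hazards in the activities,
  h_i = h₀ · exp(Σ_s (β/√ρ) a_si), with h₀ = ln2/12 per month (12-month
  median baseline survival, an AML-like figure). The scaling makes each
  planted feature's **marginal** log hazard ratio per SD of log2(x+1)
  expression equal β (`effect_size_beta`, default 1.0), which is the
  quantity a univariate screen estimates. A naive model with β summed
  independently over every member would compound to cohort hazard ratios of
  e^±10 for realistically sized modules — nothing a survival cohort shows —
  and would break the identity between the planted β and the per-feature
  estimand. β = 0 gives an exact null (co-expression remains, association
  does not).
* **Censoring**: C = `min_followup` + Exp(c), with c solved by Brent's
  method so the expected censored fraction matches `censor_rate` (default
  0.35) given the realized per-sample hazards; the 1-month floor represents
  minimal administrative follow-up. An unreachable target (too many deaths
  before the floor) raises instead of silently under-censoring.
* **Cohort size**: default 320. Under the default three-module hazard
  spread, the expected fraction of samples dying before the 1-month
  exclusion window is 20.2% (numerical integral of E[1 − exp(−h₀e^η)] with
  η ~ N(0, 6)), so 320 samples leave ≥ 210 survivors — enough for a fixed
  150/60 train/test design — with probability ≈ 1 − 1e-10.
* **Determinism**: one master seed; every artifact draws from a fixed
  substream (`[seed, 1]` pathways, `[seed, 2]` interactions, `[seed, 3]`
  expression, `[seed, 4]` survival), so identical configs are bit-identical
  and artifacts can be regenerated independently.

What the generator does **not** emulate: miRNA sequence biology, isoform
structure, batch effects, library-size artifacts, gene–gene co-expression
outside planted modules, non-exponential baseline hazards, informative
censoring. Passing recovery tests therefore show that the pipeline's
inference machinery works when its model assumptions hold — not that those
assumptions hold in any particular cohort.

## Validation experiments and problem sizes

`mirsubpath.validation` packages the recovery/calibration experiments run
by the test suite and `scripts/acceptance.py`:

* Null screen calibration: 200 replicate cohorts of 200 samples × 1000
  features, pooled rejection rate at α = 0.05 (~200k Wald tests).
* Log-rank calibration: 500 random half/half groupings of 100-sample null
  cohorts, KS test for uniformity of p-values.
* Planted recovery: 5 replicates of the full design — 40 subpathways, 3
  planted modules at β = 1, 210-sample analysis cohort split 150/60, 100
  stratified half-subsets — measuring the planted modules' dense robustness
  ranks and their risk scores' held-out log-rank p-values.

These sizes keep a full validation run around one minute on a single CPU
while leaving the binomial/KS tolerances meaningful.

## Known limitations

* The k-clique decomposition produces heavily overlapping regions on
  tree-like graphs; overlapping neighbours of a true prognostic module
  legitimately inherit part of its signal, so robustness ranks should be
  read per-region-family, not as independent discoveries.
* The good/poor stratification treats censored times as observed; with
  heavy early censoring the strata drift toward "good".
* Wald screening p-values are first-order; at very small subset sizes
  (< ~40 samples) their null rate can deviate from nominal.
* The hypergeometric urn assumes feature exchangeability; correlated
  features (including planted co-expression) make it conservative or
  anti-conservative depending on where the correlation sits.
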