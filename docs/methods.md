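# Methods

This note documents the statistical model behind each stage, the defaults
and why they are set where they are, what the synthetic-data generator does
and does not emulate, and the numerical choices a maintainer should know
about.

## Two-sample MR on cis-eQTL summary statistics

Each exposure is one *expression profile*: a gene in one CD4+ T-cell state
at one activation time point.  For instrument j, `β_GX(j)` is its effect on
the profile's expression (per effect allele, from the eQTL cohort) and
`β_GY(j)` its effect on the cancer outcome (log-odds, from the case-control
GWAS).  Under the usual instrumental-variable assumptions the causal effect
is the ratio `β_GY/β_GX`; with several approximately independent
instruments the fixed-effect IVW estimate is the inverse-variance-weighted
average of the ratios, equivalently weighted least squares of `β_GY` on
`β_GX` through the origin.

Exposure and outcome statistics are first harmonized to a common effect
allele.  Palindromic variants (A/T, C/G) with effect-allele frequency in
[0.42, 0.58] on either side — or with missing frequency — are dropped:
their strand cannot be resolved.  Outside that band they are aligned by
allele letters with a frequency-concordance check.  This rule is a
package-level choice (standard two-sample practice, conservative); it is
not dictated by the estimators.

### Instrument selection

Two pipelines, both requiring a *cis* position (gene body ± 500 kb, closed
1-based intervals) and a Steiger pass:

* strong: F ≥ 10, then greedy LD clumping at r² < 0.001;
* weak: association p < 0.05 and F ≥ 5, clumping at r² < 0.1.

F is the squared z-score `(β/se)²`; the variance-explained form
`r²(n−2)/(1−r²)` is available behind a flag and agrees to a factor
`n/(n−2)`.  Steiger filtering compares variance explained,
`r² = z²/(z²+n)`, between exposure and outcome; ties fail.  For
case-control outcomes the effective sample size `4/(1/n_cases +
1/n_controls)` replaces n — the binary trait carries less information per
sample; this case-control adaptation follows common usage.  Greedy
clumping keeps the best-p variant and removes everything in LD with a kept
variant; ties break on (p, variant id) so results are deterministic.

Note that at reference-panel sizes of a few hundred samples, chance LD
(~1/n_ref) exceeds the strong threshold of r² < 0.001, so strong sets are
typically 1–2 instruments — which is why the main analysis dispatches the
single-instrument Wald ratio so often, mirroring real single-cell eQTL MR.

### The weak-instrument suite

Eight estimators run per exposure-outcome pair (each skipped below its
instrument floor: Wald needs 1, IVW/debiased-IVW 2, median/mode/robust/
cML/RAPS 3, PRESSO 4).  MR-Egger is deliberately absent: with cis-only
instruments from one locus the InSIDE assumption is not credible.

* **Weighted median** — interpolated weighted empirical CDF of the ratio
  estimates at 0.5; weights are inverse first-order ratio variances;
  consistent while valid instruments carry ≥ 50% of the weight.
* **Weighted mode** — argmax of the weighted Gaussian-kernel density of
  the ratios; bandwidth `0.9·min(sd, mad)·n^{−1/5}` times a configurable
  factor (default 1).
* **MR-Robust** — Tukey-bisquare (c = 4.685) IRLS regression through the
  origin with 1/se² base weights, median-of-ratios start, Huber fallback.
* **Debiased IVW** — subtracts the exposure sampling variance in the
  denominator, `Σw(β_GX²−se_GX²)`, removing weak-instrument attenuation;
  a non-positive corrected denominator is flagged as "too weak", no
  estimate.
* **MR-RAPS** — profile likelihood with standardized residuals
  `t_j = (β_GY − β·β_GX)/√(se_GY² + β²se_GX² + τ²)`, overdispersion
  τ² ≥ 0 estimated jointly, Huber-robustified (k = 1.345) estimating
  equations with the exact normal-consistency constant `2Φ(k)−1`.
* **MR-PRESSO** — leave-one-out weighted residual sum of squares compared
  with a parametric-resampling null; per-instrument outlier p-values are
  Bonferroni-adjusted, and outliers are removed (IVW recomputed) only when
  the global test is itself significant.
* **cML-MA** — constrained ML allowing exactly K instruments free
  pleiotropy, for K = 0..nsnp−2, model-averaged with BIC weights.  The BIC
  penalty is `K·log(N_outcome)` with N the outcome GWAS sample size
  (fallback 1e5): a penalty growing only with the instrument count cannot
  separate a chance extreme residual from genuine pleiotropy, and the
  selection would never concentrate on K = 0.

### Standard errors and p-values at a handful of instruments

Single-cell weak-instrument sets hold ~5 instruments, where textbook
asymptotics visibly fail.  The package's choices, validated against the
generator's global-null scenario (all methods hold a 3–7% positive rate at
p < 0.05):

* median/mode bootstrap se uses IQR/1.349 of the seeded parametric
  bootstrap (1000 draws by default) — the plain SD is inflated by
  multi-modal bootstrap draws and makes the normal test badly
  conservative;
* MR-Robust and the weighted mode take their p-value from a seeded
  parametric Monte-Carlo null test (`β_GY* ~ N(0, se_GY)`), which is
  calibrated by construction; their reported se (sandwich floored by the
  model-based variance, and bootstrap IQR respectively) is for CIs;
* MR-RAPS uses an `n/(n−2)` df correction on the observed-information se
  and a t reference with df = nsnp + 2, which holds the nominal level
  across instrument counts 4–15 under the generator's null model.

### Multiple testing and validation

BH-FDR is computed per method across all exposure-outcome tests of a run
(configurable to one global family).  Cross-method validation counts, per
pair, the methods with q < 0.05 and flags validation at ≥1/≥2/≥5 methods;
a pair significant in ≥5 weak methods but not in the main analysis is a
weak-only discovery.  The method benchmark reports, per method, the
percentage of its estimates passing FDR (power proxy) and the percentage
of its significant findings validated by ≥2 other methods (robustness
proxy).

## Colocalization

Per-variant Wakefield log-ABFs with prior effect variance W = 0.15²
(quantitative) or 0.2² (case-control), computed in the stable log form.
The five-hypothesis posterior assumes at most one causal variant per trait
per region; configuration sums are done with log-sum-exp.  Priors
p1 = p2 = 1e-4, p12 = 1e-5.  Primary decision rule:
PP.H4/(PP.H3+PP.H4) > 0.70; the plain PP.H4 > 0.70 rule is available by
flag, and reports carry both the posteriors and the ratio so neither is
silently preferred.  The region is the instrument's cis window.  The
LD-check approximation passes when the instrument has panel r² > 0.7 with
any outcome variant at p < 1e-3 in the region; overall colocalization
evidence is the OR of the two.

## Single-cell differential expression

QC removes cells with ≤ 200 detected features or > 5% mitochondrial
reads (inclusive/strict exactly as written).  Normalization is library-size
scaling to 10 000 followed by log1p — a deliberate divergence from
regularized-NB normalization, which is out of scope here; the downstream
consumer is a rank test and therefore robust to monotone per-cell
transforms.  DEG is a two-sided Wilcoxon rank-sum of tumor vs normal on
normalized values for genes detected in ≥ 10% of either group;
log2FC is computed on the de-logged scale with pseudocount 1, and results
under |log2FC| 0.25 are suppressed.  A rank test cannot take a batch
covariate, so batch is handled by per-batch tests combined with Stouffer
weights √cells (default) or ignored (flag); how a covariate interacted
with the original marker test is not recoverable, hence both modes.

A DEG supports an MR signal iff its p < 0.05 and its fold-change sign
matches the MR beta; zero effects never support.

## MR-DEG

Each instrument is scanned against every exposure's summary statistics at
p < 1e-4 (configurable); the union over a signal's instruments, minus
profiles of the focal gene, is its competitor set.  Competition is at gene
level — different cell states of the same gene are the same drug target,
not a pleiotropy concern.  A DEG-supported signal is then
`likely_causal_single` (no competitors), `likely_causal_mrdeg` (no
competitor with same-cancer DEG support), or `pleiotropy_unresolved`;
signals without focal DEG support are never classified causal.
Competitors absent from the single-cell panel count as
unsupported-but-flagged by default (absence of measurement is not evidence
of absence); a strict mode treats them as unresolved.

## Specificity analyses

Cell-type enrichment: per cell-state/time stratum, Fisher's exact test of
[signals, eGenes−signals] against the remaining strata, BH within the
family — this asks whether a stratum converts eGenes into MR signals more
often than the rest, controlling for how many eGenes it has.  Cancer
enrichment rescales case counts to a common unit before the 2×2 (the
normalization the OR needs is not fully specified anywhere, so the
pseudo-count construction is flagged as a package choice; the unit adapts
at desk scale so scaled totals stay above signal counts).  Temporal
contrasts: the reference time point maximizes the summed absolute
difference to the others; pairwise Z = (b_ref−b_t)/√(se_ref²+se_t²), with
any p < 0.05 marking the triplet time-dependent.  Naive-vs-memory uses the
same Z on the best-precision estimate per compartment.  T-cell expression
specificity is two-tier — ≥5× *enriched*, ≥2× *enhanced* — against the max
(default; conservative) or mean over non-T immune cell types.

## Prioritization

MCC(v) = Σ over maximal cliques C containing v of (|C|−1)!, via
Bron–Kerbosch with pivoting; an isolated node scores 1 (singleton clique
convention).  Core genes have MCC ≥ 9 within the cancer-linked gene
universe, which is an explicit input.  The evidence score grants
DEG +1, MR-DEG +1, T-cell specificity +0.5 (either tier), time
specificity +0.5, core gene +1, clinical trial +1; total 5, prioritized at
≥ 4.  T-cell and time specificity are granted if any constituent exposure
of the pair qualifies.  The trial join is case-insensitive on gene symbol,
with an exact indication match resolved through a small controlled
vocabulary.

## The synthetic-data generator

Defaults mirror the study conditions the pipeline is built for: 120 eQTL
donors, 50 000 GWAS samples (20 000 in the desk-scale recovery scenarios),
500 reference samples, MAF 0.1–0.5, AR(1) within-block LD ρ = 0.6.

* **Genotypes** — two haplotypes per sample from a Gaussian copula with
  AR(1) correlation inside each gene block, thresholded at the MAF
  quantile.  Blocks are independent; no recombination-map realism.
* **eQTL summary statistics** — donor expression is `G·b + N(0,1)`, then
  per-variant marginal OLS; reported p-values are Wald (normal), the
  convention of released summary statistics.  Pleiotropy is wired
  explicitly: a variant can inject its effect into any set of exposures,
  across genes.
* **Outcome GWAS** — liability is the sum of causal genes' genetically
  regulated expression times their effects plus standard-normal noise;
  cases are the top `case_fraction` (default 0.1).  Per-variant summary
  statistics are one-step logistic score statistics (score and information
  from the intercept-only model), the standard GWAS approximation — exact
  to first order for small per-variant effects and fully vectorized; a
  linear-on-liability mode exists.
* **Single-cell counts** — negative-binomial per gene × cell with tumor
  means scaled by `2^logFC`, log-normal cell size factors, a simulated
  feature-count column and a Beta(2, 60) mitochondrial percentage so QC
  has something to cut.  No doublets, no ambient RNA, no batch effects on
  the means themselves.

Everything is a pure function of (config, seed); per-stage streams derive
from the scenario seed and a stage-name hash, so stages reproduce
independently.

What passing tests on these simulations do **not** show: robustness to
fine-scale LD and allele-frequency structure of real panels, to
winner's-curse-ascertained instruments, to SCTransform-vs-lognorm
differences at low depth, or to cell-type misannotation.  They do show
that every estimator implements its defining equations (oracle
equivalences), holds its type-I error under the null the model assumes,
and recovers planted effects through the full pipeline.

## Problem sizes in the validation suite

The null-calibration scenario uses 160 genes × 5 outcomes (~800
exposure-outcome suites, ~500+ tests per method) with 400 bootstrap/MC
draws per resampling method; DEG calibration uses six datasets of 150 null
genes (~900 tests); recovery runs 20 end-to-end seeds of a 20-gene
scenario (strong-instrument mode) and 50 two-gene pleiotropy replicates;
method contrasts use 50–200 summary-level replicates.  These sizes give
the binomial bands quoted in the tests a comfortable margin while keeping
the whole suite desk-scale.

## Known limitations

* Single-causal-variant colocalization only; no fine-mapping or
  multi-signal decomposition.
* Clumping approximates conditional independence; no COJO-style joint
  re-analysis (conditionally independent eQTLs are taken as given when
  the input provides them).
* The Monte-Carlo p-values for MR-Robust and the weighted mode have
  resolution 1/(draws+1); with the default 1000 draws the smallest
  attainable p is ~1e-3, which bounds those methods' FDR-corrected
  discovery power in very large runs (raise the draw count if needed).
* Binary-outcome MR on the log-odds scale ignores non-collapsibility;
  effects are interpreted as approximate population-averaged log-ORs.
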