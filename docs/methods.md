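# Methods

`tmepipe` reimplements a tumor-microenvironment (TME) characterization
workflow for bulk tumor cohorts: estimate immune-cell composition from bulk
RNA-seq, cluster patients by infiltration pattern, derive a prognostic TME
score from the genes that distinguish those patterns, and relate the score
groups to somatic mutation signatures and copy-number aberrations.  Every
stage is exercised end-to-end on synthetic cohorts with known ground truth;
this note records the models, the parameter choices that matter, and what
the synthetic experiments do and do not establish.

## Synthetic cohorts

The generator (`tmepipe.synthetic`) produces the joint data a real cohort
would supply — expression counts, survival, a MAF-like mutation table and a
SEG-like segment table — with planted structure that every downstream stage
is designed to recover.

**Expression.** A bundled LM22-style reference (22 cell types x 500 genes,
block-structured with >= 20 marker genes per type, generated from a fixed
internal seed) is mixed with per-sample cell fractions drawn from
pattern-specific Dirichlet distributions.  With `n_patterns = 3` (default),
pattern *p* boosts the Dirichlet concentration of its own block of cell
types from a baseline of 0.25 by +4.0, giving well-separated infiltration
profiles with realistic within-pattern variability.  Expected gene
expression is `library_size x (reference · fractions)` (library size
log-normal, mean 1e5, CV 0.2) and counts are negative-binomial with
gene-level dispersion 0.1 — a typical bulk RNA-seq value; the mean-variance
trend is what the voom-style transform downstream exploits.  Sixty
explicitly planted differentially expressed genes receive a x2^2.5
multiplicative effect in one pattern each.  The `SimTruth` object carries
two DEG truth sets: the planted list (for recall) and the full set of genes
whose noise-free pattern profiles differ by |log2FC| > 1 in >= 2 pairwise
contrasts (for false-discovery accounting — marker genes are genuinely
differential because the mixing proportions differ).

**Survival.** Overall survival is exponential with pattern hazard ratios
(0.5, 1, 2) on a base hazard of log(2)/1000 per day (median OS ~1000 days at
HR 1).  Exponential censoring is calibrated by solving
`E_p[c/(c + lambda_p)] = censoring_rate` (default 0.3) with Brent's method,
so the empirical censoring fraction matches the target.  Exponential
hazards keep Cox log-HR recovery closed-form.  A binary
immunotherapy-response proxy is emitted with probability 0.5 in the most
favourable pattern and 0.2 elsewhere; it exists so ROC comparisons have an
outcome, and is not a model of any particular trial endpoint.

**Mutations.** Per sample, a signature exposure vector selects among three
planted 96-context signatures: an APOBEC-like signature with 90% of its
mass on T[C>T]W and T[C>G]W, a CpG-deamination-like C>T-at-NCG signature,
and a diffuse T>C signature.  A quarter of samples (default) are
APOBEC-dominated (90% exposure); the rest carry the APOBEC signature at 2%.
Counts are multinomial (50–200 mutations/sample, uniform).  Each drawn
category becomes a MAF record with a fabricated unique position, a
consistent 3-mer context and a ±20 bp flank (uniform base composition, so
the background TCW/C ratio is ~0.125 per strand); half the records are
emitted on the purine strand to exercise pyrimidine collapsing.  Positions
are arbitrary because no genome is involved; the context strings are
authoritative.

**Copy number.** A toy genome of 4 chromosomes x 2 arms x 50 Mb.  Segment
values are N(0, 0.1) background; planted events add +1.5 to the whole of
chr2q in 60% of samples, −1.5 to chr3p in 40%, +2 to a 1-Mb window on chr1
in 40% and −2 to a 1-Mb window on chr4 in 35%.

All three generators are pure functions of `SimConfig` (the seed is a
mandatory field); independent sub-streams keep expression, mutation and CNV
draws uncorrelated.

What the synthetic cohorts do **not** emulate: gene-gene correlation beyond
cell-type mixing, batch and purity effects, non-proportional hazards,
subclonal copy-number mixtures, genome-dependent trinucleotide availability,
and signature exposures correlated with expression patterns.  Passing
recovery tests therefore demonstrates algorithmic correctness under the
stated model, not performance on TCGA-like data.

## Deconvolution

`deconvolution.deconvolve` reimplements the nu-SVR deconvolution algorithm:
genes are intersected with the reference, the reference matrix is z-scored
jointly over all entries and each mixture column over the intersected genes,
a linear-kernel nu-SVR is fitted for nu in {0.25, 0.5, 0.75}, the nu with the
smallest RMSE between fitted and observed mixture wins, negative
coefficients are clipped and the remainder normalized to the simplex.
Quantile normalization of the mixture is off by default (recommended for
RNA-seq); a rank-based variant is available.  The permutation p-value
compares each sample's fit correlation against a single shared null built
from mixtures resampled at random from the input matrix (1000 draws by
default), which makes 1000 permutations affordable for arbitrarily many
samples.  Input must be linear-scale; a max-value < 50 heuristic warns about
probable log-scale input.  Degenerate all-zero fits return uniform fractions
and a flag rather than an error.

## Consensus clustering and choice of K

`consensus.consensus_cluster` follows the resampling scheme: for each K,
subsample 80% of items 1000 times, run the base clustering (K-means, a
single k-means++ start per resample; Ward hierarchical available), and
record the fraction of co-samplings in which each pair co-clusters.  A
single start per resample is deliberate: the elbow criterion below relies
on over-split solutions being irreproducible across resamples, and
best-of-many-restarts K-means makes the spurious split of a true cluster
artificially stable, inflating the CDF-area gain just past the true K.  Final labels come from
average-linkage hierarchical clustering of 1 − consensus.  K is selected
from the area under the CDF of consensus entries: the chosen K is the
largest one whose relative area increase Δ(K) = (A(K) − A(K−1))/A(K−1)
(Δ at the smallest K is A itself) exceeds 0.1.  The reference implementation
of this workflow leaves the elbow to the analyst's eye; the 0.1 rule makes
it deterministic, all Δ values are logged, and `--k` overrides.

## Differential expression

Counts are filtered (>= 10 in >= 20% of samples, boundaries inclusive),
transformed to log2-CPM with the voom offsets
(`log2((c + 0.5)/(lib + 1) x 1e6)`; optional lowess precision weights), and
tested per gene with a moderated two-sample t: pooled residual variance
s_g^2 with d_g df, prior (d0, s0^2) by method-of-moments on log s_g^2
(closed-form trigamma inversion), posterior variance
(d0 s0^2 + d_g s_g^2)/(d0 + d_g), total df capped at the summed residual df.
The implementation reproduces R limma's eBayes t and p values to ~1e-6 on
fixtures in both the finite-d0 and infinite-d0 regimes.  Significance is the
raw-p rule (p < 1e-3 and |log2FC| > 1); BH-FDR is reported as an extra
column but plays no role in calling.  "Common" DEGs across the three
pairwise cluster contrasts default to significant-in->=2-contrasts
(`--common-rule {any,two,all}`): a strict 3-way intersection is bounded by
the smallest contrast and cannot reproduce the kind of common-DEG counts
this workflow reports, while >= 2-of-3 captures genes tied to more than one
cluster boundary.

## TME signature and score

Common DEGs are reduced with a random-forest classifier (cluster label as
class).  Ranking uses the forest's mean Gini impurity decrease, and genes
above the mean importance are kept.  Gini rather than permutation
importance is deliberate: with hundreds of interchangeable co-informative
genes, permuting any single one leaves accuracy unchanged, so permutation
importance collapses to all-zero scores and would keep nothing; Gini
importance (the R randomForest default) distributes mass across redundant
predictors and the >-mean rule keeps roughly the most informative half.
`importance="permutation"` remains available for low-redundancy inputs.

Signature genes are consensus-clustered (same machinery, genes as items, on
z-scored profiles, default k 2–5).  Each gene cluster is scored per sample
by the first principal component of its z-scored block, with the PC1 sign
fixed so the loading sum is non-negative (prevents run-to-run sign flips);
z-scoring makes every score vector zero-mean.  Univariate Cox regression of
each cluster score labels it favourable (HR < 1) or unfavourable, and

    TME score = Σ favourable cluster scores − Σ unfavourable cluster scores.

The score formula's source text is ambiguous about what X and Y denote; both
are interpreted as per-sample gene-cluster signature scores partitioned by
prognostic direction, consistent with the gene-expression-grade-index method
the formula derives from.

The score is dichotomized at the maximally selected rank statistic:
candidate cutpoints are observed scores inside the 10–90% quantile range,
each split is scored by the standardized two-group log-rank statistic
(vectorized over all cutpoints), the argmax of |statistic| wins (ties to
the smaller cutpoint), and the p-value permutes scores against (time,
event) pairs — assumption-free and seedable, unlike the asymptotic
approximations the reference package offers.

## Survival statistics

Kaplan-Meier, the k-group log-rank test (hypergeometric variance,
simultaneous-event tie convention) and Cox proportional hazards (Breslow
ties, Newton-Raphson with step-halving, |Δ log-likelihood| < 1e-9 or 50
iterations) are implemented from first principles; lifelines is used in the
test suite as an independent oracle only.  The Cox score test at beta = 0
for a two-group covariate equals the log-rank chi-square exactly when event
times are untied (asserted to 1e-6); with ties the hypergeometric correction
makes the two differ slightly.  Monotone likelihood (perfect separation) is
detected by runaway coefficients/standard errors and flagged, with
estimates reported at the iteration cap.  Breslow rather than Efron ties:
simpler, and the difference is negligible at the cohort sizes involved.

The tumor-immune cell network reports, per cell type, the −log10 log-rank p
of a median abundance split (quantile configurable) signed risk/favourable,
and retains Spearman co-infiltration edges with |rho| >= 0.2 and p < 0.05.
ROC AUC uses the Mann-Whitney rank identity with midrank ties; paired AUC
comparison uses DeLong placement-value covariance.  The binary outcome for
ROC is caller-supplied (the synthetic generator's response flag by
default) — no claim is made about what "immunotherapy effect" should mean
on real data.

## Enrichment

Over-representation is a one-sided hypergeometric tail against any GMT
collection with BH correction across sets (GO hierarchies are deliberately
out of scope — a hallmark-style GMT is the interface, which removes any
live annotation-database dependency).  GSEA is the weighted (p = 1)
Kolmogorov-Smirnov running sum on a ranked list (default ranking:
signal-to-noise between two groups, the common default when the source
does not state one); p-values by gene-label permutation (cheap and
seedable; phenotype permutation is the documented alternative for small
cohorts), NES by mean |same-sign permuted ES|.

## Mutational signatures

SNVs are tallied into the canonical 96 trinucleotide categories (six
pyrimidine substitutions x 4 x 4 flanks; purine-reference records are
reverse-complemented, and collapsing is idempotent).  Extraction uses
automatic-relevance-determination NMF: KL-divergence likelihood,
half-normal column priors with per-signature relevance lambda_k under an
inverse-gamma(a = 10) hyperprior, multiplicative updates, tolerance 1e-7,
run from `n_restarts` random starts (default 100; the restart count is a
parameter) with the best posterior objective kept.  A component is dead
when its relevance collapses to the prior floor b/((F+N)/2 + a + 1); live
components (lambda > 2x floor) define k.  A penalty-free KL polish at the
selected rank then removes the small profile bias the half-normal prior
introduces — model selection and final profiles are decoupled.  A plain
KL-NMF per fixed k with an elbow rule is available as `--method plain`.
Cosine matching takes the argmax similarity against a reference matrix
(ties to the lowest reference index).  The bundled reference is a
synthetic stand-in for the COSMIC v2 catalogue (see
`src/tmepipe/data/README.md`); the real file drops in by path.  Exposure
clustering is K-means on column-normalized exposures with silhouette
selection of r.

APOBEC enrichment follows the TCW convention: over C>T and C>G mutations
(`--subs ct` restricts to C>T), E = (mut_TCW/mut_C)/(context_TCW/context_C),
where context counts census cytosines and TCW motifs on both strands of the
±20 bp windows around the included mutations; one-sided Fisher p on the
2x2 table; samples with E > 2 are "enriched".  A per-gene one-sided Fisher
test for overrepresentation of mutations among enriched samples (BH
corrected) accompanies the per-sample report.  TMB is the nonsilent
mutation count, reported raw and per exome megabase (default 38 Mb — a
conventional exome footprint; the definition is configurable because
upstream conventions vary).

## Copy-number scoring

Arm-level events require segments beyond ±1 covering >= 50% of the arm
(thresholds follow the caller-relative ±1 convention, preset `cn1`;
`--preset gistic` switches to ±0.3).  The focal statistic is GISTIC-like, not GISTIC: per
1-Mb bin, G_amp sums the positive values of supra-threshold overlapping
segments across samples (amplitude x implicit frequency), and the null
cyclically shifts each sample's per-bin profile along the genome — this
preserves per-sample event sizes and amplitudes while destroying
cross-sample alignment, replacing GISTIC2's marker-level semi-exact
background with something simpler, assumption-light and seedable.
Empirical p-values pool permuted scores across bins (the cyclic null is
exchangeable across bins), giving p resolution ~1/(n_perm x n_bins); BH
q-values; peaks are maximal runs of bins below the q threshold, each
reported with its maximal-G bin.  When several segments overlap one bin the
largest-|value| segment represents it, which makes G-scores invariant to
segment fragmentation.

## Pipeline and reproducibility

`tmepipe run` executes the stages in dependency order from one YAML config,
writing TSV outputs and a JSON manifest with per-stage output hashes, wall
times and seeds.  Stage seeds derive from the master seed by SHA-256 of
`"{stage}:{seed}"` (mod 2^31), so adding a stage never perturbs existing
ones; a rerun with the same seed reproduces every output hash.  Exit codes:
0 ok, 2 validation error, 3 stage failure (the failing stage is named and
partial outputs are preserved).

## Problem sizes in the test suite

The suite and the acceptance script run the stages at cohort sizes chosen
for a single-CPU desk run: recovery checks use 100–300 samples, consensus
resampling 60–1000 draws, NMF 5–10 restarts, and permutation nulls 100–1000
draws, as stated per test.  The statistical conclusions (recovery of
planted structure, oracle equalities, calibration of null p-values) are
size-stable: the same checks pass at larger sizes, only more slowly.

## Known limitations

* The deconvolution permutation null is shared across samples; per-sample
  nulls would be more faithful to the original tool at 1000x the cost.
* ARD-NMF model selection at very low mutation counts (< ~50 per sample)
  can split or merge signatures; the restart count and `--method plain`
  are the levers.
* The GISTIC-like null ignores marker-level correlation structure and
  arm-level/focal arbitration, so its q-values are honest for the planted
  synthetic model but not calibrated against GISTIC2 on real arrays.
* The maximally-selected-rank cutpoint is an interior argmax; when the true
  split sits in a flat region of the statistic, neighbouring order
  statistics are statistically indistinguishable, and the permutation p is
  the meaningful quantity rather than the exact cut.
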