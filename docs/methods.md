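# Methods

`methex` implements a differential-methylation and methylation–expression
analysis pipeline for targeted bisulfite-sequencing studies with a
two-factor design (genotype WT/KO × treatment saline/HDM), together with a
synthetic-data generator that reproduces the statistical structure such a
study presents to the analysis. This note records the models, the defaults
and their rationale, the numerical choices, and the known limitations.

## Adjacent-site clustering

CpG methylation is spatially correlated over short distances, so adjacent
sites are analyzed jointly. Sites are agglomerated bottom-up within each
chromosome: every site starts as a singleton, and an adjacent pair of
clusters is merged when

* the genomic gap between their nearest member sites is ≤ `max_gap_bp`
  (default 1000 bp), and
* the *minimum* Spearman correlation of per-site methylation proportions
  over all cross pairs of member sites (complete linkage) is ≥
  `corr_threshold`.

Merging sweeps left to right and repeats until no merge is possible; with
complete linkage a merge can never enable a previously failed upstream
merge, so a single stay-in-place sweep reaches the fixed point and the
result is deterministic. Clusters with fewer than `min_sites` (default 3)
sites are discarded. Correlations use only samples with depth ≥
`min_depth` (default 5) at both sites; pairs with fewer than 3 usable
samples are treated as uncorrelatable.

Spearman correlation was chosen over Pearson because methylation
proportions live on a doubly-bounded scale and the latent association is
monotone but nonlinear. The default `corr_threshold` is 0.3: at ~30×
coverage, binomial sampling noise attenuates a latent logit-scale
correlation of ~0.95 to an observed proportion-scale correlation of
roughly 0.4–0.6 (lower still for sites near 0 or 1), and complete linkage
takes a minimum over many noisy pair estimates. A threshold of 0.5 at this
depth fragments most genuine clusters; 0.3 recovers them while random
site pairs (null Spearman sd ≈ 0.16 at 40 samples) rarely pass. All four
parameters are exposed in the configuration.

## Cluster-level test: depth-weighted beta regression

Each cluster is summarized per sample by the pooled proportion
y_s = Σ_i m_is / Σ_i d_is with pooled depth D_s. The group comparison is a
beta regression in the mean–precision parameterization,

    y_s ~ Beta(μ_s φ, (1 − μ_s) φ),   logit(μ_s) = β0 + β1 x_s,

with the Smithson–Verkuilen shrinkage y′ = (y (n − 1) + 0.5)/n applied
first because the beta likelihood is undefined at 0 and 1. Read depths
enter as observation weights normalized to sum to the number of
non-missing samples, w_s = n D_s / Σ_t D_t, and the weighted
log-likelihood Σ_s w_s log f(y′_s; μ_s, φ) is maximized by L-BFGS-B over
(β, log φ) with an analytic gradient. Normalizing the weights keeps a fit
with equal depths exactly identical to the unweighted fit and keeps
standard errors on the footing of the true sample size; raw-depth weights
would conflate coverage with replication. Starting values come from
weighted least squares on logit(y′) and a method-of-moments precision;
log φ is bounded in [log 0.01, log 1e6].

The group test is a Wald test with the variance taken from the observed
information (numerical Hessian at the optimum; the β block of the inverse
is invariant to the log-φ reparameterization at a stationary point). Two
small-sample corrections are applied: the standard error is inflated by
√(n/df) with df = n − (k + 1) estimated parameters, and the statistic is
referred to Student-t with df degrees of freedom rather than the normal.
Without them the test rejects at ~9% for a nominal 5% at n = 20 (the
maximum-likelihood precision estimate is biased upward in small samples, a
known property of beta regression); with them the null calibration study
(2,000 simulated null clusters, 10 per group, depth 30) lands at ~5%.
Non-convergence and degenerate designs are reported conservatively as
p = 1 with a flag.

Multiple testing uses Benjamini–Hochberg step-up across all fitted
clusters (delegated to statsmodels); DMRs are called at adjusted p ≤ 0.10,
an inclusive boundary. The expression and cis stages use strict < at their
thresholds.

## Baseline subtraction, strain blacklist, subsets

DMRs from the treated contrast (KO_HDM vs WT_HDM) that are shared with the
saline baseline contrast — by ≥1 bp interval overlap *or* identical
nearest gene (the union of the two match criteria) — are flagged and
removed from the headline list while remaining in the full table. The
nearest gene is the gene with minimum distance from the cluster midpoint
to the gene body, ties broken lexicographically.

Incomplete backcrossing can leave a knockout line carrying a contiguous
block of the donor strain's genome, which produces spurious strain DMRs.
The blacklist detector slides windows (default 1 Mb window, 0.5 Mb step)
over a strain-informative SNP panel and flags windows where KO samples
match the alternate strain at rate ≥ 0.9 while WT samples match at ≤ 0.1;
overlapping flagged windows merge into maximal intervals, and any DMR
overlapping them is excluded. Requiring group specificity keeps shared
genotyping noise from triggering the detector.

Gene-subset analysis selects clusters within 25 kb (boundary inclusive,
gap measured between interval boundaries) of a supplied gene list and
re-applies BH within the subset only, so a focused hypothesis is not
penalized for the genome-wide test count.

## Annotation

Gene context is assigned by overlap with precedence promoter > 5′UTR >
3′UTR > exon > intron > intergenic; the promoter is 2 kb upstream of the
strand-aware TSS (configurable — the field has no single convention).
UTRs are exonic sequence outside the CDS, oriented by strand. Island
context comes from the boundary gap to the nearest CpG island: 0 →
island, 1–3000 bp → shore, > 3000 bp → distant. The 3000 bp shore band
matches the distance cutoff used in the summaries this pipeline produces;
the conventional 2 kb shore / 2–4 kb shelf bands are deliberately not
used.

## Expression stage

Raw intensities are transformed log2(x + 1) (offset configurable) and
quantile-normalized by the classical rank-mean procedure: sort each
sample, average across samples at each rank, assign rank means back by
original rank, ties receiving the mean of the rank means they span.
Per-probe contrasts use a genotype × treatment cell-means linear model:
the tested cell difference is a t-statistic with the residual variance
pooled within all occupied cells (df = n − #cells). When only the two
contrasted cells are present this reduces exactly to the classical pooled
two-sample t-test. BH runs across probes; probes significant in the
baseline (saline) contrast are flagged and excluded from the treated
contrast's headline list.

## cis methylation–expression scan

Clusters with an uncorrected treated-contrast p < 0.05 (strict) are paired
with every probe whose midpoint lies within 1 Mb of the cluster midpoint
on the same chromosome (midpoints avoid ambiguity for long features). For
each pair, cluster methylation is regressed on probe expression with
genotype as an additive covariate, reusing the depth-weighted beta
regression with a continuous predictor — methylation is the response,
expression the predictor, and the association is thereby adjusted for
knockout status. The scan runs on the treated (HDM) arm of both genotypes.
BH is applied across all tested pairs; pairs are significant at adjusted
p < 0.05 (strict). Enrichment statistics are exact binomial tails: excess
of negative (canonically anti-correlated) coefficients against 0.5,
excess of nominally significant pairs against the nominal rate, and the
two-sided sign balance among significant pairs. A Shapiro–Wilk normality
check of the coefficient distribution is logged as a descriptive statistic
and never used as a gate.

## Synthetic data generator

The generator plants known structure so every stage can be scored against
ground truth. Per site i (in cluster c) and sample s:

    logit(p_is) = b_i + σ (√ρ u_cs + √(1−ρ) e_is) + δ_c 1[s ∈ affected group]
    d_is ~ NegBin(mean 30, dispersion 0.3), floored at 1
    m_is ~ Binomial(d_is, p_is)

with u_cs a shared per-(cluster, sample) standard normal latent variable.
Defaults (the reference study conditions used by the tests and the
acceptance script): 10 samples per genotype × treatment cell, 1800 CpG
sites on one 50 Mb synthetic chromosome, 200 planted clusters of 3–8
sites (gaps 20–150 bp), within-cluster latent correlation ρ = 0.95 —
adjacent CpGs within ~150 bp are strongly correlated in real data —
between-sample biological noise σ = 0.5 logit units, per-site baseline
b_i = cluster baseline (N(0, 1)) plus N(0, 0.3) jitter.

Planted effects: 5 clusters carry a δ = 1.5 logit knockout effect under
HDM only, 2 under both treatments (baseline DMRs, which the subtraction
stage must remove), and 2 inside the contaminated block (which the
blacklist must remove); signs are random. Effect-bearing clusters draw
their baseline uniformly from logit 0.25–0.75 because a logit shift at a
baseline near 0 or 1 is invisible on the proportion scale — planted DMRs
are meant to emulate the detectable, intermediate-methylation DMRs a study
reports, not boundary artifacts. The noise level σ = 0.5 was likewise
chosen so that the realized group difference (sampling sd ≈ 0.2 around
1.5) stays reliably detectable at 10 per group, the regime the pipeline
is meant to emulate; mouse inbred cohorts are biologically homogeneous.

Expression: 300 probes at N(8, 1) log2 baselines with N(0, 0.4) noise,
written to disk on the raw intensity scale (2^v − 1) so the pipeline's
log2(x + 1) recovers them. 20 cis pairs attach probes (within ±400 kb) to
the effect-bearing clusters round-robin — those are the clusters a gated
scan can test — with slope ±8 log2 units per proportion unit, alternating
sign. Because the scan adjusts for genotype, only within-group methylation
variance (sd ≈ 0.12 in proportion units) carries the coupling, so ±8
yields a genotype-adjusted correlation of ~0.9: a strong, reliably
detectable meQTR. 20 DE probes carry a 1 log2-unit KO×HDM shift and 3 a
KO shift under both treatments. The SNP panel has one marker per 10 kb;
inside the planted 14 Mb contaminated block KO samples match the
alternate strain at rate 0.98, all others at 0.02.

The generator is deterministic given the seed (byte-identical files) and
is first-class, tested code.

### What the generator does not emulate

Real bisulfite data have bimodal (CpG-island vs gene-body) baselines,
strand effects, conversion errors, coverage that tracks capture-bait
design, and correlated depth between neighbouring sites; arrays have
probe-affinity and batch effects; none of these are modeled. Passing the
synthetic suite therefore demonstrates correctness of the algorithms and
calibration of the tests under the stated model, not robustness to every
artifact of real data.

## Problem sizes and calibration studies

The reference conditions were sized so the whole suite and the acceptance
script each run in about a minute: 1800 sites × 40 samples per run, 10
replicate runs for the mean false-discovery proportion, 2,000 null
clusters for type-I calibration, 200 clusters for effect recovery, and
100 random panels for the clustering oracle.

Effect recovery is evaluated at 25 samples per group. The boundary
shrinkage y′ = (y(n−1)+0.5)/n is not bias-free: it compresses proportions
toward 0.5, which at n = 20 attenuates the estimated group coefficient by
roughly 8% (more off-center). At n = 50 the attenuation falls to ~5% and
the mean estimate over 200 planted clusters is within 0.1 of the planted
1.0 logit effect. This estimator bias is a known limitation of the
shrinkage transform, not of the optimizer: the fitted likelihood dominates
a dense oracle grid to 1e−6 in every audit.

## Known limitations

* The Wald test's df correction calibrates the 5% level at n = 20; very
  small groups (2–3 per group) remain approximate.
* Depth weights model sampling precision only; when biological variance
  dominates (deep sequencing), weighting is close to neutral by design
  but the likelihood is still a working model, not exact.
* Complete-linkage clustering is conservative: one noisy site can split a
  genuine cluster; fragments of ≥3 sites are still tested.
* The cis scan tests marginal cluster–probe pairs; it does not model
  linkage among overlapping pairs or mediation.
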