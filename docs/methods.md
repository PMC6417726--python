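# Methods

This note documents the models behind each pipeline stage, the defaults
and why they were chosen, what the synthetic-data generator does and does
not emulate, and the numerical conventions a maintainer needs.

## Study design assumed throughout

Three bee species — two eusocial and one solitary — each sampled at three
developmental phases of adult cuticle maturation: pharate adult (Pbm,
pigmenting cuticle under the old pupal cuticle), newly emerged adult (Ne,
0 h) and forager (Fg, fully mature integument). Expression uses three
biological replicates per phase per species (9 libraries per species).
CHC profiling uses 15 individuals per phase for the eusocial species and
4/7/7 (Pbm/Ne/Fg) for the solitary one; one small-bodied eusocial species
is extracted in pools of 3 bees.

## Synthetic expression data

Counts are negative-binomial in the mean–dispersion form,
variance = μ + α·μ², matching the dispersion parameter of the Wald test
that consumes them. α = 0 degenerates to deterministic counts (the
rounded class mean), which gives exact zero-noise recovery tests.
Defaults: baseline mean 500 per gene (no between-gene baseline spread, so
planted fold changes are exactly the configured multiplier), dispersion
0.1, fold change 4.

Each gene belongs to one planted profile class:

| class | eusocial A | eusocial B | solitary |
|---|---|---|---|
| `eusocial_heterochronic` | shape *s* | shape *s* | fc/*s* (anti-correlated) or flat |
| `all_shared` | shape *t* | shape *t* | shape *t* |
| `solitary_shifted` | flat | flat | emergence-peaked |
| `species_specific` | young-peaked | emergence-peaked | forager-peaked |
| `flat` | flat | flat | flat |

Shapes come in mirrored variant pairs — a base shape *s* and its
elementwise mirror fc/*s*, alternating within each class — because real
integument data contains genes upregulated in the young phases
(structural cuticle proteins, chitin machinery) *and* genes upregulated
in foragers (odorant-binding proteins, P450s, antioxidants). Mirroring
also keeps per-phase library composition balanced, which makes global
normalization identifiable; with one-directional planting at a large DE
fraction, no library-size normalization can separate depth from
composition.

Default class fractions (0.25 / 0.15 / 0.15 / 0.15 / 0.30) emulate the
curated cuticle-development ortholog universe on which the pattern
classification operates — such curated sets are pattern-rich (roughly a
quarter of genes carrying the eusocial-shared signature) — not
transcriptome-wide DEG rates, which are an order of magnitude lower. DE
error-control simulations configure their own mixes (pure null, or 10%
planted four-fold genes).

A configurable fraction (default 5%) of solitary-species orthologs is
absent from the map (rows blanked, counts untouched), emulating
transcripts not identified in the solitary assembly.

What the generator does **not** emulate: per-gene baseline heterogeneity,
gene length (so the abundance floor is CPM-like rather than true FPKM),
batch effects, correlated genes outside the planted classes, isoforms,
and mapping noise. Passing tests therefore demonstrate correctness of the
estimators under the declared statistical model, not robustness to every
artifact of real libraries.

## Normalization

`normalize(..., method="cpm")` is plain counts-per-million.
`ExpressionStudy` defaults to `method="median_ratio"`: median-of-ratios
size factors (per sample, the median over all-positive genes of
count/geometric-mean), rescaled so the mean normalized library is 10⁶,
keeping values on a CPM-like scale. Total-count scaling is biased
whenever expression change is asymmetric across phases; the
median-of-ratios estimator is robust as long as no single phase has a
majority of genes changed in one direction — the same reason the
reference DE tools (DESeq2, edgeR, Cuffdiff) never normalize by raw
totals. Both modes are depth-scale-invariant.

## Differential expression

Per gene and phase pair, on normalized abundances:

- **nb_wald** — group means μ̂_A, μ̂_B; pooled method-of-moments
  dispersion α̂ = max(0, (s̄² − μ̄)/μ̄²) (floored at zero, as printed);
  delta-method Wald statistic on the log fold change with
  Var(log μ̂) = (μ + αμ²)/(nμ²); means floored at 0.5 so one-sided-zero
  genes stay testable. Two-tailed normal p.
- **rank_perm** — exact permutation over all C(6,3) = 20 replicate
  relabelings of the absolute mean difference; the observed labeling is
  included, so p ≥ 0.05 at three replicates per group. Consequently
  `method="both"` (p = max of the two, the two-package intersection rule)
  cannot reach q < 0.05 at n = 3 and is intended for designs with more
  replicates; the q-based criteria are evaluated with `nb_wald`.
- BH adjustment across genes within a comparison; all-zero genes are
  reported untestable with p = 1.

Filtering is boundary-inclusive exactly as published: q < 0.05,
|log₂FC| ≥ 1, max per-phase mean ≥ 5. log₂FC uses a pseudo-count of 1 on
the normalized means; its sign convention is log₂((mean_B+1)/(mean_A+1))
for comparison "A vs B", and `direction` names the phase with the larger
mean, always consistent with the sign. The abundance floor applies to the
larger of the two phase means so a gene expressed in only one phase
remains callable.

The method-of-moments dispersion at n = 3 is noisy (no shrinkage is
applied, by design — the estimator is the documented contract), which
costs a few percent of sensitivity relative to moderated estimators;
planted 4-fold genes at mean 500 and dispersion 0.1 are still recovered
at ≥ 90% sensitivity while a pure-null simulation passes the full filter
at well under 1%.

## Bootstrap cluster support

Complete-linkage agglomeration on either correlation distance (1 − r,
range [0, 2]) or Euclidean distance; items are samples (expression) or
individuals (CHC percent profiles), features are genes or compounds.
Support comes from feature resampling only — items are never resampled:

1. For each scale ρ in 0.5, 0.6, …, 1.4, draw B feature-bootstrap
   replicates of size round(n·ρ) and recluster; count how often each
   observed node's exact leaf set reappears, giving BP(ρ).
2. Fit Φ⁻¹(1 − BP(ρ)) = v·√ρ + c/√ρ by weighted least squares (binomial
   variance weights) over scales with 0 < BP < 1; frequencies of exactly
   0 or 1 are clipped to 1/(2B), 1 − 1/(2B) when fewer than two interior
   scales exist.
3. AU = 100·(1 − Φ(v − c)); BP is reported as the raw frequency at ρ = 1.

Degenerate nodes resolve without a fit: contained in every replicate at
every scale → AU = 100 (the probit fit of a clipped constant would
otherwise report a meaninglessly small AU for a perfectly supported
cluster); never contained → AU = 0. The root always has BP = AU = 100.
Cluster identity across trees is the exact leaf set. AU > 95 is the
significance convention; on exchangeable random data the per-node rate of
AU ≥ 95 stays near the nominal few percent.

The replication default in `run-all` is 10,000 total bootstrap
replicates, divided over the 10-scale grid (1,000 per scale); per-scale
10,000 is available through the API for a full-strength analysis.
Expression trees are built on the DEG-subset matrix; CHC trees on
Euclidean distances between percent profiles.

## Ortholog profile correlation

Profiles are the 9 normalized abundances ordered Pbm, Ne, Fg with
replicates sorted within phase; species are paired by (phase, replicate
index). Replicate-level pairing is deliberate: with only 3 phase means,
p ≤ 0.1 two-tailed would demand |r| ≥ 0.988, incoherent with an r ≥ 0.6
threshold, whereas at n = 9 the p ≤ 0.1 bound corresponds to |r| ≈ 0.582,
just below the r gate — the two filters are mutually consistent.
Phase-mean pairing (n = 3) remains available.

A pair *passes positively* iff r ≥ 0.6 and p ≤ 0.1 (inclusive);
everything else — significant negative included — counts as
"negatively or non-correlated". Labels: eusocial pair passes and both
solitary pairs do not → `EUSOCIAL_SHARED`; eusocial pair passes with the
solitary member absent → `EUSOCIAL_SHARED_SOLITARY_ABSENT`; all three
pass → `ALL_SHARED`; exactly one solitary-containing pair passes while
the eusocial pair does not → `AM_CA_SHARED` / `FV_CA_SHARED`; otherwise
`NONE`. A present pair whose profile is constant (zero variance) is a
fail, not an absence. The label is a pure function of the three
pass/fail/absent states, tested exhaustively.

Under the null at n = 9, a pair passes with probability ≈ 0.044, so a
truly flat ortholog escapes `NONE` about 12% of the time — an intrinsic
property of the published thresholds, visible in the label counts.

## Co-expression networks

All gene pairs over all 9 samples (phases pooled, one network per
species); edge iff |r| ≥ 0.95 and p ≤ 0.05, both inclusive, sign
recorded. No multiple-testing correction — at n = 9 the r-floor is by far
the binding constraint. Constant genes are dropped with a warning.
Intersection maps both endpoints through the ortholog table and requires
the mapped edge to exist with the same sign (a flag relaxes the sign
match); the result is symmetric under argument exchange up to
relabeling.

## CHC quantification

Relative profiles: per individual, percent of summed peak area, over all
compounds or within each class (n-alkanes, unsaturated, methyl-branched)
with the denominator restricted accordingly.

Absolute amounts: per n-alkane standard (C23, C25, C32), ordinary least
squares of known amount (µg/ml, levels 1.25–20) on the analyte/internal-
standard area ratio gives amount = a·ratio + b with correlation R; a fit
is acceptable at R ≥ 0.99. Compounds are assigned a curve by carbon
number — up to C24 → C23; C25–C29 → C25; above C29 up to C35 → C32;
outside C20–C35 no curve is assignable and the compound is rejected. The
predicted extract concentration is scaled by the resuspension volume
(default 160 µl; 100 µl for the pooled species) and divided by the pool
size (3 for the pooled species) to give µg per bee. Negative predictions
(area below the calibration blank) are clamped to zero, flagged
`below_quantification`, and warned about rather than silently dropped.
The internal-standard area ratio is the default response; a raw-area mode
exists. The calibration equation is implemented as conventional
internal-standard calibration (regress known amount on area ratio,
predict unknowns from the fitted line).

Synthetic CHC data inverts the true calibration exactly, so zero-noise
data round-trips to the planted amounts at machine precision, and 2%
multiplicative noise yields mean absolute relative error under 5%. The
eusocial default amounts follow the late-maturation pattern (n-alkane
class totals ≈ 9 / 7.5 / 18 µg across Pbm/Ne/Fg, unsaturated strongly
forager-enriched); the solitary defaults rise between Pbm and Ne and then
plateau (early maturation), so the solitary Euclidean tree — like the
real one — does not strongly support a forager cluster, while the
eusocial trees do.

## Thickness statistics

Exactly two phases → Student's t (pooled variance), regardless of
normality. Three or more → a single Shapiro–Wilk gate on pooled
per-phase-demeaned residuals (one gate rather than per-group tests, since
the branching decision is per dataset): p ≥ α → one-way ANOVA with
Tukey's HSD; p < α → Kruskal–Wallis (midranks, tie-corrected H) with the
Conover–Iman post hoc — t statistics on rank means with the pooled rank
variance S² scaled by (N−1−H)/(N−k) on N−k df — and Bonferroni correction
applied to the pairwise p-values only. All branches emit a compact-letter
display (insert-and-absorb; letters ordered by group order) that
reproduces the pairwise significance matrix exactly.

## Pipeline and problem sizes

`run-all` simulates 2,000 genes × 3 species, classifies DEGs for all
three phase pairs, builds AU/BP trees for the DEG subsets and the three
CHC datasets at 1,000 replicates per scale, classifies all orthologs,
builds 40-gene co-expression networks with pairwise intersections, and
runs the thickness decision tree per species — a few tens of seconds on
one core, deterministic to the checksum under a fixed seed. Stage
failures for one species are reported as warnings without aborting the
rest; the report records outputs, counts, versions and the seed.

## Known limitations

- The NB Wald test is anticonservative at very small replicate numbers
  (normal reference for a noisy dispersion estimate); the published
  fold-change and abundance floors keep realized null leakage low, but
  raw p-values near the threshold should not be over-read.
- The permutation route is resolution-limited at n = 3 (p ≥ 0.05).
- AU values for nodes observed at only a couple of interior scales rest
  on a clipped two-parameter fit and are less reliable than
  well-populated fits; they are flagged via `n_scales`.
- Compact letters are a display of pairwise decisions; with
  non-transitive significance patterns groups can carry multiple letters.
- The CHC stage models peak tables, not chromatograms: co-elution,
  baseline drift and identification errors are out of scope.
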