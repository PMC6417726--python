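# cuticula

Comparative analysis of **adult cuticle maturation timing in bees**. In
eusocial species, workers stay protected inside the nest for days after
emergence and their exoskeleton finishes melanizing and sclerotizing as
adults; solitary bees leave the nest immediately and must emerge with a
mature cuticle. This heterochrony — a shift in developmental timing
between taxa — leaves detectable signatures in integument transcriptomes,
cuticular hydrocarbon (CHC) profiles, and cuticle thickness across three
developmental phases: pharate adult (**Pbm**), newly emerged (**Ne**) and
forager (**Fg**).

`cuticula` implements the full comparative workflow as a tested, reusable
pipeline for a three-species design (two eusocial, one solitary, three
replicates per phase), together with a seeded synthetic-data generator
that emulates the study's structure with planted ground truth, so every
stage is verifiable without external data:

- **Differential expression** — per-gene negative-binomial Wald test
  (method-of-moments dispersion) and/or exact label-permutation test,
  BH-adjusted, filtered at q < 0.05, |log₂FC| ≥ 1 and an abundance floor
  of 5; upregulation Venn partitions and two-proportion z-tests between
  species.
- **Bootstrap-supported clustering** — complete linkage on correlation
  (1 − r) or Euclidean distances with multiscale-bootstrap support: per
  node, the bootstrap proportion BP and the approximately unbiased
  probability AU from the fit Φ⁻¹(1 − BP(ρ)) = v·√ρ + c/√ρ,
  AU = 1 − Φ(v − c); clusters with AU > 95 are significant.
- **Ortholog profile correlation** — each ortholog trio is classified by
  which species pairs share a positively correlated expression profile
  (Pearson r ≥ 0.6 and p ≤ 0.1 over 9 replicate-paired values); the
  heterochrony signature is a eusocial-pair match that the solitary
  species does not share.
- **Co-expression networks** — edges at |r| ≥ 0.95 and p ≤ 0.05 over all
  9 samples, signed; cross-species common interactions through an
  ortholog map (SIF export).
- **CHC quantification** — percent-of-total profiles, internal-standard
  calibration (amount = a·(area/IS area) + b per C23/C25/C32 n-alkane
  standard over a 1.25–20 µg/ml series), carbon-number curve assignment,
  µg-per-bee absolute amounts with pool correction, ANOVA + Tukey HSD
  letters, and PCA loadings.
- **Cuticle thickness** — a test decision tree (Student's t for two
  phases; Shapiro–Wilk gate on residuals choosing ANOVA/Tukey vs
  Kruskal–Wallis/Conover–Iman with Bonferroni) with compact-letter
  display.

## Worked example

Calibrate a synthetic GC-MS standard series and quantify CHCs per bee:

```python
from cuticula import ChcSimConfig, generate_chc, fit_calibration, absolute_quantify
from cuticula.chc import class_totals, per_class_phase_test

cfg = ChcSimConfig(seed=1)           # 15 bees per phase, 10% peak noise
peaks, standards, truth = generate_chc(cfg)
curves = fit_calibration(standards)
for k, c in sorted(curves.items()):
    print(f"{k}: amount = {c.slope:.4f} * ratio + {c.intercept:.4f}   (R = {c.r:.4f})")

quant = absolute_quantify(peaks, curves, cfg.pool_size, cfg.extract_volume_ul)
totals = class_totals(quant)
print(totals.groupby(["compound_class", "phase"])["ug_per_bee"].agg(["mean", "std"]).round(2))
for cls, pl in per_class_phase_test(totals).items():
    print(cls, dict(pl.letters))
```

prints

```
C23: amount = 2.0371 * ratio + 0.0008   (R = 0.9997)
C25: amount = 2.2115 * ratio + 0.0675   (R = 0.9995)
C32: amount = 2.4462 * ratio + 0.1928   (R = 0.9993)
                       mean   std
compound_class phase
n_alkane       Fg     18.34  0.69
               Ne      7.50  0.24
               Pbm     8.99  0.23
unsaturated    Fg      6.56  0.37
               Ne      0.91  0.04
               Pbm     0.62  0.02
n_alkane {'Fg': 'a', 'Ne': 'b', 'Pbm': 'c'}
unsaturated {'Fg': 'a', 'Ne': 'b', 'Pbm': 'c'}
```

The fitted calibration lines recover the planted slopes with R ≥ 0.999
(the quality bar for accepting a curve is R ≥ 0.99). Foragers carry about
18 µg of n-alkanes per bee versus 8–9 µg in the earlier phases, and the
compact letters mark the forager phase as significantly different — the
late-maturation signature of a eusocial species.

Classifying ortholog expression profiles on synthetic data with 10%
noise (planted classes: 25% eusocial-shared, 15% all-shared, 30% flat, …):

```python
from cuticula import ExpressionSimConfig, generate_expression, classify_orthologs, pattern_summary

studies, omap, truth = generate_expression(ExpressionSimConfig(n_genes=1000, dispersion=0.008, seed=5))
print(pattern_summary(classify_orthologs(omap, studies)))
```

```
{'EUSOCIAL_SHARED': 250, 'EUSOCIAL_SHARED_SOLITARY_ABSENT': 27,
 'AM_CA_SHARED': 18, 'FV_CA_SHARED': 21, 'ALL_SHARED': 140, 'NONE': 544}
```

All 250 planted eusocial-heterochronic orthologs with a solitary member
are recovered, plus the 27 whose solitary ortholog was dropped from the
map.

## Command line

```bash
cuticula simulate expression --seed 1 --out sim/
cuticula deg --matrix sim/eusocialA_counts.tsv --meta sim/eusocialA_meta.tsv
cuticula cluster --matrix sim/eusocialA_counts.tsv --metric correlation --boot 10000 --seed 1
cuticula run-all --seed 1 --out run/
```

`run-all` executes every stage on a fully synthetic study and writes a
machine-readable `run_report.json` with per-stage results and a checksum
for every output file; reruns with the same seed are byte-identical.

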