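# varprio

Pathogenicity-predictor benchmarking and pedigree-aware variant
prioritization for whole-genome sequencing (WGS) studies of rare Mendelian
disease, developed around the discovery workflow used in inherited retinal
dystrophies (IRD).

WGS of an undiagnosed family yields millions of single-nucleotide variants;
the bottleneck is deciding which in-silico deleteriousness filters to apply
and at which thresholds. `varprio` implements the three ingredients of a
data-driven answer:

1. **Cutoff re-calibration.** Given a curated table of pathogenic-like and
   benign-like variants scored by *k* prediction tools, each tool's scores
   are harmonized to a higher-is-risk convention and a ROC curve is built
   per tool under per-tool deletion of missing values. The area under the
   curve is the Mann–Whitney statistic
   AUC = P(X_path > X_benign) + ½ P(X_path = X_benign),
   with variance and paired tool-vs-tool comparison by DeLong's
   structural-components method. Three operating points are offered:
   Youden's *J* = max(Se + Sp − 1), the Se = Sp crossing, and the strictest
   threshold with sensitivity ≥ 90% (the default — it bounds the
   false-negative rate of a discovery filter).
2. **Combination filter models.** Conjunctions of single-tool filters with
   pass-if-missing semantics ("score ≤ c or missing") are enumerated or
   read from a configuration file, scored by TP/FP/missing rates on the
   labeled table, and ranked under quality criteria
   (TP ≥ 85%, FP ≤ 35%, missing ≤ 30%), preferring the lowest FP rate.
3. **The discovery cascade.** A multi-sample VCF plus 6-column PED flows
   through: recurrence filtering against unaffected pseudo-controls,
   multiallelic-site removal, gnomAD frequency filtering (MAF ≤ 0.01 or
   absent), a non-splicing branch (CADDv1.6 ≥ 22.25 gate, then lenient
   MAPP/Grantham/SIFT), a splicing branch (SpliceAI max ΔS ≥ 0.405 gate,
   then lenient NNSplice), a ClinVar rescue lane for (likely) pathogenic
   entries, branch union, and pedigree filtering under AR-homozygous,
   compound-heterozygous, AD or X-linked models, with a per-stage survivor
   trace. Structural variants get the matching CNV filters (REFCN:CN
   genotype codes, ≤3-carrier recurrence, MAF ≤ 0.01, exonic overlap) and
   MEI quality/recurrence filters, and candidate genes can be checked
   against a LOEUF constraint cutoff derived from disease-vs-control gene
   ROC analysis.

Every statistical primitive is also exposed as a scikit-learn-style
estimator (`CutoffClassifier`, `ComboClassifier`) for use in pipelines and
cross-validation, and a synthetic-data module generates all inputs (score
tables, cohort VCF/PED/annotations, SV sets, gene lists) with known ground
truth.

## Worked example

Simulate a seven-family discovery cohort (14 genomes, one planted causal
homozygous variant) and a 942-variant training table, re-calibrate cutoffs,
and run the cascade for the consanguineous index family:

```bash
varprio simulate  --out-dir demo --seed 7 --n-background 300
varprio benchmark --scores demo/scores.tsv --strategy sens90 --out demo/cutoffs.json
varprio run --vcf demo/cohort.vcf --ped demo/cohort.ped --ann demo/annotations.tsv \
            --family FamA --mode ar --consanguineous \
            --out demo/candidates.tsv --trace demo/trace.json
```

`benchmark` writes one entry per tool; on this simulated table, e.g.

| tool | AUC | cutoff | %FP | %missing |
|---|---|---|---|---|
| CADDv1.6 | 0.893 | ≥ 22.294 | 31.51 | 0.0 |
| SpliceAI | 0.980 | ≥ 0.484 | 5.17 | 10.1 |
| SIFT | 0.716 | ≤ 0.134 | 60.20 | 43.1 |

i.e. at 90% sensitivity the simulated CADDv1.6 cutoff lands near the
configured 22.25 while single conservation/protein tools keep unacceptably
high FP rates — the motivation for combination filters.

`run` logs the per-stage survivor counts as JSON lines:

```
{"event": "stage", "stage": "input", "survivors": 315}
{"event": "stage", "stage": "recurrence", "survivors": 297}
{"event": "stage", "stage": "multiallelic", "survivors": 274}
{"event": "stage", "stage": "frequency", "survivors": 175}
{"event": "stage", "stage": "nonsplicing-branch", "survivors": 1}
{"event": "stage", "stage": "pedigree-AR-hom", "survivors": 1}
```

and `demo/candidates.tsv` contains the single surviving candidate — the
planted homozygote (here given the annotations of a real IRD candidate
variant in *CFAP20*):

```
chrom  pos       ref alt gene    gnomad_af  provenance   score_CADDv1.6 ...
16     58150000  C   T   CFAP20  1.21e-05   nonsplicing  29.5
```

The same steps are available as library calls (`varprio.run_cascade`,
`varprio.roc_curve`, `varprio.cutoff_at_sensitivity`, ...); see the module
docstrings and `docs/methods.md` for the underlying models and conventions.

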