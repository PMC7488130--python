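# gmiec

Per-patient multi-omics gene-module identification and drug mapping, after
the GMIEC approach to genomics-guided precision medicine.

Precision oncology asks, for one patient at a time: which group of genes is
jointly altered — up-regulated, copy-amplified, hypomethylated, mutated —
and is any of those genes the target of a known drug? `gmiec` answers this
by integrating two or more omics matrices (gene expression, copy number,
methylation, mutation status) **per patient**, clustering the chosen gene
set into *gene modules* (GMs) of genes sharing common genomic features,
attaching *drug modules* (DMs) from a gene–drug association table, scoring
every module, and automatically selecting each patient's most activated (or
most suppressed) druggable module.

## Method

For each patient *i* of the individual vector *I*, the omics layers are
sliced into a matrix **M**ᵢ = (G × m) — rows the gene set G, one column per
omics layer. Two clustering strategies are implemented:

* **M1 — unsupervised random-forest proximity + k-means.** A classification
  forest separates the real gene rows from a synthetic class built by
  independently permuting each column of **M**ᵢ (Breiman's
  product-of-marginals device). The gene–gene *proximity* is the proportion
  of trees in which two genes land in the same terminal node; k-means on
  the proximity rows yields the modules. The number of modules k can be
  fixed or chosen by silhouette analysis.
* **M2 — logic rules + k-modes.** Crisp threshold rules (over/under-
  expressed by within-patient z-score, copy gain/loss at ±0.3, hyper/hypo-
  methylation at beta 0.7/0.3, mutated at count ≥ 1) binarize **M**ᵢ into a
  gene × rule matrix; only rules whose layer was provided are applied.
  Huang k-modes (Hamming dissimilarity, per-column modes) groups genes with
  the same alteration pattern.

Each module is then scored: `score_genes` (mean of the binary rule matrix
over the module — alteration density), `score_drugs` (fraction of module
genes with ≥ 1 associated drug), and the signed **S-score** in [−1, 1] —
mean of activating rule sub-scores minus mean of suppressing ones. The
selection step picks, per patient, the extremal-S-score module among those
meeting a drug-count constraint: **AOMD** (active oncogenic module with
drugs) when the score is strictly positive, **IOMD** for the suppressed
direction, **AOM** otherwise.

A synthetic-cohort generator plants known module structure (one activated,
one suppressed, one neutral module per patient) across all four layers so
every stage can be validated by parameter recovery (adjusted Rand index)
without external data.

## Worked example

`examples/04_score_select_report.py` runs the full pipeline on a simulated
10-patient, 60-gene cohort (strong effect, 3 modules, seed 11):

```
patient   score  category  genes  drugs
P001  +0.750  AOMD        19  12
P002  +0.603  AOMD        17  14
...
P010  +0.647  AOMD        17  4

cohort counts: {'AOMD': 10, 'AOM': 0, 'IOMD': 0, 'none': 0, 'AOM_with_drug': 0}
```

Each row is one patient's selected module: an S-score of +0.75 means the
activating alteration signals dominate the suppressing ones by 75 points of
rule-pass fraction; `AOMD` says the module also carries at least one drug —
here all 10 planted activated-druggable modules were found. The other
examples show the simulator (`01`), the forest-proximity strategy (`02`,
ARI 1.0 against the planted truth on its seed), the rule/k-modes strategy
(`03`), and BED-region-to-gene mapping (`05`).

The same pipeline is available from the shell:

```sh
gmiec simulate --patients 10 --genes 60 --modules 3 --effect strong --seed 7 --out-dir cohort/
gmiec analyze --method m2 --k 3 --seed 7 \
    --expression cohort/expression.tsv --copy-number cohort/copy_number.tsv \
    --methylation cohort/methylation.tsv --mutation cohort/mutation.tsv \
    --drugs cohort/drugs.tsv --out-dir run/
gmiec select --results run/results.tsv --direction active --min-drugs 1 --out run/selection.tsv
gmiec report --results run/results.tsv --selection run/selection.tsv --out run/report.html
```

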