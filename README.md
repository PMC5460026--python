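# sigrobust

Benchmarking gene-expression signatures against stromal intratumoural
heterogeneity in multi-region tumour profiling.

## The problem

Transcriptional signatures are used to assign cancer patients to
prognostic/predictive subtypes from a single piece of tumour tissue.  But
bulk expression mixes cancer-cell (epithelial) transcripts with
fibroblast, leukocyte and endothelial transcripts, and the stromal mix
varies strongly with *where* the tissue was taken — the invasive front of
a colorectal tumour is far more fibroblast-rich than the central tumour,
and a lymph-node metastasis is leukocyte-rich.  A signature that leans on
stroma-derived genes can therefore classify the *region* that was sampled
rather than the *patient*, which is fatal for clinical use.

`sigrobust` quantifies this failure mode.  Given a cohort of patients
profiled at multiple regions (central tumour CT, invasive front IF,
lymph-node metastasis LN) and a signature gene list, it measures whether
samples group by patient-of-origin or by region-of-origin, and attributes
the signature's genes to their cellular compartment of origin.  A
synthetic multi-region generator with planted patient-intrinsic and
stromal signal makes every stage testable with no external data.

## The statistics

For a signature *S* and the expression matrix restricted to *S* (rows
median-centred, Euclidean distances between samples):

* **DIANA patient clade concordance** — divisive hierarchical clustering
  (largest-diameter cluster split by the splinter-group procedure, split
  height = cluster diameter).  Patient *p* is *concordant* iff the
  smallest clade containing all of *p*'s samples contains no other
  patient's samples; the score is the concordant fraction.
* **Normalized patient similarity** — with *r(s,t)* the Pearson
  correlation of two samples' signature profiles,
  `s_p = mean r(within-p pairs) − mean r(p-vs-others pairs)`,
  summarized by the cohort median.  0 means no within-patient excess
  correlation; 1 is the perfect-within / null-between limit.
* **PGOR** (patient group overall ratio) — cut the Ward dendrogram into
  k = 1..n_patients groups;
  `PGOR_k = (# patients with all samples in one cluster) / (# patients)`.
  Cuts are nested, so the curve starts at 1 and never increases.
* **NTP** (nearest template prediction) — subtype calls by minimal cosine
  distance to binary marker templates, with resampling p-values
  (`p = (b+1)/(n+1)` over random same-size gene sets) and
  Benjamini–Hochberg FDR gating at 0.2; cross-region call concordance is
  tabulated per patient.
* **Compartment attribution** — per-gene median expression in flow-sorted
  epithelial / fibroblast / leukocyte / endothelial reference profiles;
  a signature's dominant compartment is the median-of-medians argmax,
  with a one-way ANOVA across compartments.

## Worked example

```python
from sigrobust import SimulationParams, evaluate_signature, simulate_multiregion

data = simulate_multiregion(SimulationParams(seed=1))   # 1000 genes x 72 samples
for comp in ("epithelial", "fibroblast"):
    res = evaluate_signature(data.matrix, data.annotation, data.signature(comp))
    print(comp,
          f"concordance={res['concordance_full'].fraction:.2f}",
          f"similarity={res['similarity'].median:+.3f}",
          f"PGOR(k=24)={res['pgor'].at(24):.2f}")
```

prints

```
epithelial concordance=1.00 similarity=+0.943 PGOR(k=24)=1.00
fibroblast concordance=0.00 similarity=-0.028 PGOR(k=24)=0.00
```

i.e. a signature of patient-intrinsic (epithelial) genes keeps every
patient's three regional samples together at every level of stringency,
while a stromal (fibroblast) signature never does — its samples cluster
by region instead.  The scripts in `examples/` walk through each
capability (simulation, clustering/concordance, similarity/PGOR, NTP
subtyping, compartment attribution); `sigrobust demo --seed 1` runs the
whole pipeline from the shell, and `sigrobust evaluate` applies it to
your own TSV/CSV inputs (see `sigrobust --help`).

Applied to the deposited multi-region colorectal cohort (GEO GSE95109,
with the GSE39396 sorted-compartment reference and published signature
gene lists), the same pipeline reproduces the contrast between
stroma-dominated signatures (0% patient concordance for a 30-gene
CT-vs-IF classifier) and cancer-cell-intrinsic ones (92% for CRIS,
similarity medians up to 0.73 for Popovici, ~75% PGOR at k = 24).

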