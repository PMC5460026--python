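# Methods

## Study design the package models

A multi-region expression cohort: each patient contributes one bulk
profile per region — central tumour (CT), invasive front (IF) and
lymph-node metastasis (LN) — on a log2 intensity scale.  The scientific
question is whether a given signature's expression groups these samples by
patient-of-origin (desirable: the signature reads cancer-cell-intrinsic
biology) or by region-of-origin (the signature reads the stromal/immune
composition of the sampled site).  The default configuration mirrors a
24-patient, 72-sample design with patients labelled A–Y (M excluded), and
the closed region vocabulary CT/IF/LN (extensible per run).

## Preprocessing

Signature symbols are mapped onto the platform through an HGNC-style
alias table in a fixed order — exact (case-insensitive) match, previous
symbol, alias, Entrez id — with unmatched symbols reported as dropout
rather than silently lost; ties between approved symbols sharing an alias
go to the lexicographically smaller symbol and are logged.  Probe-level
matrices are collapsed to genes by the per-sample **median** across a
gene's probes (mean available by flag); probe-level analysis remains
possible by passing the probe-level matrix directly.  Before clustering,
each row is **median-centred** (shift only, no variance scaling; an
optional `scale` flag divides by the row SD for sensitivity analyses).
Matrices are assumed log2; `log2_transform` applies log2(x+1) to
linear-scale inputs.

## Clustering

Distances are Euclidean between sample columns over the signature genes.

**DIANA** (divisive analysis) is implemented from first principles: the
cluster with the largest diameter is split by seeding a splinter group
with the object of maximal average dissimilarity to its cluster-mates,
then repeatedly moving the object whose average dissimilarity to the
remainder most exceeds its average dissimilarity to the splinter group,
until no object prefers the splinter side.  Split height = the diameter
of the divided cluster, which makes heights monotone along the division
sequence.  All ties (cluster choice, seed, move candidate) break to the
lowest input index so runs are reproducible; the divisive coefficient
(mean over objects of 1 − d(i)/diameter(all)) is reported.

**Ward** clustering uses the Lance–Williams recurrence on squared
Euclidean distances, with merge heights recorded as the square root of
the updated squared distance (the "ward.D2" convention, matching scipy).
This choice matters because "Ward" implementations differ on whether the
recurrence sees squared or raw dissimilarities; the test suite pins the
convention against a naive implementation that recomputes the
increase-in-ESS criterion from coordinates at every step.

Divisive trees are stored with their splits reversed into merges, so both
tree kinds share one representation with non-decreasing merge heights.
**Cutting** into k groups uniformly undoes the last k−1 merges — the k−1
highest merges for Ward, the k−1 largest-diameter splits for DIANA — so
cuts are nested (the k+1 clustering refines the k clustering), which is
what makes the PGOR curve monotone.  Trees serialize to Newick with
branch lengths = parent height − child height.

DIANA runs on median-standardized signature matrices by default, matching
the rest of the pipeline; a `standardize_diana=False` flag reproduces
raw-intensity divisive clustering for comparison with implementations
whose defaults skip standardization.

## Robustness statistics

* **Patient clade concordance**: patient p is concordant iff the smallest
  clade containing all of p's samples is patient-pure.  This is the
  strictest reading of "clusters by patient" and yields the structural
  extremes (0% for a purely region-driven signature, ~100% for a purely
  patient-driven one).  Computed on the DIANA tree by convention; both
  tree kinds are accepted.
* **Normalized patient similarity**: s_p = mean Pearson correlation over
  p's within-patient sample pairs minus the mean correlation between p's
  samples and all other patients' samples, with the between-average
  pooled over (sample-of-p, sample-not-of-p) pairs.  The definition is
  anchored at 0 (no within-patient excess) and 1 (perfect within, null
  between); its exact range is [−2, 2].  Under patient-label permutation
  the per-patient score is mean-unbiased; note that the per-shuffle
  *median* sits slightly below zero when the underlying data carry strong
  within-patient structure, because the null score distribution is then
  right-skewed (a randomly composed "patient" occasionally captures a
  genuinely matched sample pair).  This median-vs-mean offset is ~0.003
  in the default configuration, two orders of magnitude below the signal
  score, and is asserted in the test suite.
* **PGOR**: computed on the Ward tree per the hclust/cutree convention,
  for k = 1..n_patients.  Monotone non-increasing by cut nesting; the
  curve's value at k = n_patients coincides with clade concordance
  whenever every patient's samples form equally-sized pure clades.

## NTP subtype classification

Templates are binary vectors over the union of the classifier's marker
genes (a gene labelled for several subtypes contributes to each).  On a
median-standardized gene-level matrix, each sample is assigned the
subtype with minimal cosine distance over the matched marker genes
(distance ties break by declared subtype order and are logged; a
zero-norm vector is treated as orthogonal, distance 1).  Significance:
`n_resamples` (default 1000) random gene sets of the matched size are
drawn from the full matrix gene universe with a fixed seed, the distance
of the sample (restricted to each random set) to the assigned template
pattern forms the null, and p = (b+1)/(n+1) where b counts null distances
at or below the observed one.  p-values are BH-adjusted across samples;
calls keep their label regardless of significance, with the FDR<0.2 flag
distinguishing (a flag drops non-significant calls to "unclassified" for
concordance counting when desired).  Cross-region concordance reports,
per region pair and for the full region set, the fraction of patients
with one shared label and the fraction with no label shared between any
two regions.

## Compartment attribution

Given flow-sorted epithelial / fibroblast / leukocyte / endothelial
reference profiles (≥2 samples per compartment), every resolvable
signature gene gets a median expression per compartment; the signature's
dominant source is the compartment with the highest **median of per-gene
medians** (robust to a few misannotated genes; margin to the runner-up
reported, exact ties declared).  A one-way ANOVA (classical F =
MS_between/MS_within) tests compartment differences; degenerate inputs
are reported explicitly (zero within-variance with unequal means → F=∞,
p=0; with equal means → undefined).  Post-hoc pairwise testing is out of
scope.

## Synthetic data generator

The generator defines the conditions under which the pipeline is
validated.  For gene g in sample s (patient p, region r):

    x_gs = b_g + δ_pg·1[epithelial] + λ_g·f_{p,r,comp(g)}·1[stromal] + ε_gs

with b_g ~ N(8, 1) log2 baseline, patient effect δ ~ N(0, 1) on
epithelial genes only, stromal loading λ_g ~ |N(2, 0.5)|, per-sample
compartment fractions f clipped to [0,1] around region means (fibroblast
0.20/0.50/0.35 and leukocyte 0.15/0.20/0.40 for CT/IF/LN, endothelial
0.05 everywhere, SD 0.05), and noise ε ~ N(0, 0.3).  250 genes per
compartment, 24 patients × 3 regions.  The IF fibroblast excess encodes
the invasive-front stromal enrichment that drives region-of-origin
clustering; the LN leukocyte excess mimics nodal immune tissue (a default
choice, not an estimate).  Mixing is additive on the log scale — a
simplification of linear-scale convex mixing that keeps stromal signal
monotone in the fraction and is adequate for the rank/distance-based
statistics downstream.  Fractions are truncated by clipping (not
resampling) to keep draws deterministic.  The sorted-reference generator
expresses each compartment gene at baseline + λ_g in its own compartment
and baseline elsewhere, with an independent seed offset.

What the generator does **not** emulate: probe-level effects, batch
structure, array saturation, correlated gene modules within a
compartment, copy-number or mutational heterogeneity within the
epithelium.  Passing parameter-recovery tests therefore shows the
statistics respond correctly to composition-driven vs patient-intrinsic
signal, not that real microarray noise is handled optimally.

## Numerical and design choices

* Bit-exact TSV round-trips: matrices are written with `%.17g` floats and
  read with correctly-rounded parsing.
* Seeded `numpy.random.default_rng` everywhere; fixed seed ⇒ bit-identical
  datasets, p-values and summary JSON.
* The GEO series-matrix reader handles the text table block
  (`!series_matrix_table_begin`/`end`) only; CEL-level processing and
  re-annotation pipelines are out of scope.
* Evaluation problem sizes: 1000 genes × 72 samples for the cohort
  analyses, 200 template-plus-noise samples for NTP validation, 1000
  label shuffles for the permutation null — sizes at which every stage
  completes in seconds while leaving the planted-signal contrasts far
  from the decision thresholds.

## Known limitations

* The exact arithmetic of the original 0-to-1 normalized similarity index
  is not published; the within-minus-between difference implemented here
  reproduces its stated endpoints, but medians on real cohorts may shift
  under the original normalization.  The definition is isolated in one
  function so alternates can be swapped in.
* DIANA tie-breaking (lowest index) is one of several defensible
  conventions; partitions can differ from other implementations on data
  with exactly tied dissimilarities.
* The random-forest CMS classifier is intentionally not reimplemented
  (published trained model); NTP covers the template-based half of
  subtype calling.
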