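"""Normalized patient similarity and the PGOR curve.

The similarity index scores each patient by how much more correlated its
own multi-region samples are with each other than with everyone else's
(0 = no excess, 1 = perfect within / null between).  The PGOR curve cuts
the Ward dendrogram into k = 1..24 groups and tracks the fraction of
patients whose samples stay together.
"""

from sigrobust import (
    SimulationParams,
    euclidean_dissimilarity,
    median_standardize,
    normalized_patient_similarity,
    pearson_similarity,
    pgor_curve,
    simulate_multiregion,
    subset_to_signature,
    ward_hclust,
)

data = simulate_multiregion(SimulationParams(seed=1))
n_patients = data.annotation["patient_id"].nunique()

for compartment in ("epithelial", "fibroblast"):
    sub, _ = subset_to_signature(data.matrix, data.signature(compartment))
    sub = median_standardize(sub)
    scores = normalized_patient_similarity(pearson_similarity(sub),
                                           data.annotation)
    tree = ward_hclust(euclidean_dissimilarity(sub))
    curve = pgor_curve(tree, data.annotation, k_max=n_patients)
    picks = [1, 2, 6, 12, n_patients]
    trace = ", ".join(f"k={k}: {curve.at(k):.2f}" for k in picks)
    print(f"{compartment}: median similarity {scores.median:+.3f} | PGOR {trace}")

print("\nA robust signature holds PGOR near 1 all the way to k = 24 (every"
      "\npatient its own cluster); a stroma-confounded one collapses as soon"
      "\nas k exceeds the number of regions.")
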