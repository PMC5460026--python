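"""Generate a synthetic multi-region tumour cohort and inspect its structure.

The generator plants two kinds of signal: a patient-intrinsic effect on
epithelial genes (stable across a patient's regions) and a region-driven
stromal effect on fibroblast/leukocyte/endothelial genes (the invasive
front is the most fibroblast-rich, the lymph node the most leukocyte-rich).
"""

from sigrobust import SimulationParams, simulate_multiregion

data = simulate_multiregion(SimulationParams(seed=1))

print(f"matrix: {data.matrix.shape[0]} genes x {data.matrix.shape[1]} samples")
print(f"patients: {data.annotation['patient_id'].nunique()}, "
      f"regions: {sorted(data.annotation['region'].unique())}")
print("genes per compartment:")
print(data.truth_compartment.value_counts().to_string())

mean_frac = (data.truth_fractions
             .groupby(["region", "compartment"])["fraction"].mean()
             .unstack())
print("\nmean simulated cell fractions per region:")
print(mean_frac.round(3).to_string())
print("\nThe IF row carries the largest fibroblast fraction: samples taken"
      "\nat the invasive front are the most stroma-contaminated, which is"
      "\nexactly the confounder the robustness metrics probe.")
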