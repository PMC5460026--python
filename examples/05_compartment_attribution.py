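"""Attribute signature genes to cellular compartments.

Uses the synthetic flow-sorted reference (epithelial / fibroblast /
leukocyte / endothelial populations) to ask where a signature's
transcripts come from: a fibroblast-dominated signature is the kind that
gets confounded by stromal content, an epithelial-dominated one is
cancer-cell intrinsic.  Also runs a one-way ANOVA across compartments for
one signature's per-gene medians.
"""

from sigrobust import (
    SimulationParams,
    compartment_medians,
    dominant_compartment,
    one_way_anova,
    simulate_facs_reference,
    simulate_multiregion,
)

params = SimulationParams(seed=1)
data = simulate_multiregion(params)
ref, labels = simulate_facs_reference(params)

for compartment in ("epithelial", "fibroblast"):
    sig = data.signature(compartment)
    profile = compartment_medians(ref, labels, sig)
    dom = dominant_compartment(profile)
    summary = ", ".join(f"{c}: {v:.2f}"
                        for c, v in dom.per_compartment.items())
    print(f"{sig.name}: dominant = {dom.label} "
          f"(margin {dom.margin:.2f} log2 units) | medians {summary}")

profile = compartment_medians(ref, labels, data.signature("epithelial"))
groups = [profile.medians[c].tolist() for c in profile.compartments]
f_stat, p = one_way_anova(groups)
print(f"\nANOVA across compartments (epithelial signature): "
      f"F = {f_stat:.1f}, p = {p:.3g}")
print("A significant F with an epithelial-dominant profile says the"
      "\nsignature's transcripts are compartment-specific rather than"
      "\nuniformly expressed.")
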