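"""Generate a synthetic opposed-lateral plan, normalize it, and summarise it.

Build a seeded two-field proton plan with ellipsoidal pelvic structures,
impose the 34.5 Gy per-field CTV prescription (69 Gy total), renormalize to
a 76 Gy (RBE) mean CTV dose, and report per-organ statistics and DVH points.
"""

from protonplan.dosimetry import (
    combine_fields,
    cumulative_dvh,
    dose_summary,
    normalize_to_ctv_mean,
)
from protonplan.synthetic import SyntheticPlanSpec, gen_plan

plan = gen_plan(SyntheticPlanSpec(seed=11))
print("Plan parameters:", plan.parameters)

combined = combine_fields(plan.fields, plan.ctv, per_field_prescription=34.5)
print(f"\nCTV mean after two-field combination: "
      f"{combined.values[plan.ctv.values].mean():.3f} Gy (expected 69)")

normalized = normalize_to_ctv_mean(combined, plan.ctv, prescription=76.0)
summary = dose_summary(normalized, plan.masks.values(), label="synthetic")
print("\nPer-organ dose summary (Gy):")
for organ, stats in summary.organs.items():
    print(f"  {organ:14s} max {stats.max:6.2f}  mean {stats.mean:6.2f}")

print("\nDVH points, V(d) = % volume receiving at least d Gy:")
for organ in ("ctv", "rectum", "bladder"):
    curve = cumulative_dvh(normalized, plan.masks[organ])
    points = ", ".join(f"V{d:.0f}={curve.volume_at_dose(d):5.1f}%" for d in (20, 50, 70))
    print(f"  {organ:8s} {points}")

print(
    "\nThe CTV mean sits exactly at the prescription by construction; organs\n"
    "outside the field edge (bladder, rectum) keep low mean doses with long\n"
    "DVH tails, while the femoral heads, crossed by both entrance channels,\n"
    "receive roughly a third of the prescription."
)
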