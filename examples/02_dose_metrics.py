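"""DVH metrics, conformity/homogeneity and criteria compliance for a plan.

Computes the full per-structure metric bundle (PTV D2/D98/D99/Dmean/CI/HI,
lung V5/V20/MLD, cord Dmax, heart V30-V60/MHD) for one synthetic plan and
checks it against the three built-in dose-constraint sets.
"""

import doseret as dr

db = dr.generate_cohort(dr.CohortSpec(n_plans=3, n_classes=3, seed=4))
rec = db.records[0]
m = dr.plan_metrics(rec)

print(f"plan {rec.plan_id} (prescription {rec.prescription_gy:.0f} Gy)")
print(f"  PTV   D2 {m.ptv_d2:6.2f}  D98 {m.ptv_d98:6.2f}  D99 {m.ptv_d99:6.2f}  "
      f"Dmean {m.ptv_dmean:6.2f} Gy")
print(f"  PTV   CI {m.ptv_ci:5.3f}  HI {m.ptv_hi:5.3f}")
print(f"  lung  V5 {m.lung_v5:5.1f}%  V20 {m.lung_v20:5.1f}%  MLD {m.mld:5.2f} Gy")
print(f"  heart V30 {m.heart_v30:4.1f}%  V40 {m.heart_v40:4.1f}%  "
      f"V45 {m.heart_v45:4.1f}%  V60 {m.heart_v60:4.1f}%  MHD {m.mhd:5.2f} Gy")
print(f"  cord  Dmax {m.cord_dmax:5.2f} Gy")

for name in ("rtog0623", "nccn", "department"):
    report = dr.check_criteria(m, dr.load_criteria(name))
    verdict = "PASS" if report.overall_pass else "FAIL"
    failed = [o.rule.label() for o in report.outcomes if not o.passed]
    print(f"  {report.criteria_name:<10} {verdict}" + (f"  ({'; '.join(failed)})" if failed else ""))

# CI near 1 means the prescription isodose hugs the PTV; HI near 0 means a
# homogeneous target dose. A FAIL names the violated constraint(s).
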