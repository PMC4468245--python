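"""SUV normalizations and the PIBGM profile for one synthetic patient.

Converts PET activity (Bq/mL) to SUV under the three body-size
normalizations, reports per-region statistics over the ground-truth bone
labels, and sweeps the PIBGM biomarker over the standard SUV-cutoff grid.
"""

from pibgm import (PhantomSpec, bsa, lbm, make_phantom, pibgm_profile,
                   region_suv_stats, suv_map)

case = make_phantom(PhantomSpec(seed=7))
meta = case.meta
print(f"patient: {meta.body_weight_kg} kg, {meta.body_height_cm} cm, "
      f"{meta.sex}, injected dose {meta.injected_dose_mbq} MBq")
print(f"BSA {bsa(meta.body_weight_kg, meta.body_height_cm):.3f} m^2, "
      f"LBM {lbm(meta.body_weight_kg, meta.body_height_cm, meta.sex):.2f} kg")

for mode in ("bw", "bsa", "lbm"):
    suv = suv_map(case.pet, meta, mode)
    stats = region_suv_stats(suv, case.truth_bone)
    parts = ", ".join(f"{r.region} {r.mean:.3f}+-{r.sd:.3f}"
                      for r in stats.itertuples())
    print(f"SUV_{mode}: {parts}")

suv_bw = suv_map(case.pet, meta, "bw")
print("\ncortex PIBGM profile (fraction of cortex voxels with SUV_bw > t):")
for res in pibgm_profile(suv_bw, case.truth_bone, "cortex"):
    print(f"  t = {res.t:.1f}: PIBGM = {res.value:.3f}  "
          f"({res.n_t}/{res.n_b} voxels)")
print("The profile is non-increasing in t by construction; the step is at "
      "the cortex uptake level, broadened by PET noise.")
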