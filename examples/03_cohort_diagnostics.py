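"""Cohort-level diagnosis: DANP cutoffs, sensitivity sweep, and ROC/AUC.

Runs the full imaging pipeline on a small phantom cohort (normals plus the
three FUO etiologies, each with a cortex-uptake uplift and between-patient
variability), sets the classification cutoff per SUV cutoff by the DANP
rule on the normal subjects, and grades the ROC of the decision biomarker
(cortex PIBGM at t = 1.2).
"""

from pibgm import PipelineConfig, run_cohort, sweep_frame

config = PipelineConfig(seed=20)
result = run_cohort(config,
                    n_per_group={"normal": 10, "inflammatory": 5,
                                 "infection": 5, "neoplasm": 5})

frame = sweep_frame(result.sweep)
cols = ["t", "cutoff", "sensitivity", "specificity", "detect_inflammatory",
        "detect_infection", "detect_neoplasm"]
print("DANP = 0.95 sweep over the SUV-cutoff grid:")
print(frame[cols].to_string(index=False, float_format=lambda v: f"{v:.3f}"))

d = result.decision
print(f"\ndecision biomarker: cortex PIBGM at t = {d.t}")
print(f"  confusion: tp {d.tp}, fp {d.fp}, tn {d.tn}, fn {d.fn}")
print(f"  sensitivity {d.sensitivity:.3f}, specificity {d.specificity:.3f}, "
      f"accuracy {d.accuracy:.3f}")
print(f"ROC AUC {result.roc.auc:.3f} -> graded '{result.roc.grade}'")
print("Specificity tracks the DANP target on the defining normals; "
      "sensitivity peaks where the cutoff best separates hot FUO cortices "
      "from normal ones.")
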