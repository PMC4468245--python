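"""Generate a synthetic PET/CT patient and segment its bones automatically.

Builds a noisy torso phantom (fat/muscle/marrow/cortex populations plus a
scanner-bed arc), removes the bed with the PET-derived body outline, fits
the two-Gaussian HU histogram to place the bone pre-threshold, refines the
bone mask with the threshold-augmented Chan-Vese contour, and scores the
result against the phantom's exact ground truth.
"""

import numpy as np

from pibgm import (BedRemovalParams, PhantomSpec, body_mask_from_pet,
                   build_histogram, compute_threshold, fit_two_gaussians,
                   make_phantom, remove_bed, seg_metrics, segment_bone_volume,
                   split_cortex_marrow)

case = make_phantom(PhantomSpec(seed=42))
print(f"phantom grid {case.ct.shape}, voxel {case.ct.spacing} mm")

body = body_mask_from_pet(case.pet, BedRemovalParams(smooth_sigma=1.0,
                                                     fraction=0.15))
ct = remove_bed(case.ct, body)
n_bed = int(np.count_nonzero(ct.data == case.spec.bed.hu))
print(f"bed removal: {n_bed} bed-valued voxels remain after masking")

edges, counts = build_histogram(ct, body)
fit = fit_two_gaussians(edges, counts)
thr = compute_threshold(fit, omega=0.5)
print(f"histogram fit: fat centre {fit.B_f:.1f} HU, muscle centre "
      f"{fit.B_m:.1f} HU -> bone pre-threshold {thr:.1f} HU")

bone = segment_bone_volume(ct, body, thr)
tpr, fpr, dice = seg_metrics(bone, case.truth_bone)
print(f"bone segmentation vs ground truth: TPR {tpr:.3f}, FPR {fpr:.4f}, "
      f"Dice {dice:.3f}")

labels = split_cortex_marrow(ct, bone)
print(f"cortex/marrow split: {labels.count('cortex')} cortex, "
      f"{labels.count('marrow')} marrow voxels "
      f"(truth: {case.truth_bone.count('cortex')} / "
      f"{case.truth_bone.count('marrow')})")
print("TPR/FPR/Dice measure voxel overlap with the phantom's exact masks; "
      "Dice 1.0 means the contour recovered the bone boundary perfectly.")
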