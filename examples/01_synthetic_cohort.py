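"""Generate stage-conditioned synthetic liver textures and a cohort.

Draws one texture per cirrhosis stage, prints the texture-energy
statistics that separate the stages, then builds a small multi-sequence
cohort and a case-level train/test split.
"""

import numpy as np
from scipy import ndimage

from cirrtex import (DEFAULT_PRESETS, STAGES, generate_cohort,
                     generate_texture, split_cases)

print("Per-stage texture statistics (64x64, seed 0):")
for stage in STAGES:
    img = generate_texture(DEFAULT_PRESETS[stage], 64, 64, seed=0)
    lap = np.mean(ndimage.laplace(img) ** 2)
    rng5 = np.mean(ndimage.maximum_filter(img, 5)
                   - ndimage.minimum_filter(img, 5))
    print(f"  {stage:>12}: mean gray {img.mean():.3f},  "
          f"mean squared Laplacian {lap:.4f},  local 5x5 range {rng5:.3f}")
print("Laplacian energy and local range grow with stage severity —")
print("the nodular, saltatory texture of advancing cirrhosis.\n")

cohort = generate_cohort(counts_per_stage=(6, 5, 5), sequences=("T1", "T2"),
                         rois_per_case_range=(2, 4), seed=7,
                         image_shape=(160, 160))
train, test = split_cases(cohort, train_fraction=0.5, seed=7)
print(f"Cohort: {len(cohort.case_ids())} cases x {len(cohort.sequences)} "
      f"sequences = {len(cohort.cases)} images")
print(f"Case-level split: {len(train)} train / {len(test)} test "
      f"(disjoint: {not set(train) & set(test)})")
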