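"""The region-adaptive pipeline step by step.

Proposes the gland-containing square from the whole-gland mask, applies
the patch-wise equalization core inside it, and verifies the
recombination identity: everything outside the region is untouched.
"""

import numpy as np

from raclahe import (RaclaheParams, apply_raclahe, count_patches,
                     generate_patient, low_contrast_spec,
                     propose_region_from_mask)

patient = generate_patient(low_contrast_spec(), patient_seed=42)
frame = patient.frames[0]
wg = patient.masks["WG"].frames[0]

params = RaclaheParams()  # literal 8-px patches, side clamp 119..149
region = propose_region_from_mask(wg, params)
print(f"proposed region: top-left ({region.r0},{region.c0}), side {region.side} px")
print(f"area fraction of frame: {region.area_fraction:.3f} "
      "(the method targets ~0.25 +/- 0.12)")
print(f"complete 8x8 patches inside: {count_patches(region, 8)}")

out = apply_raclahe(frame, region, params)
outside = ~region.contains_mask()
print("pixels changed outside region:",
      int((out.pixels[outside] != frame.pixels[outside]).sum()))
print(f"gland-region SD before {frame.pixels[region.slices].std():.1f} "
      f"-> after {out.pixels[region.slices].std():.1f}")
# The enhancement is strictly local: contrast rises inside the proposed
# square while the remainder of the frame is bit-identical.
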