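"""End-to-end demonstration: does region-adaptive enhancement help?

Runs the full loop on 50 seeded low-contrast slices: propose the gland
region from the whole-gland mask, segment each slice with the classical
threshold baseline before and after RACLAHE, and compare mean Dice.
"""

from raclahe import enhancement_demo

res = enhancement_demo(n_slices=50, seed=42)
print(f"slices:            {res['n_slices']}")
print(f"mean Dice, raw:    {res['mean_ds_raw']:.3f}")
print(f"mean Dice, RACLAHE:{res['mean_ds_enhanced']:.3f}")
print(f"gain:              {res['mean_ds_enhanced'] - res['mean_ds_raw']:+.3f}")
# The low-contrast phantom's bias field varies across the gland region,
# so one global threshold inside the region misclassifies; local
# equalization (clipped CLAHE on 64-px tiles inside the proposed region)
# restores separability and recovers a large part of the lost accuracy.
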