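"""Pixel-wise BRET maps from a simulated dual-view image pair.

Simulates short/long wavelength luminescence images of a field with two
regions of different BRET ratio and a 2/-1 pixel channel misalignment,
registers the channels, and computes the ratio map.
"""

import numpy as np

import luthy

ratio_map = np.full((96, 96), 0.15)   # cytoplasmic baseline
ratio_map[20:50, 20:50] = 0.45        # interacting compartment

short, long_, truth = luthy.simulate_image_pair(
    (96, 96), ratio_map, shift=(2, -1), background=8.0, noise_sd=4.0, seed=6
)

pair = luthy.ImagePair(short, long_)
reg = luthy.register_translation(pair, max_shift=5)
print(f"registered channel shift: {reg.shift} (true {truth['shift']}), "
      f"NCC = {reg.ncc:.4f}")

aligned = luthy.ImagePair(pair.ch_short, luthy.apply_shift(pair.ch_long, reg.shift))
bmap = luthy.compute_bret_map(aligned, kernel=3, background_percentile=5.0,
                              threshold=40.0)
print(f"foreground pixels: {int(bmap.mask.sum())} of {bmap.mask.size}")

inner = np.nanmean(bmap.ratio[20:50, 20:50])
outer_mask = bmap.mask.copy()
outer_mask[20:50, 20:50] = False
outer = np.nanmean(bmap.ratio[outer_mask])
print(f"mean ratio, interacting region: {inner:.3f} (true 0.45)")
print(f"mean ratio, baseline region:    {outer:.3f} (true 0.15)")
print("\nhigh per-pixel ratios localize where donor- and acceptor-tagged")
print("proteins interact; the threshold keeps ratios off dim background.")
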