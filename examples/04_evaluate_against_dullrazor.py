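"""Score hair removal against ground truth and the Dullrazor baseline.

Uses the classical morphological baseline alone (no training needed) so the
example is fast: Dullrazor's output and the untouched hairy image are both
compared with the clean ground truth.
"""

import numpy as np

import hairbench as hb

rng = np.random.default_rng(3)
mask_cfg = hb.MaskGenConfig.scaled_to((64, 64), num_hairs_range=(10, 20))
skin_cfg = hb.SyntheticSkinConfig(canvas_size=(64, 64),
                                  lesion_radius_range=(10.0, 20.0))

pairs = []
for _ in range(4):
    skin = hb.generate_synthetic_skin(skin_cfg, rng)
    mask = hb.generate_mask(mask_cfg, rng)
    pairs.append(hb.composite(skin, mask, hb.CompositeConfig(), rng))

for i, pair in enumerate(pairs):
    cleaned, detected = hb.dullrazor(pair.hairy)
    before = hb.compute_metrics(pair.hairy, pair.clean)
    after = hb.compute_metrics(cleaned, pair.clean)
    prf = hb.prf_near_mask(cleaned, pair.hairy, pair.clean, pair.mask)
    print(f"pair {i}: SSIM {before.ssim:.4f} -> {after.ssim:.4f}, "
          f"MAE {before.mae:.4f} -> {after.mae:.4f}, "
          f"P/R/F1 {prf.precision:.3f}/{prf.recall:.3f}/{prf.f1:.3f}")

# SSIM toward 1 and MAE toward 0 mean the removal restored the clean image;
# precision counts changed pixels that fall near the true hair mask, recall
# the fraction of true hair pixels the removal actually changed.
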