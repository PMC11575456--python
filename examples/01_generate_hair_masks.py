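"""Generate procedural Bezier hair masks and inspect their statistics.

Each mask is built from 1-40 cubic Bezier strands with arc lengths uniform
on [100, 900] working-canvas pixels and thickness uniform on 1-4 px, blurred
and downscaled to 256x256.
"""

import numpy as np

import hairbench as hb

cfg = hb.MaskGenConfig()  # the benchmark defaults
rng = np.random.default_rng(0)

for i in range(3):
    mask = hb.generate_mask(cfg, rng, keep_layers=False)
    lengths = [s.arc_length for s in mask.strand_specs]
    print(f"mask {i}: {mask.strand_count:2d} hairs "
          f"({hb.classify_density(mask.strand_count)} density), "
          f"arc length {min(lengths):5.0f}-{max(lengths):5.0f} px, "
          f"values in [{mask.values.min():.2f}, {mask.values.max():.2f}], "
          f"hair coverage {hb.binarize_mask(mask).mean():5.1%}")

# Every value is a soft opacity in [0, 1]; coverage is the fraction of
# pixels the binarized mask marks as hair-occluded.
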