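"""Overlay synthetic hair onto clean dermoscopic images.

The hair appearance stage is procedural: the hair color is derived from the
dark structures of the base image itself, a minimum hair-skin luminance
contrast is enforced, and each strand is alpha-blended with the soft mask as
opacity.  Per-strand color jitter adds the natural color variation seen in
real hair.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .masks import HairMask

__all__ = ["CompositeConfig", "PairedSample", "derive_hair_color", "composite"]

# Rec. 601 luma coefficients
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass(frozen=True)
class CompositeConfig:
    """Hair-appearance parameters.

    color_percentile selects the dark tail of the base-image luminance from
    which the hair color is taken; min_contrast is the minimum |luminance|
    gap enforced between hair color and the image's median skin tone;
    color_jitter is a per-strand uniform RGB perturbation amplitude.
    """

    color_percentile: float = 10.0
    min_contrast: float = 0.15
    color_jitter: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.color_percentile < 100.0:
            raise ValueError("color_percentile must be in (0, 100)")
        if not 0.0 <= self.min_contrast < 1.0:
            raise ValueError("min_contrast must be in [0, 1)")
        if self.color_jitter < 0:
            raise ValueError("color_jitter must be >= 0")


@dataclass
class PairedSample:
    """A (clean, hairy, mask) training/evaluation triple."""

    clean: np.ndarray
    hairy: np.ndarray
    mask: HairMask
    meta: dict = field(default_factory=dict)


def _luminance(rgb: np.ndarray) -> np.ndarray:
    return rgb @ _LUMA


def derive_hair_color(clean: np.ndarray, config: CompositeConfig,
                      rng: np.random.Generator) -> np.ndarray:
    """Pick a hair color from the dark structures of the base image.

    Returns the mean RGB over pixels at or below the color_percentile of
    luminance.  If that color sits closer than min_contrast to the image's
    median luminance, it is darkened (uniformly rescaled) until the gap is
    met, or to black when the median itself is below min_contrast.  Jitter,
    when configured, perturbs each channel uniformly.
    """
    clean = np.asarray(clean, dtype=np.float64)
    if clean.size == 0:
        raise ValueError("empty image")
    lum = _luminance(clean.reshape(-1, 3))
    cutoff = np.percentile(lum, config.color_percentile)
    dark = clean.reshape(-1, 3)[lum <= cutoff]
    color = dark.mean(axis=0)
    median = float(np.median(lum))
    color_lum = float(color @ _LUMA)
    if median - color_lum < config.min_contrast:
        target = max(median - config.min_contrast, 0.0)
        color = color * (target / color_lum) if color_lum > 1e-12 \
            else np.full(3, target)
    if config.color_jitter > 0:
        color = color + rng.uniform(-config.color_jitter, config.color_jitter, 3)
    return np.clip(color, 0.0, 1.0)


def composite(clean: np.ndarray, mask: HairMask, config: CompositeConfig,
              rng: np.random.Generator) -> PairedSample:
    """Alpha-blend hair onto a clean image: hairy = (1-m)*clean + m*color.

    When the mask carries per-strand layers, each strand receives its own
    jittered color and strands are blended sequentially; the combined mask is
    the maximum over layers, so the clean image is untouched (bit-exact)
    wherever the combined mask is zero.
    """
    clean = np.asarray(clean, dtype=np.float64)
    if clean.shape[:2] != mask.values.shape:
        raise ValueError(f"size mismatch: image {clean.shape[:2]}, "
                         f"mask {mask.values.shape}")
    per_strand = bool(mask.layers)
    base_cfg = replace(config, color_jitter=0.0) if per_strand else config
    base = derive_hair_color(clean, base_cfg, rng)
    hairy = clean.copy()
    layers = mask.layers if per_strand else [mask.values]
    colors = []
    for layer in layers:
        if per_strand and config.color_jitter > 0:
            color = np.clip(base + rng.uniform(-config.color_jitter,
                                               config.color_jitter, 3), 0.0, 1.0)
        else:
            color = base
        colors.append(color)
        m = layer[:, :, None]
        on = layer > 0
        hairy[on] = ((1.0 - m) * hairy + m * color)[on]
    meta = {
        "hair_color_base": base.tolist(),
        "strand_colors": [c.tolist() for c in colors],
        "min_contrast": config.min_contrast,
    }
    return PairedSample(clean=clean, hairy=np.clip(hairy, 0.0, 1.0),
                        mask=mask, meta=meta)
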