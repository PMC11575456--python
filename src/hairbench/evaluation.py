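"""Benchmark experiments: paired evaluation, baseline comparison, hair sweep.

`evaluate_pairs` scores hair-removed images against their clean ground
truth (MSE, MAE, SSIM, MS-SSIM) per sample, optionally alongside the
Dullrazor baseline run on the same hairy inputs, and summarizes mean and
standard deviation per metric and method.

`hair_count_sweep` measures how removal quality degrades with hair
coverage: for k = 1..k_max hairs, masks with exactly k strands are
composited onto a panel of clean images, the model removes them, and
SSIM(hairy, clean) / SSIM(removed, clean) are recorded per k.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .compositing import CompositeConfig, composite
from .dataset import SyntheticSkinConfig, generate_synthetic_skin
from .dullrazor import DullrazorConfig, dullrazor
from .masks import MaskGenConfig, generate_mask
from .metrics import compute_metrics, ssim
from .model import ModelState, forward

__all__ = ["evaluate_pairs", "hair_count_sweep", "compare_dullrazor",
           "SweepResult", "remove_hair"]

logger = logging.getLogger(__name__)

METRIC_NAMES = ["mse", "mae", "ssim", "ms_ssim"]


def remove_hair(state: ModelState, hairy: np.ndarray) -> np.ndarray:
    """Run the inpainting model on one (H,W,3) image."""
    return forward(state, hairy[None], as_array=True)[0]


@dataclass
class SweepResult:
    """Per-hair-count SSIM before and after removal (mean and std)."""

    table: pd.DataFrame  # columns: k, ssim_hairy_mean/std, ssim_removed_mean/std
    n_samples: int
    trained: bool = True


def evaluate_pairs(samples, removed_images, baseline: str | None = None,
                   dullrazor_config: DullrazorConfig | None = None,
                   scales: int | None = None
                   ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Score removed images (and optionally Dullrazor) against ground truth.

    `samples` is a sequence of PairedSample; `removed_images` maps
    sample index -> (H,W,3) removed image (list or dict).  Returns
    (per-sample table, summary with mean/std rows per method).
    """
    rows = []
    for i, sample in enumerate(samples):
        try:
            removed = removed_images[i]
        except (KeyError, IndexError):
            logger.warning("sample %d has no removed image; excluded", i)
            continue
        rec = compute_metrics(removed, sample.clean, scales=scales)
        row = {"sample": i, "method": "model", **vars(rec)}
        rows.append(row)
        if baseline == "dullrazor":
            base_img, _ = dullrazor(sample.hairy, dullrazor_config)
            rec_b = compute_metrics(base_img, sample.clean, scales=scales)
            rows.append({"sample": i, "method": "dullrazor", **vars(rec_b)})
        elif baseline is not None:
            raise ValueError(f"unknown baseline {baseline!r}")
    if not rows:
        raise ValueError("no samples were evaluated")
    table = pd.DataFrame(rows)
    summary = (table.groupby("method")[METRIC_NAMES]
               .agg(["mean", "std"]))
    summary.columns = [f"{m}_{s}" for m, s in summary.columns]
    return table, summary.reset_index()


def hair_count_sweep(state: ModelState | None, clean_images,
                     k_max: int = 20, seed: int = 0,
                     mask_config: MaskGenConfig | None = None,
                     composite_config: CompositeConfig | None = None
                     ) -> SweepResult:
    """SSIM before/after removal as hair count grows from 1 to k_max.

    An untrained (or None) model is allowed: with state=None the "removed"
    image is the hairy image itself, flagged untrained in the result.
    """
    mask_config = mask_config or MaskGenConfig()
    composite_config = composite_config or CompositeConfig()
    clean_images = list(clean_images)
    if not clean_images:
        raise ValueError("need at least one clean image")
    rng = np.random.default_rng(seed)
    rows = []
    for k in range(1, k_max + 1):
        cfg_k = replace(mask_config, num_hairs_range=(k, k))
        pre, post = [], []
        for img in clean_images:
            mask = generate_mask(cfg_k, rng)
            pair = composite(img, mask, composite_config, rng)
            pre.append(ssim(pair.hairy, pair.clean))
            removed = remove_hair(state, pair.hairy) if state is not None \
                else pair.hairy
            post.append(ssim(removed, pair.clean))
        rows.append({
            "k": k,
            "ssim_hairy_mean": float(np.mean(pre)),
            "ssim_hairy_std": float(np.std(pre, ddof=1)) if len(pre) > 1 else 0.0,
            "ssim_removed_mean": float(np.mean(post)),
            "ssim_removed_std": float(np.std(post, ddof=1)) if len(post) > 1 else 0.0,
        })
    return SweepResult(table=pd.DataFrame(rows), n_samples=len(clean_images),
                       trained=state is not None)


def compare_dullrazor(state: ModelState, n_clean: int = 10,
                      variants_per_clean: int = 10, min_hairs: int = 10,
                      seed: int = 0,
                      skin_config: SyntheticSkinConfig | None = None,
                      mask_config: MaskGenConfig | None = None,
                      composite_config: CompositeConfig | None = None,
                      scales: int | None = None
                      ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """The canned model-vs-Dullrazor protocol on synthetic skin.

    Builds n_clean synthetic lesion images with `variants_per_clean` hairy
    variants each (every mask carries at least `min_hairs` hairs), removes
    hair with both methods, and returns per-sample and summary tables.
    """
    from .compositing import PairedSample  # local import to avoid cycle noise

    skin_config = skin_config or SyntheticSkinConfig()
    mask_config = mask_config or MaskGenConfig()
    if mask_config.num_hairs_range[0] < min_hairs:
        lo = min_hairs
        hi = max(mask_config.num_hairs_range[1], lo)
        mask_config = replace(mask_config, num_hairs_range=(lo, hi))
    composite_config = composite_config or CompositeConfig()
    rng = np.random.default_rng(seed)
    samples: list[PairedSample] = []
    removed: list[np.ndarray] = []
    h, w = mask_config.canvas_size
    skin_config = replace(skin_config, canvas_size=(h, w))
    for _ in range(n_clean):
        clean = generate_synthetic_skin(skin_config, rng)
        for _ in range(variants_per_clean):
            mask = generate_mask(mask_config, rng)
            pair = composite(clean, mask, composite_config, rng)
            samples.append(pair)
            removed.append(remove_hair(state, pair.hairy))
    return evaluate_pairs(samples, removed, baseline="dullrazor",
                          scales=scales)
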