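"""The five-component composite objective for hair-removal training.

L_total = l1*L_hair + l2*L_nonhair + l3*L_normalized + l4*L_SSIM + l5*L_TV

* L_hair        — MSE restricted to hair pixels (0 when the hair set is empty)
* L_nonhair     — MSE restricted to non-hair pixels
* L_normalized  — squared hair-region error divided by the *total* pixel
                  count, expressing the hair error relative to the whole
                  image (so L_normalized = L_hair * |hair| / |all|)
* L_SSIM        — 1 - SSIM(pred, target), the metrics module's SSIM
* L_TV          — anisotropic total variation: mean absolute difference of
                  horizontally and vertically adjacent pixels

Hair/non-hair partitions come from the soft mask binarized at the mask
generator's default threshold.  Every function accepts either plain arrays
(returns float) or autodiff tensors for the prediction (returns a
differentiable scalar).
"""

from __future__ import annotations

from dataclasses import dataclass, astuple

import numpy as np

from .autodiff import Tensor, as_tensor
from .metrics import ssim

__all__ = [
    "LossWeights",
    "LossComponents",
    "WEIGHT_PRESETS",
    "loss_hair",
    "loss_non_hair",
    "loss_normalized",
    "loss_ssim",
    "loss_tv",
    "total_loss",
    "composite_loss",
]


@dataclass(frozen=True)
class LossWeights:
    """The weight vector (lambda1..lambda5) of the composite objective."""

    hair: float = 2.5
    non_hair: float = 3.5
    normalized: float = 0.3
    ssim: float = 1.0
    tv: float = 0.5

    def __post_init__(self):
        if any(w < 0 for w in astuple(self)):
            raise ValueError("loss weights must be non-negative")

    @classmethod
    def preset(cls, name: str) -> "LossWeights":
        try:
            return cls(*WEIGHT_PRESETS[name])
        except KeyError:
            raise ValueError(f"unknown preset {name!r}; "
                             f"choose from {sorted(WEIGHT_PRESETS)}") from None

    @classmethod
    def parse(cls, text: str) -> "LossWeights":
        """Accept a preset name, a comma-separated 5-vector, or a YAML path."""
        if text in WEIGHT_PRESETS:
            return cls.preset(text)
        if text.endswith((".yml", ".yaml")):
            return cls.from_yaml(text)
        parts = [float(p) for p in text.split(",")]
        if len(parts) != 5:
            raise ValueError("expected five comma-separated weights")
        return cls(*parts)

    @classmethod
    def from_yaml(cls, path) -> "LossWeights":
        """Load weights from YAML: either a 5-list or a field mapping."""
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh)
        if isinstance(data, (list, tuple)):
            if len(data) != 5:
                raise ValueError("expected five weights")
            return cls(*(float(x) for x in data))
        if isinstance(data, dict):
            return cls(**{k: float(v) for k, v in data.items()})
        raise ValueError("YAML weights must be a 5-list or a mapping")


# The three benchmark weight configurations.
WEIGHT_PRESETS = {
    "uniform": (1.0, 1.0, 1.0, 1.0, 1.0),
    "initial": (0.5, 0.5, 0.2, 0.2, 0.2),
    "tuned": (2.5, 3.5, 0.3, 1.0, 0.5),
}


@dataclass(frozen=True)
class LossComponents:
    hair: float
    non_hair: float
    normalized: float
    ssim: float
    tv: float

    def as_dict(self) -> dict:
        return {"hair": self.hair, "non_hair": self.non_hair,
                "normalized": self.normalized, "ssim": self.ssim, "tv": self.tv}


# ------------------------------------------------------------ mask plumbing

def _prep(pred, target, hair_pixels):
    """Normalize inputs to (N,C,H,W) tensors and an (N,1,H,W) float mask."""
    pt = pred if isinstance(pred, Tensor) else _img_to_tensor(pred)
    tt = target if isinstance(target, Tensor) else _img_to_tensor(target)
    if pt.shape != tt.shape:
        raise ValueError(f"shape mismatch: {pt.shape} vs {tt.shape}")
    m = np.asarray(hair_pixels)
    if m.ndim == 2:
        m = m[None, None]
    elif m.ndim == 3:  # (N, H, W)
        m = m[:, None]
    if m.shape[0] != pt.shape[0] or m.shape[2:] != pt.shape[2:]:
        raise ValueError(f"mask shape {m.shape} incompatible with {pt.shape}")
    return pt, tt, m.astype(np.float64)


def _img_to_tensor(x) -> Tensor:
    x = np.asarray(x, dtype=np.float64)
    if x.ndim == 2:
        x = x[None, None]
    elif x.ndim == 3:
        x = x.transpose(2, 0, 1)[None]
    elif x.ndim != 4:
        raise ValueError("images must be (H,W), (H,W,C) or (N,C,H,W)")
    return Tensor(x)


def _maybe_float(result: Tensor, *inputs):
    return result if any(isinstance(i, Tensor) for i in inputs) else result.item()


# ------------------------------------------------------------------- losses

def loss_hair(pred, target, hair_pixels):
    """MSE over hair pixels (all channels); 0 when no pixel is hair."""
    pt, tt, m = _prep(pred, target, hair_pixels)
    n = m.sum() * pt.shape[1]
    if n == 0:
        return _maybe_float(Tensor(0.0) + 0.0 * pt.sum(), pred)
    out = ((pt - tt).square() * m).sum() / n
    return _maybe_float(out, pred)


def loss_non_hair(pred, target, hair_pixels):
    """MSE over the complement of the hair set; 0 when everything is hair."""
    pt, tt, m = _prep(pred, target, hair_pixels)
    inv = 1.0 - m
    n = inv.sum() * pt.shape[1]
    if n == 0:
        return _maybe_float(Tensor(0.0) + 0.0 * pt.sum(), pred)
    out = ((pt - tt).square() * inv).sum() / n
    return _maybe_float(out, pred)


def loss_normalized(pred, target, hair_pixels):
    """Hair-region squared error relative to the whole image.

    Sum of squared differences over hair pixels divided by the total pixel
    count (times channels), i.e. loss_hair scaled by |hair| / |all|.
    """
    pt, tt, m = _prep(pred, target, hair_pixels)
    total = pt.shape[0] * pt.shape[1] * pt.shape[2] * pt.shape[3]
    out = ((pt - tt).square() * m).sum() / total
    return _maybe_float(out, pred)


def loss_ssim(pred, target):
    """Structural dissimilarity 1 - SSIM(pred, target)."""
    pt = pred if isinstance(pred, Tensor) else _img_to_tensor(pred)
    tt = target if isinstance(target, Tensor) else _img_to_tensor(target)
    out = 1.0 - ssim(pt, tt)
    return _maybe_float(out, pred)


def loss_tv(pred):
    """Anisotropic total variation: mean |difference| of adjacent pixels."""
    pt = pred if isinstance(pred, Tensor) else _img_to_tensor(pred)
    n, c, h, w = pt.shape
    dh = pt.slice_rows(3, 1, w) - pt.slice_rows(3, 0, w - 1)
    dv = pt.slice_rows(2, 1, h) - pt.slice_rows(2, 0, h - 1)
    n_pairs = n * c * (h * (w - 1) + (h - 1) * w)
    out = (dh.abs().sum() + dv.abs().sum()) / n_pairs
    return _maybe_float(out, pred)


def total_loss(components, weights: LossWeights):
    """Weighted sum of the five components.

    `components` may be a LossComponents of floats or a 5-tuple of scalars /
    tensors in the order (hair, non_hair, normalized, ssim, tv).
    """
    if isinstance(components, LossComponents):
        comp = astuple(components)
    else:
        comp = tuple(components)
    lam = astuple(weights)
    out = sum((w * (c if isinstance(c, Tensor) else as_tensor(float(c)))
               for w, c in zip(lam, comp)), start=Tensor(0.0))
    return out if any(isinstance(c, Tensor) for c in comp) else out.item()


def composite_loss(pred, target, hair_pixels, weights: LossWeights):
    """All five components plus the weighted total in one pass.

    Returns (total, LossComponents-of-floats); `total` is a Tensor when
    `pred` is a Tensor.
    """
    lh = loss_hair(pred, target, hair_pixels)
    ln = loss_non_hair(pred, target, hair_pixels)
    lz = loss_normalized(pred, target, hair_pixels)
    ls = loss_ssim(pred, target)
    lt = loss_tv(pred)
    total = total_loss((lh, ln, lz, ls, lt), weights)
    comps = LossComponents(
        *(float(x.item()) if isinstance(x, Tensor) else float(x)
          for x in (lh, ln, lz, ls, lt)))
    return total, comps
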