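"""Image-quality metrics: MSE, MAE, SSIM, MS-SSIM and near-mask PRF.

SSIM uses Gaussian-windowed local statistics (11x11 window, sigma 1.5,
K1=0.01, K2=0.03, dynamic range 1) computed in valid mode, i.e. the border
where the window does not fit is cropped before averaging.  The same code
path runs on plain arrays (returning floats) and on autodiff tensors
(returning a differentiable scalar), so the SSIM term of the training loss
and the reported SSIM metric are one implementation.

MS-SSIM follows the usual multi-scale construction: contrast-structure
terms on a dyadic pyramid (2x2 mean pooling between scales), the luminance
term at the coarsest scale only, exponents from the conventional five-scale
weight vector renormalized to the number of scales used.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import binary_dilation

from .autodiff import Tensor
from .masks import HairMask, binarize_mask

__all__ = [
    "MetricsRecord",
    "PRFRecord",
    "mse",
    "mae",
    "ssim",
    "ms_ssim",
    "compute_metrics",
    "prf_near_mask",
]

MSSSIM_WEIGHTS = (0.0448, 0.2856, 0.3001, 0.2363, 0.1333)


@dataclass(frozen=True)
class MetricsRecord:
    mse: float
    mae: float
    ssim: float
    ms_ssim: float


@dataclass(frozen=True)
class PRFRecord:
    """Precision/recall/F1 of hair-pixel detection near the true mask.

    A predicted hair pixel counts toward precision when it falls within the
    ground-truth mask dilated by `dilation_radius`; recall is measured
    against the undilated mask.
    """

    precision: float
    recall: float
    f1: float
    dilation_radius: int
    empty_truth: bool = False
    no_predictions: bool = False


# ----------------------------------------------------------- shape plumbing

def _check_pair(a: np.ndarray, b: np.ndarray) -> None:
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")


def _to_nchw(x) -> Tensor:
    """Accept (H,W), (H,W,C) arrays or (N,C,H,W) tensors."""
    if isinstance(x, Tensor):
        if x.ndim != 4:
            raise ValueError("tensor inputs must be (N, C, H, W)")
        return x
    x = np.asarray(x, dtype=np.float64)
    if x.ndim == 2:
        x = x[None, None]
    elif x.ndim == 3:
        x = x.transpose(2, 0, 1)[None]
    else:
        raise ValueError("array inputs must be (H, W) or (H, W, C)")
    return Tensor(x)


# ------------------------------------------------------------ simple errors

def mse(a: np.ndarray, b: np.ndarray) -> float:
    """Mean squared difference over all pixels and channels."""
    a, b = np.asarray(a, dtype=np.float64), np.asarray(b, dtype=np.float64)
    _check_pair(a, b)
    return float(np.mean((a - b) ** 2))


def mae(a: np.ndarray, b: np.ndarray) -> float:
    """Mean absolute difference over all pixels and channels."""
    a, b = np.asarray(a, dtype=np.float64), np.asarray(b, dtype=np.float64)
    _check_pair(a, b)
    return float(np.mean(np.abs(a - b)))


# -------------------------------------------------------------------- SSIM

def gaussian_window(size: int = 11, sigma: float = 1.5) -> np.ndarray:
    ax = np.arange(size, dtype=np.float64) - (size - 1) / 2.0
    g = np.exp(-(ax ** 2) / (2.0 * sigma ** 2))
    k = np.outer(g, g)
    return k / k.sum()


def _ssim_maps(at: Tensor, bt: Tensor, kernel: np.ndarray,
               c1: float, c2: float) -> tuple[Tensor, Tensor]:
    """Luminance and contrast-structure maps on the valid window region."""
    mu_a = at.depthwise_valid_conv(kernel)
    mu_b = bt.depthwise_valid_conv(kernel)
    e_aa = at.square().depthwise_valid_conv(kernel)
    e_bb = bt.square().depthwise_valid_conv(kernel)
    e_ab = (at * bt).depthwise_valid_conv(kernel)
    var_a = e_aa - mu_a.square()
    var_b = e_bb - mu_b.square()
    cov = e_ab - mu_a * mu_b
    lum = (2.0 * mu_a * mu_b + c1) / (mu_a.square() + mu_b.square() + c1)
    cs = (2.0 * cov + c2) / (var_a + var_b + c2)
    return lum, cs


def ssim(a, b, window: int = 11, sigma: float = 1.5,
         k1: float = 0.01, k2: float = 0.03, data_range: float = 1.0):
    """Structural similarity, averaged over channels and valid positions.

    Returns a float for array inputs and a differentiable scalar Tensor for
    Tensor inputs.
    """
    at, bt = _to_nchw(a), _to_nchw(b)
    if at.shape != bt.shape:
        raise ValueError(f"shape mismatch: {at.shape} vs {bt.shape}")
    if min(at.shape[2], at.shape[3]) < window:
        raise ValueError(f"image smaller than the {window}x{window} SSIM window")
    kernel = gaussian_window(window, sigma)
    c1, c2 = (k1 * data_range) ** 2, (k2 * data_range) ** 2
    lum, cs = _ssim_maps(at, bt, kernel, c1, c2)
    out = (lum * cs).mean()
    if isinstance(a, Tensor) or isinstance(b, Tensor):
        return out
    return out.item()


def _max_scales(shape: tuple[int, ...], window: int) -> int:
    s = 1
    h, w = shape[-2], shape[-1]
    while min(h // 2, w // 2) >= window and s < len(MSSSIM_WEIGHTS):
        h, w = h // 2, w // 2
        s += 1
    return s


def ms_ssim(a, b, scales: int | None = None, window: int = 11,
            sigma: float = 1.5, k1: float = 0.01, k2: float = 0.03,
            data_range: float = 1.0) -> float:
    """Multi-scale SSIM.

    `scales=None` uses the largest feasible number of dyadic scales (at most
    5) for the image size; requesting more scales than the image supports is
    an error.  With one scale this reduces to plain SSIM.
    """
    at, bt = _to_nchw(a), _to_nchw(b)
    if at.shape != bt.shape:
        raise ValueError(f"shape mismatch: {at.shape} vs {bt.shape}")
    feasible = _max_scales(at.shape, window)
    if min(at.shape[2], at.shape[3]) < window:
        raise ValueError(f"image smaller than the {window}x{window} SSIM window")
    if scales is None:
        scales = feasible
    elif scales > feasible or scales < 1:
        raise ValueError(f"{scales} scales unsupported for size "
                         f"{at.shape[2]}x{at.shape[3]} (max {feasible})")
    kernel = gaussian_window(window, sigma)
    c1, c2 = (k1 * data_range) ** 2, (k2 * data_range) ** 2
    weights = np.asarray(MSSSIM_WEIGHTS[:scales])
    weights = weights / weights.sum()
    result = 1.0
    for level in range(scales):
        lum, cs = _ssim_maps(at, bt, kernel, c1, c2)
        if level == scales - 1:
            # coarsest scale carries the full SSIM (luminance included)
            mssim = max(float((lum * cs).mean().item()), 1e-8)
            result *= mssim ** weights[level]
        else:
            mcs = max(float(cs.mean().item()), 1e-8)
            result *= mcs ** weights[level]
            h, w = at.shape[2], at.shape[3]
            at = Tensor(at.value[:, :, :h - h % 2, :w - w % 2]).avgpool2()
            bt = Tensor(bt.value[:, :, :h - h % 2, :w - w % 2]).avgpool2()
    return float(result)


def compute_metrics(a: np.ndarray, b: np.ndarray,
                    scales: int | None = None) -> MetricsRecord:
    """All four quality metrics for one image pair."""
    return MetricsRecord(mse=mse(a, b), mae=mae(a, b), ssim=ssim(a, b),
                         ms_ssim=ms_ssim(a, b, scales=scales))


# --------------------------------------------------------------------- PRF

def prf_near_mask(removed: np.ndarray, hairy: np.ndarray, clean: np.ndarray,
                  mask: HairMask | np.ndarray, dilation_radius: int = 5,
                  change_threshold: float = 0.02,
                  mask_threshold: float = 0.1) -> PRFRecord:
    """Detection quality of the removal, evaluated near the true hair mask.

    A pixel counts as "predicted hair" when the removal changed it by at
    least `change_threshold` in any channel.  Precision is the fraction of
    predicted pixels lying within the true mask dilated by
    `dilation_radius`; recall is the fraction of true hair pixels predicted.
    """
    removed = np.asarray(removed, dtype=np.float64)
    hairy = np.asarray(hairy, dtype=np.float64)
    _check_pair(removed, hairy)
    if clean is not None:
        _check_pair(removed, np.asarray(clean))
    truth = binarize_mask(mask, mask_threshold)
    change = np.abs(removed - hairy)
    if change.ndim == 3:
        change = change.max(axis=2)
    predicted = change >= change_threshold
    if dilation_radius > 0:
        yy, xx = np.mgrid[-dilation_radius:dilation_radius + 1,
                          -dilation_radius:dilation_radius + 1]
        near = binary_dilation(truth, yy ** 2 + xx ** 2 <= dilation_radius ** 2)
    else:
        near = truth
    n_pred = int(predicted.sum())
    n_truth = int(truth.sum())
    precision = float((predicted & near).sum() / n_pred) if n_pred else 0.0
    recall = float((predicted & truth).sum() / n_truth) if n_truth else 0.0
    f1 = 2 * precision * recall / (precision + recall) \
        if (precision + recall) > 0 else 0.0
    return PRFRecord(precision=precision, recall=recall, f1=f1,
                     dilation_radius=dilation_radius,
                     empty_truth=n_truth == 0, no_predictions=n_pred == 0)
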