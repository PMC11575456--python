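"""U-Net-like encoder-decoder for dermoscopic hair inpainting.

The network maps a hairy RGB image to a hair-free RGB image of the same
size.  Each encoder level applies two 3x3 convolutions with ReLU and halves
the resolution with 2x2 max pooling; each decoder level upsamples with a 2x2
transposed convolution, concatenates the matching encoder feature map (skip
connection) and applies two 3x3 convolutions.  A final 1x1 convolution with
a sigmoid projects to three channels in [0, 1].

Channel widths double per level starting from `base_channels`.  With
depth=1 the model degenerates to a plain convolutional stack (no pooling,
no skips).  Implemented on the package's numpy autodiff engine.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .autodiff import Tensor, concat_channels

__all__ = ["UNetConfig", "ModelState", "init_model", "forward",
           "save_checkpoint", "load_checkpoint"]

CHECKPOINT_VERSION = 1


@dataclass(frozen=True)
class UNetConfig:
    depth: int = 4
    base_channels: int = 16
    kernel_size: int = 3
    output_kernel: int = 1
    input_size: tuple[int, int, int] = (256, 256, 3)
    init_seed: int = 0

    def __post_init__(self):
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        h, w, _c = self.input_size
        f = 2 ** (self.depth - 1)
        if h % f or w % f:
            raise ValueError(
                f"input size {h}x{w} not divisible by 2^(depth-1) = {f}")

    def channels(self) -> list[int]:
        return [self.base_channels * 2 ** i for i in range(self.depth)]


@dataclass
class ModelState:
    """Trainable parameters keyed by layer name, plus the architecture."""

    params: dict[str, Tensor]
    config: UNetConfig

    def num_parameters(self) -> int:
        return sum(p.value.size for p in self.params.values())


def _he_conv(rng, f, c, k) -> np.ndarray:
    return rng.standard_normal((f, c, k, k)) * np.sqrt(2.0 / (c * k * k))


def init_model(config: UNetConfig) -> ModelState:
    """Allocate and initialize all parameters (He initialization, seeded)."""
    rng = np.random.default_rng(config.init_seed)
    k = config.kernel_size
    chans = config.channels()
    in_c = config.input_size[2]
    params: dict[str, np.ndarray] = {}

    prev = in_c
    for lvl, c in enumerate(chans):
        params[f"enc{lvl}_conv1_w"] = _he_conv(rng, c, prev, k)
        params[f"enc{lvl}_conv1_b"] = np.zeros(c)
        params[f"enc{lvl}_conv2_w"] = _he_conv(rng, c, c, k)
        params[f"enc{lvl}_conv2_b"] = np.zeros(c)
        prev = c
    for lvl in range(config.depth - 2, -1, -1):
        c_up, c = chans[lvl + 1], chans[lvl]
        # transposed conv kernel (C_in, C_out, 2, 2)
        params[f"dec{lvl}_up_w"] = (rng.standard_normal((c_up, c, 2, 2))
                                    * np.sqrt(2.0 / c_up))
        params[f"dec{lvl}_up_b"] = np.zeros(c)
        params[f"dec{lvl}_conv1_w"] = _he_conv(rng, c, 2 * c, k)
        params[f"dec{lvl}_conv1_b"] = np.zeros(c)
        params[f"dec{lvl}_conv2_w"] = _he_conv(rng, c, c, k)
        params[f"dec{lvl}_conv2_b"] = np.zeros(c)
    params["out_w"] = _he_conv(rng, in_c, chans[0], config.output_kernel)
    params["out_b"] = np.zeros(in_c)

    tensors = {name: Tensor(v, requires_grad=True) for name, v in params.items()}
    return ModelState(params=tensors, config=config)


def _images_to_batch(images) -> Tensor:
    """(H,W,C), (N,H,W,C) arrays or ready (N,C,H,W) tensors -> tensor."""
    if isinstance(images, Tensor):
        return images
    x = np.asarray(images, dtype=np.float64)
    if x.ndim == 3:
        x = x[None]
    if x.ndim != 4:
        raise ValueError("expected (H,W,C) or (N,H,W,C) image batch")
    return Tensor(x.transpose(0, 3, 1, 2))


def forward(state: ModelState, images, as_array: bool = False):
    """Run the network; output has the input's spatial size, values in [0,1].

    `images` is (H,W,C), (N,H,W,C) in [0,1] or an (N,C,H,W) Tensor.  Returns
    an (N,C,H,W) Tensor, or (N,H,W,C) numpy array when `as_array`.
    """
    cfg = state.config
    x = _images_to_batch(images)
    h, w = x.shape[2], x.shape[3]
    eh, ew, ec = cfg.input_size
    if x.shape[1] != ec:
        raise ValueError(f"expected {ec} channels, got {x.shape[1]}")
    f = 2 ** (cfg.depth - 1)
    if h % f or w % f:
        raise ValueError(f"spatial size {h}x{w} not divisible by {f}")
    p = state.params
    pad = cfg.kernel_size // 2

    skips = []
    for lvl in range(cfg.depth):
        x = x.conv2d(p[f"enc{lvl}_conv1_w"], p[f"enc{lvl}_conv1_b"], pad).relu()
        x = x.conv2d(p[f"enc{lvl}_conv2_w"], p[f"enc{lvl}_conv2_b"], pad).relu()
        if lvl < cfg.depth - 1:
            skips.append(x)
            x = x.maxpool2()
    for lvl in range(cfg.depth - 2, -1, -1):
        x = x.conv_transpose2x2(p[f"dec{lvl}_up_w"], p[f"dec{lvl}_up_b"])
        x = concat_channels(skips[lvl], x)
        x = x.conv2d(p[f"dec{lvl}_conv1_w"], p[f"dec{lvl}_conv1_b"], pad).relu()
        x = x.conv2d(p[f"dec{lvl}_conv2_w"], p[f"dec{lvl}_conv2_b"], pad).relu()
    out = x.conv2d(p["out_w"], p["out_b"], cfg.output_kernel // 2).sigmoid()
    if as_array:
        return out.value.transpose(0, 2, 3, 1)
    return out


# ---------------------------------------------------------------- persistence

def save_checkpoint(state: ModelState, path: str | Path) -> None:
    """Write config JSON next to an .npz parameter blob."""
    path = Path(path)
    np.savez(path.with_suffix(".npz"),
             **{k: v.value for k, v in state.params.items()})
    meta = {"version": CHECKPOINT_VERSION, "config": asdict(state.config)}
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def load_checkpoint(path: str | Path) -> ModelState:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    if meta.get("version", 0) > CHECKPOINT_VERSION:
        raise ValueError("checkpoint written by a newer version")
    cfg_d = meta["config"]
    cfg_d["input_size"] = tuple(cfg_d["input_size"])
    cfg = UNetConfig(**cfg_d)
    blob = np.load(path.with_suffix(".npz"))
    params = {k: Tensor(blob[k], requires_grad=True) for k in blob.files}
    return ModelState(params=params, config=cfg)
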