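"""Custom training loop: explicit forward/backward passes with Adam.

Each iteration is one optimizer step on one mini-batch: forward the hairy
images, evaluate the five-component composite loss against the clean
targets, backpropagate through the autodiff tape, and apply an Adam update.
The per-iteration component values are recorded as the loss history so the
training dynamics can be plotted and audited.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .compositing import PairedSample
from .dataset import load_image
from .losses import LossComponents, LossWeights, composite_loss, total_loss
from .masks import binarize_mask, load_mask
from .model import ModelState, forward, save_checkpoint

__all__ = ["TrainConfig", "LossHistory", "AdamState", "train_step", "train",
           "samples_from_manifest", "plot_history"]

logger = logging.getLogger(__name__)

HISTORY_COLUMNS = ["hair", "non_hair", "normalized", "ssim", "tv", "total"]


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 1e-4
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    iterations: int = 200
    batch_size: int = 4
    weights: LossWeights = field(default_factory=LossWeights)
    mask_threshold: float = 0.1
    seed: int = 0
    checkpoint_every: int = 0  # 0 = only final
    device: str = "cpu"

    def __post_init__(self):
        # lr == 0 is allowed as a degenerate no-update diagnostic mode
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be >= 0")
        if self.iterations < 1 or self.batch_size < 1:
            raise ValueError("iterations and batch_size must be >= 1")


@dataclass
class LossHistory:
    """Per-iteration loss components; `total` is their weighted sum."""

    records: list[LossComponents] = field(default_factory=list)
    weights: LossWeights = field(default_factory=LossWeights)

    def append(self, comps: LossComponents) -> None:
        self.records.append(comps)

    def to_frame(self) -> pd.DataFrame:
        rows = [{**c.as_dict(), "total": total_loss(c, self.weights)}
                for c in self.records]
        return pd.DataFrame(rows, columns=HISTORY_COLUMNS)

    def save(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def load(cls, path, weights: LossWeights | None = None) -> "LossHistory":
        df = pd.read_csv(path)
        hist = cls(weights=weights or LossWeights())
        for _, r in df.iterrows():
            hist.append(LossComponents(r["hair"], r["non_hair"],
                                       r["normalized"], r["ssim"], r["tv"]))
        return hist


class AdamState:
    """First/second-moment accumulators for every parameter."""

    def __init__(self, state: ModelState):
        self.m = {k: np.zeros_like(p.value) for k, p in state.params.items()}
        self.v = {k: np.zeros_like(p.value) for k, p in state.params.items()}
        self.t = 0

    def update(self, state: ModelState, config: TrainConfig) -> None:
        self.t += 1
        b1, b2 = config.beta1, config.beta2
        bias1 = 1.0 - b1 ** self.t
        bias2 = 1.0 - b2 ** self.t
        for k, p in state.params.items():
            g = p.grad
            if g is None:
                continue
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / bias1
            vhat = self.v[k] / bias2
            p.value -= config.learning_rate * mhat / (np.sqrt(vhat) + config.eps)
            p.grad = None


def _batch_arrays(batch: list[PairedSample], mask_threshold: float):
    hairy = np.stack([s.hairy for s in batch])           # (N,H,W,3)
    clean = np.stack([s.clean for s in batch]).transpose(0, 3, 1, 2)
    masks = np.stack([binarize_mask(s.mask, mask_threshold) for s in batch])
    return hairy, clean, masks


def train_step(state: ModelState, batch: list[PairedSample],
               config: TrainConfig, adam: AdamState | None = None
               ) -> tuple[ModelState, LossComponents]:
    """One forward/backward/Adam step on a mini-batch; updates in place."""
    if not batch:
        raise ValueError("empty batch")
    adam = adam or AdamState(state)
    hairy, clean, masks = _batch_arrays(batch, config.mask_threshold)
    pred = forward(state, hairy)
    total, comps = composite_loss(pred, clean, masks, config.weights)
    if not np.isfinite(total.item()):
        raise FloatingPointError(
            f"non-finite training loss at step {adam.t + 1}: {comps}")
    total.backward()
    adam.update(state, config)
    return state, comps


def train(state: ModelState, samples, config: TrainConfig,
          out_dir: str | Path | None = None
          ) -> tuple[ModelState, LossHistory]:
    """Optimize for config.iterations steps over seeded-shuffled batches.

    `samples` is either a list of PairedSample or a (manifest, )-style
    DataFrame with file paths; with a manifest, only rows whose `split`
    column says "train" are used.
    """
    if isinstance(samples, pd.DataFrame):
        samples = samples_from_manifest(samples, split="train",
                                        mask_threshold=config.mask_threshold)
    samples = list(samples)
    if not samples:
        raise ValueError("no training samples")
    rng = np.random.default_rng(config.seed)
    adam = AdamState(state)
    history = LossHistory(weights=config.weights)
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)

    order: list[int] = []
    for it in range(config.iterations):
        while len(order) < config.batch_size:
            order.extend(rng.permutation(len(samples)).tolist())
        idx, order = order[:config.batch_size], order[config.batch_size:]
        batch = [samples[i] for i in idx]
        state, comps = train_step(state, batch, config, adam)
        history.append(comps)
        if out_dir is not None and config.checkpoint_every and \
                (it + 1) % config.checkpoint_every == 0:
            save_checkpoint(state, out_dir / f"ckpt_{it + 1:06d}")
    if out_dir is not None:
        save_checkpoint(state, out_dir / "ckpt_final")
        history.save(out_dir / "loss_history.csv")
    return state, history


def samples_from_manifest(manifest: pd.DataFrame, split: str | None = None,
                          mask_threshold: float = 0.1) -> list[PairedSample]:
    """Load PairedSamples for the given split from a dataset manifest."""
    rows = manifest if split is None else manifest[manifest["split"] == split]
    if split is not None and "split" not in manifest.columns:
        raise ValueError("manifest has no split column")
    out = []
    for _, r in rows.iterrows():
        clean = load_image(r["clean_path"], size=None)
        hairy = load_image(r["hairy_path"], size=None)
        mask = load_mask(r["mask_path"])
        out.append(PairedSample(clean=clean, hairy=hairy, mask=mask,
                                meta={"sample_id": r["sample_id"]}))
    return out


def plot_history(history: LossHistory, path: str | Path) -> None:
    """Loss-history chart: the five components plus the total per iteration."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = history.to_frame()
    fig, ax = plt.subplots(figsize=(7, 4.5))
    for col in ["hair", "non_hair", "normalized", "ssim", "tv"]:
        ax.plot(df.index + 1, df[col], label=col, linewidth=1)
    ax.plot(df.index + 1, df["total"], label="total", color="black", linewidth=2)
    ax.set_xlabel("training iteration")
    ax.set_ylabel("loss")
    ax.set_yscale("log")
    ax.legend(ncol=3, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
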