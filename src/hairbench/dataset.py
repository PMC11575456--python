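"""Dataset assembly: synthetic skin fixtures, pairing, density bins, splits.

The benchmark pairs hair-free lesion images with procedurally generated hair
masks and their composites.  Clean images come either from a user-supplied
directory of dermoscopic photographs or from the built-in synthetic-skin
generator (skin-tone background, one irregular elliptical pigmented lesion,
texture noise) so the whole pipeline runs without any external data.

Hair density bins follow the benchmark convention: low = 1-5 hairs, medium =
6-20, high = 21-40; under a uniform 1-40 hair count these bins carry
12.5% / 37.5% / 50% of the samples.  The train/test split takes
ceil(train_fraction * N) samples for training (80% of 1064 -> 852/212) and
keys on the clean-image id so no clean image leaks across the split.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, replace
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from skimage.transform import resize

from .compositing import CompositeConfig, composite
from .masks import MaskGenConfig, generate_mask, save_mask

__all__ = [
    "SyntheticSkinConfig",
    "SKIN_TONE_PRESETS",
    "generate_synthetic_skin",
    "classify_density",
    "split_train_test",
    "build_dataset",
    "load_manifest",
    "save_manifest",
    "load_image",
]

logger = logging.getLogger(__name__)

DENSITY_BINS = {"low": (1, 5), "medium": (6, 20), "high": (21, 40)}

# Approximate sRGB skin tones from very light to very dark.
SKIN_TONE_PRESETS = {
    "light": (0.96, 0.80, 0.69),
    "medium_light": (0.92, 0.72, 0.58),
    "medium": (0.85, 0.62, 0.45),
    "medium_dark": (0.65, 0.44, 0.30),
    "dark": (0.42, 0.27, 0.18),
}


@dataclass(frozen=True)
class SyntheticSkinConfig:
    """Synthetic hair-free lesion image: skin background + pigmented lesion."""

    canvas_size: tuple[int, int] = (256, 256)
    skin_tone: str | tuple[float, float, float] = "medium_light"
    lesion_radius_range: tuple[float, float] = (40.0, 80.0)
    border_irregularity: float = 0.15
    pigment_noise: float = 0.03
    shading_amplitude: float = 0.04
    seed: int = 0

    def tone_rgb(self) -> np.ndarray:
        tone = SKIN_TONE_PRESETS[self.skin_tone] \
            if isinstance(self.skin_tone, str) else self.skin_tone
        rgb = np.asarray(tone, dtype=np.float64)
        if rgb.min() < 0 or rgb.max() > 1:
            raise ValueError("skin tone channels must lie in [0, 1]")
        return rgb

    def __post_init__(self):
        h, w = self.canvas_size
        if self.lesion_radius_range[1] > min(h, w) / 2:
            raise ValueError("lesion must fit within the canvas")
        if self.border_irregularity < 0 or self.pigment_noise < 0:
            raise ValueError("irregularity/noise must be >= 0")


def generate_synthetic_skin(config: SyntheticSkinConfig,
                            rng: np.random.Generator) -> np.ndarray:
    """Render one clean lesion image, values in [0, 1].

    The lesion is an ellipse whose radius is modulated by a low-order random
    Fourier series (border irregularity); its interior is darker brown
    pigment with fine noise.  The skin background carries low-frequency
    shading so it is not perfectly flat.
    """
    h, w = config.canvas_size
    tone = config.tone_rgb()
    img = np.broadcast_to(tone, (h, w, 3)).copy()

    # low-frequency shading on the skin
    if config.shading_amplitude > 0:
        shade = gaussian_filter(rng.standard_normal((h, w)), min(h, w) / 8)
        rngmax = np.abs(shade).max()
        if rngmax > 0:
            shade = shade / rngmax * config.shading_amplitude
        img *= (1.0 + shade)[:, :, None]

    # lesion geometry
    cy = h / 2 + rng.uniform(-h * 0.08, h * 0.08)
    cx = w / 2 + rng.uniform(-w * 0.08, w * 0.08)
    ry = rng.uniform(*config.lesion_radius_range)
    rx = rng.uniform(*config.lesion_radius_range)
    phi = rng.uniform(0, np.pi)
    amps = rng.uniform(-1, 1, size=5)
    phases = rng.uniform(0, 2 * np.pi, size=5)

    yy, xx = np.mgrid[0:h, 0:w]
    dy, dx = yy - cy, xx - cx
    u = np.cos(phi) * dx + np.sin(phi) * dy
    v = -np.sin(phi) * dx + np.cos(phi) * dy
    rho = np.hypot(u / rx, v / ry)  # 1 on the unperturbed boundary
    theta = np.arctan2(v, u)
    wobble = sum(a * np.cos((k + 2) * theta + p)
                 for k, (a, p) in enumerate(zip(amps, phases)))
    boundary = 1.0 + config.border_irregularity * wobble / len(amps)
    # soft edge ~1.5 px wide so the border is not aliased
    edge_scale = 1.5 / float(min(rx, ry))
    z = np.clip((rho - boundary) / max(edge_scale, 1e-6), -60.0, 60.0)
    inside = 1.0 / (1.0 + np.exp(z))

    pigment = tone * np.array([0.45, 0.30, 0.28])  # dark brown relative to skin
    lesion = np.broadcast_to(pigment, (h, w, 3)).copy()
    if config.pigment_noise > 0:
        lesion += rng.standard_normal((h, w, 3)) * config.pigment_noise
        lesion += (gaussian_filter(rng.standard_normal((h, w)), 6)
                   * config.pigment_noise * 2)[:, :, None]
    img = (1.0 - inside[:, :, None]) * img + inside[:, :, None] * lesion
    return np.clip(img, 0.0, 1.0)


def classify_density(n_hairs: int) -> str:
    """Map a hair count to its density class: 1-5 low, 6-20 medium, 21-40 high."""
    n = int(n_hairs)
    for name, (lo, hi) in DENSITY_BINS.items():
        if lo <= n <= hi:
            return name
    raise ValueError(f"hair count {n} outside the supported range 1-40")


def split_train_test(manifest: pd.DataFrame, train_fraction: float = 0.8,
                     seed: int = 0) -> pd.DataFrame:
    """Assign train/test by seeded shuffle; train size = ceil(fraction * N).

    The shuffle operates on unique clean-image ids (column `clean_id`, or
    `sample_id` when absent) so that no clean image appears in both splits.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must be in (0, 1)")
    if len(manifest) == 0:
        raise ValueError("empty manifest")
    out = manifest.copy()
    key = "clean_id" if "clean_id" in out.columns else "sample_id"
    ids = list(dict.fromkeys(out[key]))  # stable order
    rng = np.random.default_rng(seed)
    order = [ids[i] for i in rng.permutation(len(ids))]
    n_train_ids = math.ceil(train_fraction * len(order))
    train_ids = set(order[:n_train_ids])
    out["split"] = [("train" if i in train_ids else "test") for i in out[key]]
    return out


def _path_columns(df: pd.DataFrame):
    return [c for c in df.columns if c.endswith("_path")]


def save_manifest(manifest: pd.DataFrame, path: str | Path) -> None:
    """Write the manifest CSV; file paths under the CSV's directory are
    stored relative to it so the dataset directory stays relocatable."""
    path = Path(path)
    root = path.resolve().parent
    out = manifest.copy()
    for col in _path_columns(out):
        out[col] = [
            p.relative_to(root).as_posix() if (p := Path(v).resolve()).is_relative_to(root)
            else str(v)
            for v in out[col]
        ]
    out.to_csv(path, index=False)


def load_manifest(path: str | Path) -> pd.DataFrame:
    """Read a manifest CSV, resolving relative file paths against its
    directory."""
    path = Path(path)
    df = pd.read_csv(path)
    root = path.resolve().parent
    for col in _path_columns(df):
        df[col] = [str(root / v) if not Path(v).is_absolute() else v
                   for v in df[col]]
    return df


def load_image(path: str | Path, size: tuple[int, int] | None = (256, 256)) -> np.ndarray:
    """Read an RGB image as float64 in [0, 1], resized with bilinear filtering."""
    img = iio.imread(path)
    if img.ndim == 2:
        img = np.stack([img] * 3, axis=-1)
    img = img[:, :, :3].astype(np.float64) / 255.0
    if size is not None and img.shape[:2] != tuple(size):
        img = resize(img, size, order=1, anti_aliasing=True, preserve_range=True)
    return np.clip(img, 0.0, 1.0)


def _iter_clean_images(clean_source, n_samples: int, canvas: tuple[int, int],
                       rng: np.random.Generator):
    """Yield (clean_id, image) pairs from a directory or the skin generator."""
    if isinstance(clean_source, SyntheticSkinConfig):
        cfg = replace(clean_source, canvas_size=canvas)
        tones = list(SKIN_TONE_PRESETS)
        for i in range(n_samples):
            tone = tones[int(rng.integers(len(tones)))]
            yield f"skin{i:05d}", generate_synthetic_skin(
                replace(cfg, skin_tone=tone), rng)
        return
    paths = sorted(p for p in Path(clean_source).iterdir()
                   if p.suffix.lower() in {".png", ".jpg", ".jpeg"})
    if not paths:
        raise ValueError(f"no PNG/JPEG images found in {clean_source}")
    produced = 0
    i = 0
    while produced < n_samples:
        p = paths[i % len(paths)]
        i += 1
        try:
            img = load_image(p, canvas)
        except Exception as exc:  # unreadable file: skip with warning
            logger.warning("skipping unreadable clean image %s: %s", p, exc)
            paths = [q for q in paths if q != p]
            if not paths:
                raise ValueError("no readable clean images left") from exc
            continue
        yield p.stem, img
        produced += 1


def build_dataset(clean_source, n_samples: int, out_dir: str | Path,
                  mask_config: MaskGenConfig | None = None,
                  composite_config: CompositeConfig | None = None,
                  seed: int = 0, train_fraction: float = 0.8) -> pd.DataFrame:
    """Generate n_samples paired (clean, hairy, mask) triples on disk.

    `clean_source` is either a directory of hair-free images or a
    SyntheticSkinConfig.  Returns the manifest with density classes and the
    train/test split; also writes manifest.csv and a JSON config snapshot.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    mask_config = mask_config or MaskGenConfig()
    composite_config = composite_config or CompositeConfig()
    out_dir = Path(out_dir)
    for sub in ("clean", "hairy", "masks"):
        (out_dir / sub).mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    rows = []
    for idx, (clean_id, clean) in enumerate(
            _iter_clean_images(clean_source, n_samples, mask_config.canvas_size, rng)):
        sample_id = f"s{idx:05d}"
        mask = generate_mask(mask_config, rng)
        pair = composite(clean, mask, composite_config, rng)
        clean_path = out_dir / "clean" / f"{sample_id}.png"
        hairy_path = out_dir / "hairy" / f"{sample_id}.png"
        mask_path = out_dir / "masks" / f"{sample_id}.png"
        iio.imwrite(clean_path, np.round(pair.clean * 255).astype(np.uint8))
        iio.imwrite(hairy_path, np.round(pair.hairy * 255).astype(np.uint8))
        save_mask(mask, mask_path)
        rows.append({
            "sample_id": sample_id,
            "clean_id": clean_id,
            "clean_path": str(clean_path.resolve()),
            "hairy_path": str(hairy_path.resolve()),
            "mask_path": str(mask_path.resolve()),
            "n_hairs": mask.strand_count,
            "density_class": classify_density(mask.strand_count),
        })
    if not rows:
        raise ValueError("dataset build produced no samples")
    manifest = split_train_test(pd.DataFrame(rows), train_fraction, seed)
    save_manifest(manifest, out_dir / "manifest.csv")
    snapshot = {
        "n_samples": n_samples,
        "seed": seed,
        "train_fraction": train_fraction,
        "mask_config": {k: (list(v) if isinstance(v, tuple) else v)
                        for k, v in vars(mask_config).items()},
        "composite_config": vars(composite_config).copy(),
        "clean_source": (str(clean_source)
                         if not isinstance(clean_source, SyntheticSkinConfig)
                         else "synthetic-skin"),
    }
    (out_dir / "config.json").write_text(json.dumps(snapshot, indent=1))
    return manifest
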