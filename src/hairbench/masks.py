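"""Procedural hair-mask generation from cubic Bezier strands.

Each synthetic hair is a cubic Bezier curve defined by four control points,
rasterized as an anti-aliased stroke of 1-4 px thickness and softened with a
Gaussian blur, mimicking slightly out-of-focus hairs in dermoscopic images.
Strand geometry (control points, arc length 100-900 px, thickness) lives on a
high-resolution working canvas (default 1024x1024) so the full length range
remains meaningful; the finished mask is downscaled to the model's canvas
size (default 256x256).

Coordinates are (row, col), 0-based, with pixel centers at integer positions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.transform import resize

__all__ = [
    "StrandSpec",
    "MaskGenConfig",
    "HairMask",
    "bezier_point",
    "bezier_polyline",
    "sample_strand_spec",
    "rasterize_strand",
    "generate_mask",
    "binarize_mask",
    "save_mask",
    "load_mask",
]


# --------------------------------------------------------------------- types

@dataclass(frozen=True)
class StrandSpec:
    """One hair strand: four Bezier control points, thickness, arc length.

    Control points are (row, col) in working-canvas pixels; `arc_length` is
    the polyline arc length of the sampled curve, also in working pixels.
    """

    control_points: np.ndarray  # (4, 2) float
    thickness: int
    arc_length: float

    def __post_init__(self):
        cps = np.asarray(self.control_points, dtype=np.float64)
        if cps.shape != (4, 2):
            raise ValueError("a cubic strand needs exactly four 2-D control points")
        object.__setattr__(self, "control_points", cps)

    def to_json(self) -> dict:
        return {
            "control_points": self.control_points.tolist(),
            "thickness": int(self.thickness),
            "arc_length": float(self.arc_length),
        }

    @classmethod
    def from_json(cls, d: dict) -> "StrandSpec":
        return cls(np.asarray(d["control_points"]), int(d["thickness"]),
                   float(d["arc_length"]))


@dataclass(frozen=True)
class MaskGenConfig:
    """Parameters of the hair-mask generator.

    Defaults follow the benchmark conditions: 1-40 hairs per mask, arc
    lengths uniform on [100, 900] px, thickness uniform on {1,2,3,4} px, all
    at working resolution.
    """

    canvas_size: tuple[int, int] = (256, 256)
    working_size: tuple[int, int] = (1024, 1024)
    num_hairs_range: tuple[int, int] = (1, 40)
    length_range: tuple[float, float] = (100.0, 900.0)
    thickness_range: tuple[int, int] = (1, 4)
    blur_sigma: float = 0.8
    curve_samples: int = 100
    margin_frac: float = 0.15
    seed: int = 0

    def __post_init__(self):
        if self.num_hairs_range[0] < 1 or self.num_hairs_range[1] < self.num_hairs_range[0]:
            raise ValueError("num_hairs_range must be a non-empty range with min >= 1")
        if self.length_range[0] <= 0 or self.length_range[1] < self.length_range[0]:
            raise ValueError("length_range must be a non-empty positive range")
        if self.thickness_range[0] < 1 or self.thickness_range[1] < self.thickness_range[0]:
            raise ValueError("thickness_range must be a non-empty range with min >= 1")
        if self.blur_sigma <= 0:
            raise ValueError("blur_sigma must be > 0")
        if self.curve_samples < 2:
            raise ValueError("curve_samples must be >= 2")

    @classmethod
    def scaled_to(cls, canvas_size: tuple[int, int], **overrides) -> "MaskGenConfig":
        """Benchmark geometry rescaled to another canvas size.

        Keeps the 4x supersampled working canvas and scales the arc-length
        range by canvas/256, so hairs have the same apparent width and
        relative length at any output resolution.
        """
        s = min(canvas_size) / 256.0
        defaults = dict(
            canvas_size=tuple(canvas_size),
            working_size=(canvas_size[0] * 4, canvas_size[1] * 4),
            length_range=(100.0 * s, 900.0 * s),
        )
        defaults.update(overrides)
        return cls(**defaults)


@dataclass
class HairMask:
    """Soft hair mask in [0, 1] plus the strand specs that produced it.

    `layers`, when present, holds one blurred per-strand mask at canvas
    resolution; the combined mask is their pointwise maximum, so a strand
    layer is zero wherever the combined mask is zero.
    """

    values: np.ndarray
    strand_specs: list[StrandSpec] = field(default_factory=list)
    layers: list[np.ndarray] | None = None
    working_size: tuple[int, int] | None = None

    @property
    def strand_count(self) -> int:
        return len(self.strand_specs)


# ----------------------------------------------------------------- geometry

def bezier_point(control_points, t: float) -> np.ndarray:
    """Evaluate a cubic Bezier curve at parameter t in [0, 1]."""
    cps = np.asarray(control_points, dtype=np.float64)
    if cps.shape != (4, 2):
        raise ValueError("cubic Bezier needs exactly four 2-D control points")
    t = float(t)
    if not 0.0 <= t <= 1.0:
        raise ValueError(f"t={t} outside [0, 1]")
    u = 1.0 - t
    return (u ** 3 * cps[0] + 3 * u ** 2 * t * cps[1]
            + 3 * u * t ** 2 * cps[2] + t ** 3 * cps[3])


def bezier_polyline(control_points, n_samples: int) -> np.ndarray:
    """Sample the curve at n_samples uniformly spaced parameter values."""
    cps = np.asarray(control_points, dtype=np.float64)
    if cps.shape != (4, 2):
        raise ValueError("cubic Bezier needs exactly four 2-D control points")
    t = np.linspace(0.0, 1.0, n_samples)[:, None]
    u = 1.0 - t
    return (u ** 3 * cps[0] + 3 * u ** 2 * t * cps[1]
            + 3 * u * t ** 2 * cps[2] + t ** 3 * cps[3])


def _polyline_length(points: np.ndarray) -> float:
    return float(np.sqrt(((points[1:] - points[:-1]) ** 2).sum(axis=1)).sum())


def sample_strand_spec(config: MaskGenConfig, rng: np.random.Generator) -> StrandSpec:
    """Draw one strand with uniform thickness and uniform arc length.

    Control points are sampled uniformly on a margin-extended working canvas
    (hairs may enter or leave the field of view), then the control polygon is
    rescaled about its centroid to an arc length drawn uniformly from the
    configured range.  Rescaling is exact for arc length — a uniform scaling
    of the control points scales the whole curve — so no rejection loop is
    needed.
    """
    h, w = config.working_size
    mr, mc = config.margin_frac * h, config.margin_frac * w
    thickness = int(rng.integers(config.thickness_range[0],
                                 config.thickness_range[1] + 1))
    while True:
        cps = np.column_stack([rng.uniform(-mr, h - 1 + mr, size=4),
                               rng.uniform(-mc, w - 1 + mc, size=4)])
        raw_len = _polyline_length(bezier_polyline(cps, config.curve_samples))
        if raw_len > 1e-9:
            break
    target = float(rng.uniform(*config.length_range))
    centroid = cps.mean(axis=0)
    cps = centroid + (cps - centroid) * (target / raw_len)
    return StrandSpec(cps, thickness, target)


# -------------------------------------------------------------- rasterizing

def _segment_distance_field(dist: np.ndarray, p: np.ndarray, q: np.ndarray,
                            margin: float) -> None:
    """Min-update `dist` with point-to-segment distances inside a local bbox."""
    h, w = dist.shape
    r0 = max(int(np.floor(min(p[0], q[0]) - margin)), 0)
    r1 = min(int(np.ceil(max(p[0], q[0]) + margin)), h - 1)
    c0 = max(int(np.floor(min(p[1], q[1]) - margin)), 0)
    c1 = min(int(np.ceil(max(p[1], q[1]) + margin)), w - 1)
    if r0 > r1 or c0 > c1:
        return
    rows = np.arange(r0, r1 + 1, dtype=np.float64)[:, None]
    cols = np.arange(c0, c1 + 1, dtype=np.float64)[None, :]
    dr, dc = q[0] - p[0], q[1] - p[1]
    seg2 = dr * dr + dc * dc
    if seg2 < 1e-18:
        d = np.hypot(rows - p[0], cols - p[1])
    else:
        t = ((rows - p[0]) * dr + (cols - p[1]) * dc) / seg2
        np.clip(t, 0.0, 1.0, out=t)
        d = np.hypot(rows - (p[0] + t * dr), cols - (p[1] + t * dc))
    np.minimum(dist[r0:r1 + 1, c0:c1 + 1], d, out=dist[r0:r1 + 1, c0:c1 + 1])


def _strand_coverage(spec: StrandSpec, shape: tuple[int, int],
                     origin: tuple[float, float],
                     curve_samples: int) -> np.ndarray:
    """Anti-aliased stroke coverage of one strand on a local canvas.

    Coverage at a pixel is clip(thickness/2 + 1/2 - d, 0, 1) with d the
    distance from the pixel center to the sampled Bezier polyline.
    """
    pts = bezier_polyline(spec.control_points, curve_samples) - np.asarray(origin)
    r = spec.thickness / 2.0
    dist = np.full(shape, np.inf)
    for k in range(len(pts) - 1):
        _segment_distance_field(dist, pts[k], pts[k + 1], r + 1.0)
    return np.clip(r + 0.5 - dist, 0.0, 1.0)


def rasterize_strand(canvas: np.ndarray, spec: StrandSpec,
                     curve_samples: int = 100) -> np.ndarray:
    """Draw one strand onto `canvas` as an anti-aliased stroke.

    Strokes merge into the canvas by pointwise maximum, which saturates at
    1; pixels outside the canvas are clipped silently.  Returns the updated
    canvas (modified in place).
    """
    coverage = _strand_coverage(spec, canvas.shape, (0.0, 0.0), curve_samples)
    np.maximum(canvas, coverage, out=canvas)
    return canvas


def _downscale(img: np.ndarray, out_shape: tuple[int, int]) -> np.ndarray:
    """Downscale to out_shape; exact block mean for integer factors."""
    h, w = img.shape
    oh, ow = out_shape
    if (h, w) == (oh, ow):
        return img
    if h % oh == 0 and w % ow == 0:
        return img.reshape(oh, h // oh, ow, w // ow).mean(axis=(1, 3))
    return resize(img, out_shape, order=1, anti_aliasing=True,
                  preserve_range=True)


def generate_mask(config: MaskGenConfig, rng: np.random.Generator,
                  keep_layers: bool = True) -> HairMask:
    """Generate one hair mask.

    Starts from an all-zero working canvas, draws n strands (n uniform on
    num_hairs_range), blurs each strand with a Gaussian of `blur_sigma`,
    downscales to `canvas_size` and clamps to [0, 1].  The combined mask is
    the pointwise maximum over per-strand layers, so overlapping strands
    saturate rather than add.
    """
    n = int(rng.integers(config.num_hairs_range[0], config.num_hairs_range[1] + 1))
    wh, ww = config.working_size
    ch, cw = config.canvas_size
    integer_scale = wh % ch == 0 and ww % cw == 0
    sr, sc = (wh // ch, ww // cw) if integer_scale else (1, 1)
    blur_margin = int(np.ceil(4 * config.blur_sigma)) + 1

    specs: list[StrandSpec] = []
    layers: list[np.ndarray] = []
    combined = np.zeros(config.canvas_size)
    for _ in range(n):
        spec = sample_strand_spec(config, rng)
        specs.append(spec)
        pad = spec.thickness / 2.0 + 1.0 + blur_margin
        if integer_scale:
            # work only inside the strand's bounding box, aligned to the
            # downscale factor so the block mean stays exact
            pts = bezier_polyline(spec.control_points, config.curve_samples)
            r0 = int(np.floor((pts[:, 0].min() - pad) / sr)) * sr
            r1 = int(np.ceil((pts[:, 0].max() + pad + 1) / sr)) * sr
            c0 = int(np.floor((pts[:, 1].min() - pad) / sc)) * sc
            c1 = int(np.ceil((pts[:, 1].max() + pad + 1) / sc)) * sc
            r0, r1 = max(r0, 0), min(r1, wh)
            c0, c1 = max(c0, 0), min(c1, ww)
            layer = np.zeros(config.canvas_size)
            if r1 > r0 and c1 > c0:
                sub = _strand_coverage(spec, (r1 - r0, c1 - c0), (r0, c0),
                                       config.curve_samples)
                sub = gaussian_filter(sub, config.blur_sigma, mode="constant")
                block = sub.reshape((r1 - r0) // sr, sr,
                                    (c1 - c0) // sc, sc).mean(axis=(1, 3))
                layer[r0 // sr:r1 // sr, c0 // sc:c1 // sc] = np.clip(block, 0.0, 1.0)
        else:
            work = np.zeros(config.working_size)
            rasterize_strand(work, spec, config.curve_samples)
            work = gaussian_filter(work, config.blur_sigma, mode="constant")
            layer = np.clip(_downscale(work, config.canvas_size), 0.0, 1.0)
        layers.append(layer)
        np.maximum(combined, layer, out=combined)
    return HairMask(values=combined, strand_specs=specs,
                    layers=layers if keep_layers else None,
                    working_size=config.working_size)


def binarize_mask(mask, threshold: float = 0.1) -> np.ndarray:
    """Boolean hair/non-hair partition: a pixel is hair iff value >= threshold."""
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie strictly inside (0, 1)")
    values = mask.values if isinstance(mask, HairMask) else np.asarray(mask)
    return values >= threshold


# ----------------------------------------------------------------------- io

def save_mask(mask: HairMask, path: str | Path) -> None:
    """Write an 8-bit PNG plus a JSON sidecar with the strand specs."""
    path = Path(path)
    iio.imwrite(path, np.round(mask.values * 255.0).astype(np.uint8))
    meta = {
        "strand_count": mask.strand_count,
        "working_size": list(mask.working_size) if mask.working_size else None,
        "strands": [s.to_json() for s in mask.strand_specs],
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def load_mask(path: str | Path) -> HairMask:
    path = Path(path)
    values = iio.imread(path).astype(np.float64) / 255.0
    specs: list[StrandSpec] = []
    working = None
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        specs = [StrandSpec.from_json(d) for d in meta["strands"]]
        working = tuple(meta["working_size"]) if meta.get("working_size") else None
    return HairMask(values=values, strand_specs=specs, working_size=working)
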