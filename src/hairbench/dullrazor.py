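"""Dullrazor-style morphological hair removal baseline.

Classic dark-hair removal: per color channel, a grayscale morphological
closing with line structuring elements at 0, 45, 90 and 135 degrees lifts
thin dark structures toward the surrounding skin; pixels where the closing
response (closed - original, maximum over orientations and channels)
exceeds a threshold form the hair mask.  Small connected components are
discarded, hair pixels are replaced by linear interpolation between the two
nearest non-hair pixels along the normal of the locally dominant hair
orientation, and the replaced pixels are smoothed with a median filter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import distance_transform_edt, median_filter
from skimage.morphology import closing, remove_small_objects

__all__ = ["DullrazorConfig", "line_footprint", "dullrazor"]


@dataclass(frozen=True)
class DullrazorConfig:
    line_length: int = 9
    detection_threshold: float = 0.1
    min_component_size: int = 10
    median_size: int = 5
    max_march: int = 30  # search range (px) for interpolation endpoints

    def __post_init__(self):
        if self.line_length < 3:
            raise ValueError("line_length must be >= 3")
        if not 0 < self.detection_threshold < 1:
            raise ValueError("detection_threshold must be in (0, 1)")


def line_footprint(length: int, angle_deg: int) -> np.ndarray:
    """Binary line structuring element at 0, 45, 90 or 135 degrees."""
    if angle_deg % 180 == 0:
        return np.ones((1, length), dtype=bool)
    if angle_deg % 180 == 90:
        return np.ones((length, 1), dtype=bool)
    eye = np.eye(length, dtype=bool)
    if angle_deg % 180 == 45:
        return eye[::-1]  # anti-diagonal: rises left to right
    if angle_deg % 180 == 135:
        return eye
    raise ValueError("only 0/45/90/135 degree lines are supported")


_ANGLES = (0, 45, 90, 135)
# step along the normal of each hair orientation (row, col)
_NORMALS = {0: (1, 0), 45: (1, 1), 90: (0, 1), 135: (1, -1)}


def _interpolate_hair_pixels(channel: np.ndarray, mask: np.ndarray,
                             orient: np.ndarray, max_march: int) -> np.ndarray:
    """Replace masked pixels by interpolating along the local normal."""
    out = channel.copy()
    h, w = channel.shape
    rows, cols = np.nonzero(mask)
    for r, c in zip(rows, cols):
        dr, dc = _NORMALS[_ANGLES[orient[r, c]]]
        ends = []
        for sign in (1, -1):
            rr, cc = r, c
            for step in range(1, max_march + 1):
                rr, cc = r + sign * step * dr, c + sign * step * dc
                if not (0 <= rr < h and 0 <= cc < w):
                    break
                if not mask[rr, cc]:
                    ends.append((step, channel[rr, cc]))
                    break
        if len(ends) == 2:
            (d1, v1), (d2, v2) = ends
            out[r, c] = (v1 * d2 + v2 * d1) / (d1 + d2)
        elif len(ends) == 1:
            out[r, c] = ends[0][1]
        # else: leave as is; nearest-valid fallback below
    return out


def dullrazor(image: np.ndarray, config: DullrazorConfig | None = None
              ) -> tuple[np.ndarray, np.ndarray]:
    """Remove dark hairs from an RGB image in [0, 1].

    Returns (cleaned image, detected boolean hair mask).
    """
    config = config or DullrazorConfig()
    image = np.asarray(image, dtype=np.float64)
    single = image.ndim == 2
    if single:
        image = image[:, :, None]
    h, w, nchan = image.shape

    footprints = [line_footprint(config.line_length, a) for a in _ANGLES]
    # response per orientation = max over channels of (closing - original)
    responses = np.zeros((len(_ANGLES), h, w))
    for ai, fp in enumerate(footprints):
        for ch in range(nchan):
            closed = closing(image[:, :, ch], fp)
            np.maximum(responses[ai], closed - image[:, :, ch],
                       out=responses[ai])
    response = responses.max(axis=0)
    orient = responses.argmax(axis=0)  # dominant hair orientation index

    mask = response > config.detection_threshold
    if config.min_component_size > 1:
        # objects strictly smaller than min_component_size are dropped
        mask = remove_small_objects(mask, max_size=config.min_component_size - 1)

    if not mask.any():
        out = image[:, :, 0] if single else image
        return out.copy(), mask

    cleaned = np.empty_like(image)
    for ch in range(nchan):
        cleaned[:, :, ch] = _interpolate_hair_pixels(
            image[:, :, ch], mask, orient, config.max_march)
    # pixels the directional march could not resolve: copy nearest non-hair
    unresolved = mask & (cleaned == image).all(axis=2) if nchan > 1 else \
        mask & (cleaned[:, :, 0] == image[:, :, 0])
    if unresolved.any():
        _, (ir, ic) = distance_transform_edt(mask, return_indices=True)
        cleaned[unresolved] = image[ir[unresolved], ic[unresolved]]

    # median smoothing applied to the replaced pixels only
    if config.median_size > 1:
        for ch in range(nchan):
            med = median_filter(cleaned[:, :, ch], size=config.median_size)
            cleaned[:, :, ch][mask] = med[mask]

    out = cleaned[:, :, 0] if single else cleaned
    return np.clip(out, 0.0, 1.0), mask
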