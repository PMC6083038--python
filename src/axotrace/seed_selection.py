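"""Seed-point generation for semi-automatic axon tracing.

Seeds are candidate starting points lying on axon centerlines, found from a
3D stack in five steps:

1. maximum-intensity projection of the stack onto the x-y plane;
2. band thresholding of the projection with user-set lower/upper bounds
   (the one interactive step: the upper cut removes saturated artifacts);
3. Euclidean distance transform of the foreground, so that pixels on the
   axonal medial axis carry the highest local values;
4. local-maximum selection of the distance map within N x N windows to fix
   the seed (x, y) positions;
5. for each (x, y), the seed z is the brightest plane of that column.

The distance transform runs in 2D on the projection; boundary is taken with
8-connectivity (any foreground pixel touching background, including
diagonally, scores exactly 1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List

import numpy as np
from scipy import ndimage

from .volume_io import ConfocalStack

__all__ = [
    "SeedParams",
    "Seed",
    "max_intensity_projection",
    "binarize_band",
    "distance_transform",
    "local_maxima",
    "select_seeds",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SeedParams:
    """User-set thresholds and the local-maximum window size (pixels)."""

    lower_threshold: float
    upper_threshold: float
    window_n: int = 5

    def __post_init__(self) -> None:
        if not self.lower_threshold < self.upper_threshold:
            raise ValueError(
                f"lower_threshold ({self.lower_threshold}) must be < "
                f"upper_threshold ({self.upper_threshold})"
            )
        if self.window_n < 3 or self.window_n % 2 == 0:
            raise ValueError(f"window_n must be odd and >= 3, got {self.window_n}")


@dataclass(frozen=True)
class Seed:
    """A candidate tracing start point (integer voxel indices)."""

    x: int
    y: int
    z: int
    intensity: float
    distance_score: float


def max_intensity_projection(stack: ConfocalStack) -> np.ndarray:
    """Project the stack onto the x-y plane by the maximum over z."""
    return np.asarray(stack.intensities).max(axis=0)


def binarize_band(image: np.ndarray, params: SeedParams) -> np.ndarray:
    """Band-pass threshold: foreground iff lower <= value <= upper."""
    image = np.asarray(image)
    return (image >= params.lower_threshold) & (image <= params.upper_threshold)


def distance_transform(mask: np.ndarray) -> np.ndarray:
    """Score each foreground pixel by its Euclidean distance to background.

    Background pixels are 0.  Foreground pixels 8-adjacent to background
    score exactly 1; interior pixels carry the exact Euclidean distance (in
    pixels) to the nearest background pixel, so ridge pixels on the medial
    axis attain the highest local values.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim != 2:
        raise ValueError("mask must be 2D")
    if mask.all():
        raise ValueError("mask has no background pixel; distance is undefined")
    dist = ndimage.distance_transform_edt(mask)
    # clamp the 8-connected boundary (diagonal-only contacts score sqrt(2)) to 1
    near_bg = ndimage.maximum_filter(~mask, size=3, mode="constant", cval=False)
    dist[mask & near_bg] = 1.0
    return dist


def local_maxima(dist: np.ndarray, window_n: int) -> List[tuple]:
    """Local maxima of the distance map in N x N windows, with deterministic
    plateau handling.

    Candidates are pixels attaining the maximum of their centred
    ``window_n x window_n`` window.  They are then visited in order of
    decreasing distance score (ties broken by smaller ``(y, x)``) and
    accepted greedily unless an already accepted seed lies within the window
    (non-maximum suppression).  On ridge plateaus this yields seeds spaced by
    the window along the medial axis, so every axon receives interior seeds.

    Returns a list of ``(y, x)`` tuples.
    """
    dist = np.asarray(dist)
    half = window_n // 2
    wmax = ndimage.maximum_filter(dist, size=window_n, mode="constant", cval=0.0)
    ys, xs = np.nonzero((dist > 0) & (dist >= wmax))
    if ys.size == 0:
        return []
    vals = dist[ys, xs]
    order = np.lexsort((xs, ys, -vals))  # by -value, then y, then x
    taken = np.zeros(dist.shape, dtype=bool)
    out: List[tuple] = []
    for idx in order:
        y, x = int(ys[idx]), int(xs[idx])
        y0, y1 = max(0, y - half), min(dist.shape[0], y + half + 1)
        x0, x1 = max(0, x - half), min(dist.shape[1], x + half + 1)
        if taken[y0:y1, x0:x1].any():
            continue
        taken[y, x] = True
        out.append((y, x))
    return out


def select_seeds(stack: ConfocalStack, params: SeedParams) -> List[Seed]:
    """Run the five seed-selection steps and return seeds sorted by score.

    Seeds are ordered by decreasing distance score (ties by smaller (y, x)),
    the order in which the tracer consumes them.  An empty foreground (after
    banding) yields an empty list with a warning, not an error.
    """
    mip = max_intensity_projection(stack)
    mask = binarize_band(mip, params)
    if not mask.any():
        log.warning(
            "no foreground pixels in band [%g, %g]; returning no seeds",
            params.lower_threshold,
            params.upper_threshold,
        )
        return []
    dist = distance_transform(mask)
    coords = local_maxima(dist, params.window_n)
    intensities = stack.intensities
    seeds = []
    for y, x in coords:
        z = int(np.argmax(intensities[:, y, x]))
        seeds.append(
            Seed(
                x=x,
                y=y,
                z=z,
                intensity=float(intensities[z, y, x]),
                distance_score=float(dist[y, x]),
            )
        )
    seeds.sort(key=lambda s: (-s.distance_score, s.y, s.x))
    return seeds
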