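"""Recursive 3D vectorial tracking of axons and axonal density quantification.

Starting from seed points on axon centerlines (see ``seed_selection``), each
axon is followed through the smoothed volume ``G`` by repeated local
eigen-analysis of the Hessian:

1. the stack is convolved with an isotropic (in pixels) Gaussian of scale
   ``sigma`` to make it (almost) differentiable;
2. at the current point the 3x3 Hessian of ``G`` is estimated by second-order
   central differences and eigen-decomposed; a bright tube satisfies
   ``lambda2 ~ lambda3 << 0`` (cross-section) and ``lambda1 ~ 0`` (axis), and
   the minor eigenvector points along the axon;
3. after each step along the minor eigenvector, the point is pulled back onto
   the medial axis by searching a small disc in the plane normal to the
   travel direction for the intensity maximum (the centerline is the
   brightest in-plane point after Gaussian smoothing).

Tracing is bidirectional (a seed usually sits mid-axon), marches in pixel
units on the (possibly anisotropic) voxel grid, and converts to micrometres
only when emitting the final polyline.  Termination: loss of tubularity,
intensity below a floor, proximity to the volume boundary, stepping into a
voxel claimed by an earlier trace, or the step budget.

Axonal density is the summed traced length divided by the physical volume of
the stack, in um per um^3.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
from scipy import ndimage

from .seed_selection import Seed, SeedParams, select_seeds
from .volume_io import AxonTrace, ConfocalStack

__all__ = [
    "TracerParams",
    "HessianEigen",
    "BoundaryError",
    "smooth_volume",
    "hessian_eigen",
    "is_tubular",
    "medial_correct",
    "trace_from_seed",
    "trace_all",
    "axon_density",
]

log = logging.getLogger(__name__)


class BoundaryError(ValueError):
    """Raised when an operation would sample outside the volume."""


@dataclass(frozen=True)
class TracerParams:
    """Tunable parameters of the vectorial tracker.

    ``sigma`` (default 5 px) trades noise suppression against the merging of
    nearby tortuous segments.  ``hessian_window`` (default 9 px) sets the
    boundary margin and the medial-correction search disc so that the whole
    axon cross-section plus surrounding background is in view.  Tubularity is
    operationalised with two scale-free ratios: ``|l1|/|l3| <=
    tubularity_flatness_max`` (axis eigenvalue near zero) and
    ``min(|l2|,|l3|)/max(|l2|,|l3|) >= tubularity_ratio_min`` (round
    cross-section).  ``min_intensity`` is a floor on the smoothed intensity;
    when None it defaults to half the smoothed intensity at the seed, which
    adapts to the local attenuation introduced by smoothing.
    """

    sigma: float = 5.0
    hessian_window: int = 9
    step_size: float = 1.0
    tubularity_ratio_min: float = 0.5
    tubularity_flatness_max: float = 0.25
    min_intensity: Optional[float] = None
    max_steps: int = 10000
    min_nodes: int = 5

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if self.hessian_window < 3 or self.hessian_window % 2 == 0:
            raise ValueError("hessian_window must be odd and >= 3")
        if self.step_size <= 0:
            raise ValueError("step_size must be > 0")
        if self.max_steps < 1:
            raise ValueError("max_steps must be >= 1")


@dataclass(frozen=True)
class HessianEigen:
    """Eigen-system of the local Hessian, sorted by ascending magnitude.

    ``eigenvalues[0]`` is the minor eigenvalue (|l1| <= |l2| <= |l3|) and
    ``eigenvectors[:, i]`` the unit eigenvector for ``eigenvalues[i]``, in
    (z, y, x) component order.
    """

    eigenvalues: np.ndarray  # (3,)
    eigenvectors: np.ndarray  # (3, 3), columns

    @property
    def minor_vector(self) -> np.ndarray:
        return self.eigenvectors[:, 0]


def smooth_volume(stack, sigma: float) -> np.ndarray:
    """Gaussian-smooth the stack (isotropic in pixel units, reflective edges)."""
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    arr = stack.intensities if isinstance(stack, ConfocalStack) else np.asarray(stack)
    return ndimage.gaussian_filter(arr.astype(float), sigma=sigma, mode="reflect")


class _Interpolator:
    """Cubic-spline interpolation of a smoothed grid at fractional points."""

    def __init__(self, G: np.ndarray):
        self.shape = G.shape
        self.coeffs = ndimage.spline_filter(np.asarray(G, dtype=float), order=3)

    def __call__(self, pts_zyx: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(pts_zyx, dtype=float))
        return ndimage.map_coordinates(
            self.coeffs, pts.T, order=3, prefilter=False, mode="nearest"
        )


def _check_margin(shape: Sequence[int], point: np.ndarray, margin: float) -> bool:
    point = np.asarray(point, dtype=float)
    return bool(
        np.all(point >= margin) and np.all(point <= np.asarray(shape) - 1 - margin)
    )


# central-difference stencil offsets for the 3x3 Hessian, unit pixel spacing
_AXES = np.eye(3)


def _hessian_matrix(interp: _Interpolator, point: np.ndarray) -> np.ndarray:
    p = np.asarray(point, dtype=float)
    pts = [p]
    for i in range(3):
        pts += [p + _AXES[i], p - _AXES[i]]
    for i in range(3):
        for j in range(i + 1, 3):
            pts += [
                p + _AXES[i] + _AXES[j],
                p + _AXES[i] - _AXES[j],
                p - _AXES[i] + _AXES[j],
                p - _AXES[i] - _AXES[j],
            ]
    vals = interp(np.array(pts))
    f0 = vals[0]
    H = np.empty((3, 3))
    for i in range(3):
        fp, fm = vals[1 + 2 * i], vals[2 + 2 * i]
        H[i, i] = fp - 2.0 * f0 + fm
    k = 7
    for i in range(3):
        for j in range(i + 1, 3):
            fpp, fpm, fmp, fmm = vals[k : k + 4]
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / 4.0
            k += 4
    return H


def hessian_eigen(G: np.ndarray, point, window: int = 9) -> HessianEigen:
    """Eigen-decompose the Hessian of ``G`` at a (z, y, x) point.

    Second derivatives are unit-spacing central differences of the smoothed
    grid (interpolated with cubic splines at fractional positions); the
    window fixes the boundary margin required around the point.  Eigenvalues
    are sorted by ascending magnitude with matching orthonormal eigenvectors.
    """
    G = np.asarray(G)
    point = np.asarray(point, dtype=float)
    margin = window // 2
    if not _check_margin(G.shape, point, margin):
        raise BoundaryError(f"point {point} closer than {margin} voxels to a face")
    interp = G if isinstance(G, _Interpolator) else _Interpolator(G)
    return _eigen_at(interp, point)


def _eigen_at(interp: _Interpolator, point: np.ndarray) -> HessianEigen:
    H = _hessian_matrix(interp, point)
    w, v = np.linalg.eigh(H)
    order = np.argsort(np.abs(w), kind="stable")
    return HessianEigen(eigenvalues=w[order], eigenvectors=v[:, order])


def is_tubular(eig: HessianEigen, params: TracerParams) -> bool:
    """True iff the eigen-system describes a bright tubular structure.

    Requires both cross-sectional curvatures negative, the axis curvature
    small relative to the strongest one, and a round cross-section.
    """
    l1, l2, l3 = eig.eigenvalues
    if l2 >= 0 or l3 >= 0:
        return False
    a1, a2, a3 = abs(l1), abs(l2), abs(l3)
    if a3 == 0:
        return False
    if a1 / a3 > params.tubularity_flatness_max:
        return False
    if min(a2, a3) / max(a2, a3) < params.tubularity_ratio_min:
        return False
    return True


def _normal_basis(direction: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    helper = np.array([1.0, 0.0, 0.0]) if abs(d[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    u = np.cross(d, helper)
    u /= np.linalg.norm(u)
    v = np.cross(d, u)
    return u, v


def medial_correct(
    G,
    point,
    direction,
    radius: float = 4.0,
    spacing: float = 0.5,
) -> np.ndarray:
    """Re-centre a point on the medial axis of its tube.

    Samples the smoothed volume on a discrete disc (default radius =
    ``hessian_window // 2`` pixels, 0.5 px spacing) in the plane through
    ``point`` normal to ``direction`` and returns the position of maximal
    interpolated intensity.  Ties are broken toward the disc centre so a
    constant volume returns the input point.  Samples outside the volume are
    dropped (truncated disc); a disc fully outside raises ``BoundaryError``.
    """
    interp = G if isinstance(G, _Interpolator) else _Interpolator(np.asarray(G))
    p = np.asarray(point, dtype=float)
    u, v = _normal_basis(direction)
    offs = np.arange(-radius, radius + 1e-9, spacing)
    ss, tt = np.meshgrid(offs, offs, indexing="ij")
    keep = ss**2 + tt**2 <= radius**2 + 1e-9
    ss, tt = ss[keep], tt[keep]
    pts = p[None, :] + ss[:, None] * u[None, :] + tt[:, None] * v[None, :]
    upper = np.asarray(interp.shape, dtype=float) - 1.0
    inside = np.all((pts >= 0.0) & (pts <= upper), axis=1)
    if not inside.any():
        raise BoundaryError("medial-correction disc lies fully outside the volume")
    pts, ss, tt = pts[inside], ss[inside], tt[inside]
    vals = interp(pts)
    best = np.max(vals)
    cand = np.flatnonzero(vals >= best - 1e-12)
    rho = ss[cand] ** 2 + tt[cand] ** 2
    pick = cand[np.argmin(rho)]
    return pts[pick]


# ---------------------------------------------------------------------------
# Tracing
# ---------------------------------------------------------------------------

def _walk(
    interp: _Interpolator,
    start: np.ndarray,
    direction: np.ndarray,
    params: TracerParams,
    min_intensity: float,
    claimed: Set[Tuple[int, int, int]],
    own: Set[Tuple[int, int, int]],
) -> Tuple[List[np.ndarray], str]:
    """March from ``start`` along ``direction``; returns (nodes, stop reason)."""
    margin = params.hessian_window // 2
    radius = float(margin)
    p = np.asarray(start, dtype=float)
    v = np.asarray(direction, dtype=float)
    v = v / np.linalg.norm(v)
    nodes: List[np.ndarray] = []
    recent: List[Tuple[int, int, int]] = [tuple(np.round(p).astype(int))]
    for step in range(params.max_steps):
        q = p + params.step_size * v
        if not _check_margin(interp.shape, q, margin):
            return nodes, "boundary"
        try:
            q = medial_correct(interp, q, v, radius=radius)
        except BoundaryError:
            return nodes, "boundary"
        if not _check_margin(interp.shape, q, margin):
            return nodes, "boundary"
        if float(interp(q)[0]) < min_intensity:
            return nodes, "intensity"
        eig = _eigen_at(interp, q)
        if not is_tubular(eig, params):
            return nodes, "tubularity"
        w = eig.minor_vector
        dot = float(w @ v)
        if abs(dot) < 0.1:
            return nodes, "direction-ambiguous"
        if dot < 0:
            w = -w
        vox = tuple(np.round(q).astype(int))
        if vox in claimed:
            return nodes, "claimed"
        if vox in own and vox not in recent and step > 3:
            return nodes, "self-loop"
        own.add(vox)
        recent.append(vox)
        if len(recent) > 5:
            recent.pop(0)
        nodes.append(q)
        p, v = q, w
    return nodes, "max-steps"


def _trace_core(
    interp: _Interpolator,
    stack: ConfocalStack,
    seed: Seed,
    params: TracerParams,
    claimed: Optional[Set[Tuple[int, int, int]]],
) -> Tuple[Optional[AxonTrace], Set[Tuple[int, int, int]]]:
    claimed = claimed if claimed is not None else set()
    margin = params.hessian_window // 2
    p0 = np.array([seed.z, seed.y, seed.x], dtype=float)
    if not _check_margin(interp.shape, p0, margin):
        return None, set()
    eig = _eigen_at(interp, p0)
    if not is_tubular(eig, params):
        return None, set()
    v0 = eig.minor_vector
    try:
        p0 = medial_correct(interp, p0, v0, radius=float(margin))
    except BoundaryError:
        pass
    if not _check_margin(interp.shape, p0, margin):
        return None, set()
    eig = _eigen_at(interp, p0)
    if not is_tubular(eig, params):
        return None, set()
    v0 = eig.minor_vector
    g0 = float(interp(p0)[0])
    min_intensity = (
        params.min_intensity if params.min_intensity is not None else 0.5 * g0
    )
    own: Set[Tuple[int, int, int]] = {tuple(np.round(p0).astype(int))}
    fwd, reason_f = _walk(interp, p0, v0, params, min_intensity, claimed, own)
    bwd, reason_b = _walk(interp, p0, -v0, params, min_intensity, claimed, own)
    log.debug(
        "seed (%d,%d,%d): %d+%d nodes (stop: %s/%s)",
        seed.x, seed.y, seed.z, len(fwd), len(bwd), reason_f, reason_b,
    )
    pts_px = list(reversed(bwd)) + [p0] + fwd
    if len(pts_px) < 2:
        return None, own
    pts_um = stack.index_to_um(np.array(pts_px))
    # drop accidental duplicate consecutive points from tight corrections
    keep = np.ones(len(pts_um), dtype=bool)
    keep[1:] = np.any(np.diff(pts_um, axis=0) != 0.0, axis=1)
    pts_um = pts_um[keep]
    if len(pts_um) < 2:
        return None, own
    return AxonTrace(points=pts_um, seed_index=-1), own


def trace_from_seed(
    stack: ConfocalStack,
    seed: Seed,
    params: TracerParams = TracerParams(),
    claimed: Optional[Set[Tuple[int, int, int]]] = None,
    _interp: Optional[_Interpolator] = None,
) -> Optional[AxonTrace]:
    """Trace one axon bidirectionally from a seed.

    Returns the traced centerline in um, or None when the seed does not sit
    on a tubular structure (logged, not an error).
    """
    interp = _interp if _interp is not None else _Interpolator(smooth_volume(stack, params.sigma))
    trace, _ = _trace_core(interp, stack, seed, params, claimed)
    return trace


def _dilate_voxels(
    voxels: Iterable[Tuple[int, int, int]], shape: Sequence[int]
) -> Set[Tuple[int, int, int]]:
    out: Set[Tuple[int, int, int]] = set()
    nz, ny, nx = shape
    for z, y, x in voxels:
        for dz in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for dx in (-1, 0, 1):
                    zz, yy, xx = z + dz, y + dy, x + dx
                    if 0 <= zz < nz and 0 <= yy < ny and 0 <= xx < nx:
                        out.add((zz, yy, xx))
    return out


def trace_all(
    stack: ConfocalStack,
    seed_params: SeedParams,
    tracer_params: TracerParams = TracerParams(),
) -> List[AxonTrace]:
    """Seed the stack and trace every axon, suppressing redundant traces.

    Seeds are processed in descending distance-score order; each accepted
    trace claims its visited voxels (dilated by 1 voxel), and later seeds
    falling on claimed voxels are skipped so one axon yields one trace.
    Stub traces shorter than ``min_nodes`` nodes are discarded.
    """
    seeds = select_seeds(stack, seed_params)
    if not seeds:
        return []
    interp = _Interpolator(smooth_volume(stack, tracer_params.sigma))
    claimed: Set[Tuple[int, int, int]] = set()
    traces: List[AxonTrace] = []
    n_skipped = 0
    for i, seed in enumerate(seeds):
        if (seed.z, seed.y, seed.x) in claimed:
            n_skipped += 1
            continue
        trace, visited = _trace_core(interp, stack, seed, tracer_params, claimed)
        if trace is None or trace.n_points < tracer_params.min_nodes:
            continue
        trace.seed_index = i
        traces.append(trace)
        claimed |= _dilate_voxels(visited, stack.shape)
    log.info(
        "traced %d axons from %d seeds (%d suppressed as redundant)",
        len(traces), len(seeds), n_skipped,
    )
    return traces


def axon_density(traces: Sequence[AxonTrace], stack: ConfocalStack) -> float:
    """Total traced centerline length per unit imaged volume (um / um^3)."""
    volume = stack.physical_volume
    if volume <= 0:
        raise ValueError("stack has zero physical volume")
    return float(sum(t.length for t in traces)) / volume
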