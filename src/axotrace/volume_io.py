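"""Calibrated image volumes and traced centerlines, with TIFF / SWC round-trip I/O.

The two core containers used throughout the package are

``ConfocalStack``
    a 3D non-negative intensity grid indexed ``(z, y, x)`` together with its
    per-axis voxel calibration in micrometres.  Confocal stacks are anisotropic
    in practice (optical section spacing of 0.5-0.6 um against a lateral
    resolution of ~0.4 um), so the calibration is always carried per axis.

``AxonTrace``
    an ordered 3D polyline of ``(x, y, z)`` positions in micrometres
    representing one traced axon centerline.

Voxel indices are 0-based and a voxel's physical position is
``(index + 0.5) * voxel_size`` (voxel-centre convention), which keeps analytic
phantoms exact under rendering and re-reading.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Tuple, Union

import numpy as np
import tifffile

__all__ = [
    "ConfocalStack",
    "AxonTrace",
    "read_stack",
    "write_stack",
    "read_swc",
    "write_swc",
]

PathLike = Union[str, Path]


@dataclass
class ConfocalStack:
    """A calibrated 3D fluorescence intensity grid.

    Parameters
    ----------
    intensities
        3D array indexed ``(z, y, x)``; finite and non-negative.
    voxel_size
        ``(dz, dy, dx)`` in micrometres, each strictly positive.
    name
        Free-text identifier, used only for reporting.
    """

    intensities: np.ndarray
    voxel_size: Tuple[float, float, float]
    name: str = ""

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities)
        if self.intensities.ndim != 3:
            raise ValueError(
                f"intensities must be 3D (z, y, x), got ndim={self.intensities.ndim}"
            )
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("intensities must be finite")
        if np.any(self.intensities < 0):
            raise ValueError("intensities must be non-negative")
        vs = tuple(float(v) for v in self.voxel_size)
        if len(vs) != 3 or any(v <= 0 for v in vs):
            raise ValueError(f"voxel_size must be three positive values, got {self.voxel_size}")
        self.voxel_size = vs

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.intensities.shape  # type: ignore[return-value]

    @property
    def physical_volume(self) -> float:
        """Physical volume of the imaged region in um^3."""
        nz, ny, nx = self.intensities.shape
        dz, dy, dx = self.voxel_size
        return nz * dz * ny * dy * nx * dx

    def index_to_um(self, zyx: np.ndarray) -> np.ndarray:
        """Convert fractional ``(z, y, x)`` voxel indices to ``(x, y, z)`` um."""
        zyx = np.atleast_2d(np.asarray(zyx, dtype=float))
        um = (zyx + 0.5) * np.asarray(self.voxel_size)
        return um[:, ::-1]

    def um_to_index(self, xyz: np.ndarray) -> np.ndarray:
        """Convert ``(x, y, z)`` um positions to fractional ``(z, y, x)`` indices."""
        xyz = np.atleast_2d(np.asarray(xyz, dtype=float))
        zyx = xyz[:, ::-1] / np.asarray(self.voxel_size) - 0.5
        return zyx


@dataclass
class AxonTrace:
    """An ordered polyline of 3D positions (um) for one traced axon segment."""

    points: np.ndarray  # (N, 3) columns (x, y, z) in um
    seed_index: int = -1
    radii: Optional[np.ndarray] = None  # (N,) in um

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 1:
            raise ValueError("points must be an (N>=1, 3) array of (x, y, z) um")
        if not np.all(np.isfinite(pts)):
            raise ValueError("trace points must be finite")
        if pts.shape[0] > 1:
            seg = np.diff(pts, axis=0)
            if np.any(np.all(seg == 0.0, axis=1)):
                raise ValueError("consecutive trace points must be distinct")
        self.points = pts
        if self.radii is not None:
            r = np.asarray(self.radii, dtype=float)
            if r.shape != (pts.shape[0],):
                raise ValueError("radii must match the number of points")
            self.radii = r

    @property
    def n_points(self) -> int:
        return self.points.shape[0]

    @property
    def length(self) -> float:
        """Polyline length in um (sum of segment lengths)."""
        if self.points.shape[0] < 2:
            return 0.0
        return float(np.sum(np.linalg.norm(np.diff(self.points, axis=0), axis=1)))


def read_stack(path: PathLike, voxel_size: Tuple[float, float, float]) -> ConfocalStack:
    """Read a single- or multi-page grayscale TIFF as a calibrated stack.

    A single 2D page becomes a one-plane volume.  Multi-channel (RGB/RGBA)
    input is rejected: select and export one channel before tracing.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        if getattr(page, "samplesperpixel", 1) > 1:
            raise ValueError(
                f"{path} is multi-channel; select a single channel "
                "(e.g. the axon-label channel) and save it as grayscale TIFF"
            )
        arr = tif.asarray()
    if arr.ndim == 2:
        arr = arr[None, :, :]
    if arr.ndim != 3:
        raise ValueError(f"expected a 2D or 3D grayscale TIFF, got shape {arr.shape}")
    return ConfocalStack(intensities=arr, voxel_size=voxel_size, name=path.stem)


def write_stack(stack: ConfocalStack, path: PathLike) -> None:
    """Write a stack as a multi-page grayscale TIFF (dtype preserved)."""
    tifffile.imwrite(Path(path), stack.intensities, photometric="minisblack")


def write_swc(trace: AxonTrace, path: PathLike, structure_type: int = 2) -> None:
    """Write a trace as standard 7-column SWC.

    Nodes are numbered 1..N along the polyline; node ``i`` has parent ``i - 1``
    and the root's parent is ``-1``.  Structure type defaults to 2 (axon).
    """
    if trace.n_points < 1:
        raise ValueError("cannot write an empty trace")
    radii = trace.radii if trace.radii is not None else np.full(trace.n_points, 1.0)
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("# id type x y z radius parent\n")
        for i, ((x, y, z), r) in enumerate(zip(trace.points, radii), start=1):
            parent = i - 1 if i > 1 else -1
            fh.write(f"{i} {structure_type} {x:.6f} {y:.6f} {z:.6f} {r:.6f} {parent}\n")


def read_swc(path: PathLike) -> AxonTrace:
    """Read an SWC file describing a simple (unbranched) path.

    Raises on malformed rows, dangling parent references, or branching
    morphologies (this package traces segments, not trees).
    """
    path = Path(path)
    nodes: dict[int, tuple[np.ndarray, float, int]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 7:
                raise ValueError(f"{path}:{lineno}: expected 7 columns, got {len(parts)}")
            try:
                nid = int(parts[0])
                xyz = np.array([float(parts[2]), float(parts[3]), float(parts[4])])
                radius = float(parts[5])
                parent = int(parts[6])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed SWC row") from exc
            if nid in nodes:
                raise ValueError(f"{path}:{lineno}: duplicate node id {nid}")
            nodes[nid] = (xyz, radius, parent)
    if not nodes:
        raise ValueError(f"{path}: no nodes found")
    for nid, (_, _, parent) in nodes.items():
        if parent != -1 and parent not in nodes:
            raise ValueError(f"{path}: node {nid} references missing parent {parent}")
    roots = [nid for nid, (_, _, p) in nodes.items() if p == -1]
    if len(roots) != 1:
        raise ValueError(f"{path}: expected exactly one root, found {len(roots)}")
    children: dict[int, list[int]] = {}
    for nid, (_, _, parent) in nodes.items():
        if parent != -1:
            children.setdefault(parent, []).append(nid)
    order = [roots[0]]
    while order[-1] in children:
        kids = children[order[-1]]
        if len(kids) > 1:
            raise ValueError(f"{path}: branching morphology (node {order[-1]} has {len(kids)} children)")
        order.append(kids[0])
    if len(order) != len(nodes):
        raise ValueError(f"{path}: disconnected nodes present")
    pts = np.array([nodes[nid][0] for nid in order])
    radii = np.array([nodes[nid][1] for nid in order])
    return AxonTrace(points=pts, radii=radii)
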