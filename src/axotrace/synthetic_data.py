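"""Ground-truthed synthetic inputs: tubular image phantoms, Gaussian-mixture
samples, and miniature-EPSC current traces.

Every generator is a pure function of its spec: the same spec and seed produce
byte-identical output.  The phantoms emulate confocal stacks of fluorescently
labelled axons; tubes are rendered with the Gaussian cross-section
``I(d) = peak * exp(-2 d^2 / w^2)`` (``d`` = distance to the centerline in
pixels), the same functional form as the mixture kernel, so Hessian
eigenvalues on the tube axis have a closed form that the tracer tests use.
Noise is additive Gaussian read noise plus optional Poisson shot noise;
defaults bracket confocal practice (SNR ~5-20).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .volume_io import ConfocalStack

__all__ = [
    "Line3D",
    "Helix",
    "Bezier",
    "Tube",
    "PhantomSpec",
    "PhantomTruth",
    "make_phantom",
    "MixtureSpec",
    "sample_mixture",
    "MEPSCKinetics",
    "synth_mepsc_trace",
]


# ---------------------------------------------------------------------------
# Parametric curves (positions in um)
# ---------------------------------------------------------------------------

class Curve:
    """A parametric 3D path ``t in [0, 1] -> (x, y, z)`` um."""

    def point(self, t: np.ndarray) -> np.ndarray:  # (N, 3)
        raise NotImplementedError

    def length(self) -> float:
        """Arc length in um (analytic where available, else 64-node quadrature)."""
        nodes, weights = np.polynomial.legendre.leggauss(64)
        t = 0.5 * (nodes + 1.0)
        eps = 1e-6
        p_hi = self.point(np.clip(t + eps, 0, 1))
        p_lo = self.point(np.clip(t - eps, 0, 1))
        dt = np.clip(t + eps, 0, 1) - np.clip(t - eps, 0, 1)
        speed = np.linalg.norm(p_hi - p_lo, axis=1) / dt
        return float(0.5 * np.sum(weights * speed))

    def polyline(self, n: int = 1000) -> np.ndarray:
        """Dense polyline sampling of the curve, (n, 3) in um."""
        return self.point(np.linspace(0.0, 1.0, n))


@dataclass(frozen=True)
class Line3D(Curve):
    start: Tuple[float, float, float]
    end: Tuple[float, float, float]

    def point(self, t: np.ndarray) -> np.ndarray:
        t = np.atleast_1d(np.asarray(t, dtype=float))[:, None]
        a = np.asarray(self.start, dtype=float)
        b = np.asarray(self.end, dtype=float)
        return a + t * (b - a)

    def length(self) -> float:
        return float(np.linalg.norm(np.asarray(self.end) - np.asarray(self.start)))


@dataclass(frozen=True)
class Helix(Curve):
    """Helix about an axis-aligned direction.

    ``length = turns * sqrt((2 pi R)^2 + pitch^2)``.
    """

    center: Tuple[float, float, float]  # (x, y, z) um of the helix axis at t=0
    radius: float  # um
    pitch: float  # um of axial advance per turn
    turns: float
    axis: str = "z"
    phase: float = 0.0

    def point(self, t: np.ndarray) -> np.ndarray:
        t = np.atleast_1d(np.asarray(t, dtype=float))
        theta = self.phase + 2.0 * math.pi * self.turns * t
        u = self.radius * np.cos(theta)
        v = self.radius * np.sin(theta)
        w = self.pitch * self.turns * t
        c = np.asarray(self.center, dtype=float)
        out = np.empty((t.size, 3))
        axes = {"x": (1, 2, 0), "y": (2, 0, 1), "z": (0, 1, 2)}
        iu, iv, iw = axes[self.axis]
        out[:, iu] = c[iu] + u
        out[:, iv] = c[iv] + v
        out[:, iw] = c[iw] + w
        return out

    def length(self) -> float:
        return float(self.turns * math.hypot(2.0 * math.pi * self.radius, self.pitch))


@dataclass(frozen=True)
class Bezier(Curve):
    """Bezier curve of arbitrary degree from its control points (um)."""

    control_points: Tuple[Tuple[float, float, float], ...]

    def point(self, t: np.ndarray) -> np.ndarray:
        t = np.atleast_1d(np.asarray(t, dtype=float))
        cps = np.asarray(self.control_points, dtype=float)
        n = cps.shape[0] - 1
        out = np.zeros((t.size, 3))
        for i in range(n + 1):
            coef = math.comb(n, i) * t**i * (1.0 - t) ** (n - i)
            out += coef[:, None] * cps[i]
        return out


# ---------------------------------------------------------------------------
# Image phantoms
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Tube:
    """A rendered tube: a curve plus its width (pixels) and peak intensity."""

    curve: Curve
    width_px: float = 3.0  # Gaussian cross-section width parameter w, >= 2 px
    peak: float = 200.0

    def __post_init__(self) -> None:
        if self.width_px < 2.0:
            raise ValueError("tube width must be >= 2 px for a resolvable cross-section")


@dataclass(frozen=True)
class PhantomSpec:
    """Specification of a synthetic tubular stack with known centerlines."""

    shape: Tuple[int, int, int]  # (nz, ny, nx) voxels
    voxel_size: Tuple[float, float, float] = (0.25, 0.25, 0.25)  # um
    tubes: Tuple[Tube, ...] = ()
    background: float = 10.0
    noise_sd: float = 0.0  # additive Gaussian SD, intensity units
    poisson_scale: Optional[float] = None  # photons per intensity unit, or None
    seed: int = 0
    name: str = "phantom"


@dataclass
class PhantomTruth:
    """Analytic ground truth accompanying a rendered phantom."""

    centerlines_um: List[np.ndarray]  # (N, 3) polylines, columns (x, y, z) um
    lengths_um: List[float]

    @property
    def total_length_um(self) -> float:
        return float(sum(self.lengths_um))


def _curve_distance_px(spec: PhantomSpec, tube: Tube) -> np.ndarray:
    """Distance (pixels) from every voxel centre to the tube centerline.

    Exact point-to-segment distance for straight lines; for curved paths the
    curve is sampled at <=0.1 px spacing and queried through a KD-tree, which
    bounds the distance error by half the sampling step.
    """
    nz, ny, nx = spec.shape
    vs = np.asarray(spec.voxel_size)
    zz, yy, xx = np.meshgrid(
        np.arange(nz), np.arange(ny), np.arange(nx), indexing="ij"
    )
    # voxel centres in pixel coordinates (z, y, x)
    vox = np.stack([zz, yy, xx], axis=-1).reshape(-1, 3).astype(float)

    def um_to_px(pts_um: np.ndarray) -> np.ndarray:
        return pts_um[:, ::-1] / vs - 0.5  # (z, y, x) px

    if isinstance(tube.curve, Line3D):
        a = um_to_px(tube.curve.point(np.array([0.0])))[0]
        b = um_to_px(tube.curve.point(np.array([1.0])))[0]
        ab = b - a
        denom = float(ab @ ab)
        if denom == 0.0:
            d = np.linalg.norm(vox - a, axis=1)
        else:
            t = np.clip((vox - a) @ ab / denom, 0.0, 1.0)
            proj = a + t[:, None] * ab
            d = np.linalg.norm(vox - proj, axis=1)
        return d.reshape(spec.shape)

    approx_len_px = tube.curve.length() / float(np.min(vs))
    n = max(64, int(approx_len_px / 0.1))
    samples = um_to_px(tube.curve.polyline(n))
    tree = cKDTree(samples)
    d, _ = tree.query(vox, k=1)
    return d.reshape(spec.shape)


def make_phantom(spec: PhantomSpec) -> Tuple[ConfocalStack, PhantomTruth]:
    """Render a tubular phantom and return it with its analytic ground truth.

    Overlapping tubes blend by maximum intensity.  Noise (Poisson then
    Gaussian) is applied after rendering; negative values are clipped to zero
    to preserve the non-negativity invariant of intensity data.
    """
    img = np.zeros(spec.shape, dtype=float)
    for tube in spec.tubes:
        d = _curve_distance_px(spec, tube)
        contrib = tube.peak * np.exp(-2.0 * d**2 / tube.width_px**2)
        np.maximum(img, contrib, out=img)
    img += spec.background

    rng = np.random.default_rng(spec.seed)
    if spec.poisson_scale is not None:
        img = rng.poisson(np.clip(img, 0, None) * spec.poisson_scale) / spec.poisson_scale
    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
    img = np.clip(img, 0.0, None)

    stack = ConfocalStack(intensities=img, voxel_size=spec.voxel_size, name=spec.name)
    truth = PhantomTruth(
        centerlines_um=[t.curve.polyline(2000) for t in spec.tubes],
        lengths_um=[t.curve.length() for t in spec.tubes],
    )
    return stack, truth


def benchmark_phantoms(seed: int = 0, noise_sd: float = 0.0) -> List[PhantomSpec]:
    """The package's standard tracing-validation suite (10 phantoms).

    Six straight tubes (the three near-axis orientations, two obliques, one
    pair of well-separated parallels) and four curved tubes (three helices of
    differing radius/pitch and one Bezier arc), all with the default thin-tube
    rendering (w = 3 px, peak 200 over background 10, 0.25 um isotropic
    voxels).  ``noise_sd = 40`` gives peak-SNR 5 stacks.  The tube steepest in
    z keeps a small lateral drift: an axon exactly perpendicular to the x-y
    projection collapses to a point in the maximum-intensity projection and
    cannot be seeded, a geometric limit of projection-based seeding.
    """
    v = 0.25

    def pt(x_px: float, y_px: float, z_px: float):
        return ((x_px + 0.5) * v, (y_px + 0.5) * v, (z_px + 0.5) * v)

    def tube(curve: Curve) -> Tube:
        return Tube(curve, width_px=3.0, peak=200.0)

    geometries = [
        ((24, 32, 220), Line3D(pt(10, 16, 12), pt(210, 16, 12))),
        ((24, 220, 32), Line3D(pt(16, 10, 12), pt(16, 210, 12))),
        ((220, 32, 48), Line3D(pt(12, 16, 10), pt(36, 16, 210))),  # steep in z
        ((24, 100, 200), Line3D(pt(12, 12, 12), pt(188, 88, 12))),
        ((100, 100, 100), Line3D(pt(12, 12, 12), pt(88, 88, 88))),
        (
            (24, 64, 200),
            [Line3D(pt(10, 20, 12), pt(190, 20, 12)), Line3D(pt(10, 44, 12), pt(190, 44, 12))],
        ),
        ((80, 96, 96), Helix(center=pt(48, 48, 8), radius=14 * v, pitch=24 * v, turns=1.8)),
        ((64, 88, 88), Helix(center=pt(44, 44, 8), radius=16 * v, pitch=28 * v, turns=1.25)),
        ((90, 72, 72), Helix(center=pt(36, 36, 6), radius=10 * v, pitch=30 * v, turns=2.2)),
        (
            (24, 80, 200),
            Bezier((pt(12, 24, 12), pt(71, 52, 12), pt(130, 28, 12), pt(188, 56, 12))),
        ),
    ]
    specs = []
    for i, (shape, curves) in enumerate(geometries):
        curves = curves if isinstance(curves, list) else [curves]
        specs.append(
            PhantomSpec(
                shape=shape,
                voxel_size=(v, v, v),
                tubes=tuple(tube(c) for c in curves),
                background=10.0,
                noise_sd=noise_sd,
                seed=seed * 100 + i,
                name=f"benchmark-{i}",
            )
        )
    return specs


# ---------------------------------------------------------------------------
# Gaussian mixtures
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MixtureSpec:
    """1D Gaussian mixture: per-component (fraction, center, width).

    ``width`` is the same ``w`` used by the fitting kernel
    ``exp(-2 (x - xc)^2 / w^2)``, i.e. SD = w / 2.  The default components
    emulate the small/medium/large synaptic populations resolved from
    amplitude and puncta-area distributions (fractions 0.31/0.41/0.28).
    """

    components: Tuple[Tuple[float, float, float], ...] = (
        (0.31, -5.0, 2.0),
        (0.41, -12.0, 2.0),
        (0.28, -22.0, 2.0),
    )
    n: int = 5000
    seed: int = 0

    def __post_init__(self) -> None:
        fracs = [c[0] for c in self.components]
        if abs(sum(fracs) - 1.0) > 1e-9:
            raise ValueError(f"fractions must sum to 1, got {sum(fracs)}")
        if any(c[2] <= 0 for c in self.components):
            raise ValueError("widths must be positive")


def sample_mixture(spec: MixtureSpec, rng: Optional[np.random.Generator] = None) -> np.ndarray:
    """Draw ``n`` samples; component counts are multinomial in the fractions."""
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    if spec.n == 0:
        return np.empty(0)
    fracs = np.array([c[0] for c in spec.components])
    counts = rng.multinomial(spec.n, fracs)
    parts = [
        rng.normal(center, width / 2.0, size=cnt)
        for cnt, (_, center, width) in zip(counts, spec.components)
    ]
    samples = np.concatenate(parts)
    rng.shuffle(samples)
    return samples


# ---------------------------------------------------------------------------
# Synthetic mEPSC traces
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MEPSCKinetics:
    """Bi-exponential synaptic event kinetics (ms).

    Events are a difference of exponentials: a fast+slow decay pair minus a
    rising exponential, normalised to unit peak.  Defaults give a ~0.5 ms
    10-90% rise and a weighted decay of ~5 ms, typical of glutamatergic
    miniature currents at somatic recordings.
    """

    rise_tau: float = 0.5
    decay_tau1: float = 2.0
    decay_tau2: float = 8.0
    fast_fraction: float = 0.6  # amplitude share of decay_tau1

    def kernel(self, sampling_rate: float, duration_ms: float = 80.0) -> np.ndarray:
        """Unit-peak event waveform sampled at ``sampling_rate`` Hz."""
        t = np.arange(0.0, duration_ms, 1000.0 / sampling_rate)
        f = self.fast_fraction
        shape = (
            f * np.exp(-t / self.decay_tau1)
            + (1.0 - f) * np.exp(-t / self.decay_tau2)
            - np.exp(-t / self.rise_tau)
        )
        peak = np.max(shape)
        if peak <= 0:
            raise ValueError("degenerate kinetics: rise must be faster than decay")
        return shape / peak


def synth_mepsc_trace(
    rate: float,
    duration: float,
    amplitude_mixture: Optional[MixtureSpec] = None,
    kinetics: MEPSCKinetics = MEPSCKinetics(),
    noise_sd: float = 1.0,
    sampling_rate: float = 20000.0,
    seed: int = 0,
):
    """Simulate a voltage-clamp current trace with Poisson-timed mEPSCs.

    Parameters
    ----------
    rate
        Mean event rate in Hz (Poisson process).
    duration
        Trace duration in seconds.
    amplitude_mixture
        Mixture the (negative, pA) event amplitudes are drawn from; the
        default emulates small/medium/large event populations.
    noise_sd
        Baseline Gaussian noise SD in pA (default 1 pA, a quiet whole-cell
        recording).

    Returns
    -------
    (CurrentTrace, pandas.DataFrame)
        The trace and a ground-truth table with one row per event:
        ``onset_s``, ``peak_s``, ``amplitude_pa``.
    """
    from .ephys_features import CurrentTrace  # local import to avoid a cycle

    if rate < 0:
        raise ValueError("rate must be >= 0")
    if amplitude_mixture is None:
        amplitude_mixture = MixtureSpec()
    rng = np.random.default_rng(seed)
    n_samples = int(round(duration * sampling_rate))
    current = np.zeros(n_samples)

    n_events = rng.poisson(rate * duration)
    onsets = np.sort(rng.uniform(0.0, duration, size=n_events))
    amplitudes = (
        sample_mixture(
            MixtureSpec(amplitude_mixture.components, n=n_events, seed=0),
            rng=rng,
        )
        if n_events
        else np.empty(0)
    )

    kernel = kinetics.kernel(sampling_rate)
    peak_offset_s = float(np.argmax(kernel)) / sampling_rate
    rows = []
    for onset, amp in zip(onsets, amplitudes):
        i0 = int(round(onset * sampling_rate))
        i1 = min(i0 + kernel.size, n_samples)
        if i1 <= i0:
            continue
        current[i0:i1] += amp * kernel[: i1 - i0]
        rows.append({"onset_s": onset, "peak_s": onset + peak_offset_s, "amplitude_pa": amp})

    if noise_sd > 0:
        current += rng.normal(0.0, noise_sd, size=n_samples)

    truth = pd.DataFrame(rows, columns=["onset_s", "peak_s", "amplitude_pa"])
    trace = CurrentTrace(samples=current, sampling_rate=sampling_rate)
    return trace, truth
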