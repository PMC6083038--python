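"""Shared fixtures and ground-truth evaluation helpers."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings
from scipy.spatial import cKDTree

from axotrace import (
    Helix,
    Line3D,
    PhantomSpec,
    SeedParams,
    TracerParams,
    Tube,
    make_phantom,
)

settings.register_profile(
    "package",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("package")


# ---------------------------------------------------------------------------
# Phantom evaluation against analytic centerlines
# ---------------------------------------------------------------------------

def evaluate_traces(traces, truth, voxel_size):
    """Coverage and accuracy of traces against analytic centerlines.

    Returns ``(coverage, mean_deviation_px)``: the fraction of ground-truth
    centerline points lying within 2 px of a traced point, and the mean
    distance (pixels) from traced points to the true centerline.
    """
    vs = np.asarray(voxel_size)[::-1]  # (x, y, z) scaling for um -> px
    truth_px = np.vstack(truth.centerlines_um) / vs
    if not traces:
        return 0.0, np.inf
    trace_px = np.vstack([t.points for t in traces]) / vs
    d_dev, _ = cKDTree(truth_px).query(trace_px)
    d_cov, _ = cKDTree(trace_px).query(truth_px)
    return float((d_cov <= 2.0).mean()), float(d_dev.mean())


def line_um(x0, x1, y_idx, z_idx, voxel=0.25):
    """An x-axis line through voxel centers, endpoints at pixel indices."""
    return Line3D(
        ((x0 + 0.5) * voxel, (y_idx + 0.5) * voxel, (z_idx + 0.5) * voxel),
        ((x1 + 0.5) * voxel, (y_idx + 0.5) * voxel, (z_idx + 0.5) * voxel),
    )


@pytest.fixture(scope="session")
def straight_tube():
    """A noise-free straight tube phantom with its analytic truth."""
    spec = PhantomSpec(
        shape=(24, 32, 200),
        voxel_size=(0.25, 0.25, 0.25),
        tubes=(Tube(line_um(10, 190, 16, 12), width_px=3.0, peak=200.0),),
        background=10.0,
        seed=11,
    )
    stack, truth = make_phantom(spec)
    return stack, truth


@pytest.fixture(scope="session")
def tracer_params():
    """Tracer settings used for the thin synthetic tubes (w = 3 px)."""
    return TracerParams(sigma=3.0)


@pytest.fixture(scope="session")
def seed_params_clean():
    return SeedParams(lower_threshold=70.0, upper_threshold=1e6)
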