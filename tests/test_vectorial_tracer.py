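import numpy as np
import pytest
from scipy.spatial import cKDTree

from axotrace import (
    AxonTrace,
    BoundaryError,
    ConfocalStack,
    HessianEigen,
    PhantomSpec,
    Seed,
    SeedParams,
    TracerParams,
    Tube,
    axon_density,
    hessian_eigen,
    is_tubular,
    make_phantom,
    medial_correct,
    smooth_volume,
    trace_all,
    trace_from_seed,
)
from conftest import evaluate_traces, line_um


def analytic_tube(shape=(24, 33, 33), w=4.0, axis_y=16, axis_x=16):
    """Grid sampling of I = exp(-2 ((x-cx)^2 + (y-cy)^2) / w^2), tube along z."""
    z, y, x = np.indices(shape, dtype=float)
    return np.exp(-2.0 * ((x - axis_x) ** 2 + (y - axis_y) ** 2) / w**2)


class TestSmoothing:
    def test_impulse_response_peaks_at_impulse(self):
        arr = np.zeros((15, 15, 15))
        arr[7, 7, 7] = 1.0
        G = smooth_volume(arr, sigma=1.5)
        assert np.unravel_index(np.argmax(G), G.shape) == (7, 7, 7)
        assert G.sum() == pytest.approx(1.0, rel=1e-3)  # mass conserved

    def test_constant_volume_unchanged(self):
        G = smooth_volume(np.full((8, 8, 8), 3.0), sigma=2.0)
        assert np.allclose(G, 3.0, atol=1e-12)

    def test_matches_direct_convolution_in_interior(self):
        rng = np.random.default_rng(2)
        arr = rng.random((16, 16, 16))
        sigma, radius = 1.5, int(4 * 1.5 + 0.5)
        i = np.arange(-radius, radius + 1)
        k1 = np.exp(-0.5 * (i / sigma) ** 2)
        k1 /= k1.sum()
        from scipy.signal import convolve

        kernel = k1[:, None, None] * k1[None, :, None] * k1[None, None, :]
        direct = convolve(arr, kernel, mode="same")
        G = smooth_volume(arr, sigma=sigma)
        core = (slice(radius, -radius),) * 3
        assert np.allclose(G[core], direct[core], atol=1e-8)

    def test_sigma_validated(self):
        with pytest.raises(ValueError):
            smooth_volume(np.ones((4, 4, 4)), sigma=0.0)


class TestHessianEigen:
    def test_analytic_tube_axis(self):
        w = 4.0
        G = analytic_tube(w=w)
        eig = hessian_eigen(G, (12, 16, 16), window=9)
        # frozen oracle: unit-spacing second difference of the analytic profile
        lam_fd = 2.0 * (np.exp(-2.0 / w**2) - 1.0)
        assert eig.eigenvalues[0] == pytest.approx(0.0, abs=1e-9)
        assert eig.eigenvalues[1] == pytest.approx(lam_fd, abs=1e-9)
        assert eig.eigenvalues[2] == pytest.approx(lam_fd, abs=1e-9)
        # and the continuum value -4/w^2 within the discretisation error
        assert eig.eigenvalues[2] == pytest.approx(-4.0 / w**2, rel=0.10)
        # minor eigenvector along the tube axis (z)
        assert abs(eig.minor_vector[0]) == pytest.approx(1.0, abs=1e-6)

    def test_isotropic_quadratic_bowl(self):
        a = 0.3
        z, y, x = np.indices((13, 13, 13), dtype=float) - 6.0
        G = a * (x**2 + y**2 + z**2)
        eig = hessian_eigen(G, (6, 6, 6), window=9)
        assert np.allclose(eig.eigenvalues, 2.0 * a, atol=1e-9)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_characteristic_polynomial_roots(self, seed):
        rng = np.random.default_rng(seed)
        M = rng.normal(size=(3, 3))
        M = (M + M.T) / 2.0
        # quadratic grid whose Hessian is exactly M under central differences
        z, y, x = np.indices((13, 13, 13), dtype=float) - 6.0
        coords = np.stack([z, y, x])
        G = 0.5 * np.einsum("i...,ij,j...->...", coords, M, coords)
        G = G - G.min()  # Hessian is shift-invariant
        eig = hessian_eigen(G, (6, 6, 6), window=9)
        # independent oracle: roots of det(M - lam I) via the companion matrix
        c2 = -np.trace(M)
        c1 = (
            M[0, 0] * M[1, 1] - M[0, 1] * M[1, 0]
            + M[0, 0] * M[2, 2] - M[0, 2] * M[2, 0]
            + M[1, 1] * M[2, 2] - M[1, 2] * M[2, 1]
        )
        c0 = -(
            M[0, 0] * (M[1, 1] * M[2, 2] - M[1, 2] * M[2, 1])
            - M[0, 1] * (M[1, 0] * M[2, 2] - M[1, 2] * M[2, 0])
            + M[0, 2] * (M[1, 0] * M[2, 1] - M[1, 1] * M[2, 0])
        )
        roots = np.sort_complex(np.roots([1.0, c2, c1, c0])).real
        expected = roots[np.argsort(np.abs(roots), kind="stable")]
        assert np.allclose(eig.eigenvalues, expected, atol=1e-9)
        # defining relation and orthonormality
        for i in range(3):
            v = eig.eigenvectors[:, i]
            assert np.allclose(M @ v, eig.eigenvalues[i] * v, atol=1e-6)
        assert np.allclose(eig.eigenvectors.T @ eig.eigenvectors, np.eye(3), atol=1e-6)

    def test_boundary_margin_enforced(self):
        G = analytic_tube()
        with pytest.raises(BoundaryError):
            hessian_eigen(G, (2, 16, 16), window=9)


class TestTubularity:
    def test_ideal_tube_accepted(self):
        eig = HessianEigen(np.array([0.0, -1.0, -1.0]), np.eye(3))
        assert is_tubular(eig, TracerParams())

    def test_blob_rejected(self):
        eig = HessianEigen(np.array([-1.0, -1.0, -1.0]), np.eye(3))
        assert not is_tubular(eig, TracerParams())

    def test_tube_axis_vs_background(self):
        G = smooth_volume(200.0 * analytic_tube(shape=(24, 33, 33), w=3.0), 2.0)
        params = TracerParams(sigma=2.0)
        on_axis = hessian_eigen(G, (12, 16, 16))
        off_axis = hessian_eigen(G, (12, 5, 5))
        assert is_tubular(on_axis, params)
        assert not is_tubular(off_axis, params)


class TestMedialCorrection:
    def test_recenters_offset_point(self):
        G = analytic_tube(w=4.0)
        corrected = medial_correct(G, (12.0, 18.0, 16.0), (1.0, 0.0, 0.0))
        assert abs(corrected[1] - 16.0) <= 0.5
        assert abs(corrected[2] - 16.0) <= 0.5

    def test_on_axis_point_is_nearly_fixed(self):
        G = analytic_tube(w=4.0)
        corrected = medial_correct(G, (12.0, 16.0, 16.0), (1.0, 0.0, 0.0))
        assert np.linalg.norm(corrected - np.array([12.0, 16.0, 16.0])) <= 0.25

    def test_constant_volume_ties_to_center(self):
        G = np.full((15, 15, 15), 2.0)
        p = np.array([7.0, 7.0, 7.0])
        assert np.allclose(medial_correct(G, p, (0.0, 0.0, 1.0)), p, atol=1e-9)

    def test_fully_outside_disc_raises(self):
        G = np.full((15, 15, 15), 2.0)
        with pytest.raises(BoundaryError):
            medial_correct(G, (200.0, 200.0, 200.0), (0.0, 0.0, 1.0))


class TestTraceFromSeed:
    def test_straight_tube_recovered(self, straight_tube, tracer_params):
        stack, truth = straight_tube
        seed = Seed(x=100, y=16, z=12, intensity=210.0, distance_score=3.0)
        trace = trace_from_seed(stack, seed, tracer_params)
        assert trace is not None
        assert trace.length >= 0.90 * truth.total_length_um
        cov, dev = evaluate_traces([trace], truth, stack.voxel_size)
        assert dev <= 1.0

    def test_background_seed_yields_no_trace(self, straight_tube, tracer_params):
        stack, _ = straight_tube
        seed = Seed(x=100, y=5, z=5, intensity=10.0, distance_score=1.0)
        assert trace_from_seed(stack, seed, tracer_params) is None


class TestTraceAll:
    def test_two_disjoint_tubes_give_two_traces(self, tracer_params, seed_params_clean):
        spec = PhantomSpec(
            shape=(24, 64, 160),
            voxel_size=(0.25, 0.25, 0.25),
            tubes=(
                Tube(line_um(10, 150, 20, 12), width_px=3.0, peak=200.0),
                Tube(line_um(10, 150, 44, 12), width_px=3.0, peak=200.0),
            ),
            background=10.0,
            seed=21,
        )
        stack, truth = make_phantom(spec)
        traces = trace_all(stack, seed_params_clean, tracer_params)
        assert len(traces) == 2
        total = sum(t.length for t in traces)
        assert total == pytest.approx(truth.total_length_um, rel=0.10)

    def test_blank_stack_gives_no_traces(self, tracer_params, seed_params_clean):
        stack = ConfocalStack(np.zeros((12, 24, 24)), (0.25, 0.25, 0.25))
        assert trace_all(stack, seed_params_clean, tracer_params) == []

    def test_all_points_inside_volume(self, straight_tube, tracer_params, seed_params_clean):
        stack, _ = straight_tube
        traces = trace_all(stack, seed_params_clean, tracer_params)
        assert traces
        nz, ny, nx = stack.shape
        dz, dy, dx = stack.voxel_size
        for t in traces:
            assert np.all(t.points >= 0.0)
            assert np.all(t.points <= np.array([nx * dx, ny * dy, nz * dz]))

    def test_rotating_the_volume_rotates_the_trace(self, tracer_params, seed_params_clean):
        spec = PhantomSpec(
            shape=(24, 48, 96),
            voxel_size=(0.25, 0.25, 0.25),
            tubes=(Tube(line_um(10, 86, 24, 12), width_px=3.0, peak=200.0),),
            background=10.0,
            seed=31,
        )
        stack, _ = make_phantom(spec)
        traces = trace_all(stack, seed_params_clean, tracer_params)
        # rotate 90 degrees in the x-y plane: new[y', x'] = old[x, ny-1-y]
        rot = np.rot90(stack.intensities, k=1, axes=(1, 2))
        stack_rot = ConfocalStack(rot, (0.25, 0.25, 0.25))
        traces_rot = trace_all(stack_rot, seed_params_clean, tracer_params)
        assert len(traces) == len(traces_rot) == 1

        def endpoints_px(trace, stack_obj):
            zyx = stack_obj.um_to_index(trace.points)
            return zyx[[0, -1]]

        e = endpoints_px(traces[0], stack)
        er = endpoints_px(traces_rot[0], stack_rot)
        ny = stack.shape[1]
        # forward map of (z, y, x) under rot90(axes=(1, 2)): (z, y, x) -> (z, nx'-1-x ... )
        expected = np.stack([e[:, 0], e[:, 2], ny - 1 - e[:, 1]], axis=1)
        d = np.abs(expected[:, None, :] - er[None, :, :]).max(axis=2)
        assert min(d[0, 1], d[0, 0]) <= 1.0 and min(d[1, 0], d[1, 1]) <= 1.0

    def test_noise_never_improves_accuracy_on_average(self, tracer_params):
        devs = {0.0: [], 40.0: []}
        for noise_sd, out in devs.items():
            for rep in range(5):
                spec = PhantomSpec(
                    shape=(20, 32, 140),
                    voxel_size=(0.25, 0.25, 0.25),
                    tubes=(Tube(line_um(10, 130, 16, 10), width_px=3.0, peak=200.0),),
                    background=10.0,
                    noise_sd=noise_sd,
                    seed=100 + rep,
                )
                stack, truth = make_phantom(spec)
                lower = 70.0 if noise_sd == 0 else 180.0
                traces = trace_all(stack, SeedParams(lower, 1e6), tracer_params)
                _, dev = evaluate_traces(traces, truth, stack.voxel_size)
                out.append(dev)
        assert np.mean(devs[40.0]) >= np.mean(devs[0.0]) - 0.1


class TestEigenvectorAlignment:
    @pytest.mark.parametrize("sigma", [2.0, 3.5, 5.0])
    def test_minor_eigenvector_within_5_degrees(self, sigma):
        spec = PhantomSpec(
            shape=(24, 33, 64),
            voxel_size=(0.25, 0.25, 0.25),
            tubes=(Tube(line_um(4, 60, 16, 12), width_px=3.0, peak=1.0),),
            background=0.0,
            seed=0,
        )
        stack, _ = make_phantom(spec)
        G = smooth_volume(stack, sigma)
        eig = hessian_eigen(G, (12, 16, 32), window=9)
        angle = np.degrees(np.arccos(min(1.0, abs(eig.minor_vector[2]))))
        assert angle <= 5.0


class TestAxonDensity:
    def test_single_trace_arithmetic(self):
        stack = ConfocalStack(np.ones((100, 100, 100)), (0.5, 0.5, 0.5))  # 50 um cube
        trace = AxonTrace(points=np.array([[0.0, 25.0, 25.0], [50.0, 25.0, 25.0]]))
        assert axon_density([trace], stack) == pytest.approx(4.0e-4)

    def test_no_traces_zero_density(self):
        stack = ConfocalStack(np.ones((10, 10, 10)), (1, 1, 1))
        assert axon_density([], stack) == 0.0
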