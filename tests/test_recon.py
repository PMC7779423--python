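import numpy as np
import pytest

from shardrecon.basis import fit_shard_basis, n_sh_coeffs
from shardrecon.gradients import GradientTable
from shardrecon.geometry import (
    ReconVolume,
    ScatteredSliceSet,
    SliceProfile,
    build_layout,
    combined_kernel,
)
from shardrecon.recon import (
    ExcitationOperators,
    ReconConfig,
    laplacian_apply,
    normal_apply,
    solve_reconstruction,
    zderiv8_apply,
)
from shardrecon.simulate import uniform_directions

Z8 = np.array([1, -8, 28, -56, 70, -56, 28, -8, 1], dtype=float)


class TestLaplacian:
    def test_annihilates_constants(self):
        img = np.full((6, 6, 12, 2), 3.7)
        out = laplacian_apply(img, [1.5, 1.5, 1.5])
        assert np.max(np.abs(out)) < 1e-12

    def test_impulse_stencil(self):
        img = np.zeros((5, 5, 9, 1))
        img[2, 2, 4, 0] = 1.0
        out = laplacian_apply(img, [1.0, 1.0, 1.0])
        assert out[2, 2, 4, 0] == pytest.approx(-6.0)
        for p in [(1, 2, 4), (3, 2, 4), (2, 1, 4), (2, 3, 4), (2, 2, 3), (2, 2, 5)]:
            assert out[p + (0,)] == pytest.approx(1.0)

    def test_matches_dense_matrix_oracle(self, rng):
        # explicit 1-D second-difference matrices with reflective ends
        n = 5
        vox = np.array([1.5, 2.0, 1.0])

        def d2(n, h):
            M = np.zeros((n, n))
            for i in range(n):
                M[i, i] = -2.0
                if i > 0:
                    M[i, i - 1] += 1.0
                else:
                    M[i, i] += 1.0
                if i < n - 1:
                    M[i, i + 1] += 1.0
                else:
                    M[i, i] += 1.0
            return M / h**2

        img = rng.normal(size=(n, n, 9, 1))
        out = laplacian_apply(img, vox)
        expect = (
            np.einsum("ij,jklc->iklc", d2(n, vox[0]), img)
            + np.einsum("ij,kjlc->kilc", d2(n, vox[1]), img)
            + np.einsum("ij,kljc->klic", d2(9, vox[2]), img)
        )
        assert np.max(np.abs(out - expect)) < 1e-12


class TestZderiv8:
    def test_annihilates_constants(self):
        img = np.full((4, 4, 12, 2), -1.3)
        assert np.max(np.abs(zderiv8_apply(img))) < 1e-9

    def test_annihilates_degree7_polynomial_interior(self):
        z = np.arange(32, dtype=float)
        poly = ((z - 15) / 10) ** 7 - 3 * ((z - 15) / 10) ** 4 + z / 50
        img = np.broadcast_to(poly[None, None, :, None], (3, 3, 32, 1)).copy()
        out = zderiv8_apply(img)
        interior = out[:, :, 8:-8]
        assert np.max(np.abs(interior)) < 1e-9

    def test_impulse_response(self):
        img = np.zeros((3, 3, 21, 1))
        img[1, 1, 10, 0] = 1.0
        out = zderiv8_apply(img)
        assert np.allclose(out[1, 1, 6:15, 0], Z8, atol=1e-12)

    def test_depth_too_small_rejected(self):
        with pytest.raises(ValueError):
            zderiv8_apply(np.zeros((4, 4, 8, 1)))


@pytest.fixture(scope="module")
def tiny_problem():
    """6^3 two-shell problem small enough for dense oracles."""
    rng = np.random.default_rng(5)
    n_b0, n_dw = 2, 10
    bvals = np.r_[np.zeros(n_b0), np.full(n_dw, 1000.0)]
    bvecs = np.r_[
        np.tile([0.0, 0.0, 1.0], (n_b0, 1)), uniform_directions(n_dw)
    ]
    grad = GradientTable(bvals, bvecs)
    layout = build_layout(6, 2, 1, 1, grad)
    affine = np.diag([2.0, 2.0, 2.0, 1.0])
    kernel = combined_kernel(SliceProfile.gaussian(2.0), 2.0)
    coeffs_shells = [
        rng.normal(size=(20, n_sh_coeffs(0))),
        rng.normal(size=(20, n_sh_coeffs(2))),
    ]
    basis = fit_shard_basis(coeffs_shells, np.ones(20, bool))
    r = basis.rank
    truth = rng.normal(size=(6, 6, 6, r))
    mask = np.ones((6, 6, 6), bool)
    x0 = ReconVolume(truth, affine)
    ops_probe = ExcitationOperators(
        ScatteredSliceSet(np.zeros((6, 6, 6, grad.n_volumes)), layout, grad, mask),
        np.zeros((layout.n_excitations, 6)), basis, kernel, affine,
        x0.center_world,
    )
    data = np.zeros((6, 6, 6, grad.n_volumes))
    for e, exc in enumerate(layout.excitations):
        data[:, :, list(exc.slices), exc.volume] = ops_probe.forward(e, truth)
    slices = ScatteredSliceSet(data, layout, grad, mask)
    return slices, basis, kernel, affine, truth, rng


def _dense_forward(ops, slices, shape_r):
    """Assemble the stacked forward matrix column by column."""
    n_exc = len(ops.ops)
    nvox = int(np.prod(shape_r))
    cols = []
    for j in range(nvox):
        v = np.zeros(nvox)
        v[j] = 1.0
        v = v.reshape(shape_r)
        col = np.concatenate(
            [ops.forward(e, v).ravel() for e in range(n_exc)]
        )
        cols.append(col)
    return np.array(cols).T


class TestNormalOperator:
    def test_symmetry(self, tiny_problem, rng):
        slices, basis, kernel, affine, truth, _ = tiny_problem
        x0 = ReconVolume(np.zeros_like(truth), affine)
        ops = ExcitationOperators(
            slices, np.zeros((slices.layout.n_excitations, 6)), basis,
            kernel, affine, x0.center_world,
        )
        cfg = ReconConfig(1e-3, 0.0, 5)  # z-deriv needs depth>=9, off here
        u = rng.normal(size=truth.shape)
        v = rng.normal(size=truth.shape)
        Eu = normal_apply(u, ops, cfg, x0.voxel_size)
        Ev = normal_apply(v, ops, cfg, x0.voxel_size)
        assert np.vdot(Eu, v) == pytest.approx(np.vdot(u, Ev), rel=1e-10)

    def test_zero_weights_zero_reg_is_zero_operator(self, tiny_problem, rng):
        slices, basis, kernel, affine, truth, _ = tiny_problem
        x0 = ReconVolume(np.zeros_like(truth), affine)
        ops = ExcitationOperators(
            slices, np.zeros((slices.layout.n_excitations, 6)), basis,
            kernel, affine, x0.center_world,
        )
        cfg = ReconConfig(0.0, 0.0, 5)
        v = rng.normal(size=truth.shape)
        out = normal_apply(
            v, ops, cfg, x0.voxel_size,
            weights=np.zeros(slices.layout.n_excitations),
        )
        assert np.max(np.abs(out)) == 0.0

    def test_matches_dense_assembly(self, tiny_problem, rng):
        slices, basis, kernel, affine, truth, _ = tiny_problem
        x0 = ReconVolume(np.zeros_like(truth), affine)
        poses = np.zeros((slices.layout.n_excitations, 6))
        ops = ExcitationOperators(
            slices, poses, basis, kernel, affine, x0.center_world
        )
        cfg = ReconConfig(0.0, 0.0, 5)
        A = _dense_forward(ops, slices, truth.shape)
        n_v = slices.grad.n_volumes
        E_dense = A.T @ A / n_v
        v = rng.normal(size=truth.shape)
        got = normal_apply(v, ops, cfg, x0.voxel_size)
        expect = (E_dense @ v.ravel()).reshape(truth.shape)
        assert np.max(np.abs(got - expect)) < 1e-8 * np.abs(expect).max()


class TestSolveReconstruction:
    def test_matches_dense_least_squares(self, tiny_problem):
        """CG solution agrees with a dense regularized LS oracle."""
        slices, basis, kernel, affine, truth, rng = tiny_problem
        x0 = ReconVolume(np.zeros_like(truth), affine)
        poses = np.zeros((slices.layout.n_excitations, 6))
        cfg = ReconConfig(1e-3, 0.0, 50, 1e-12)
        x, residuals, hist = solve_reconstruction(
            slices, poses, basis, cfg, x0, kernel
        )
        ops = ExcitationOperators(
            slices, poses, basis, kernel, affine, x0.center_world
        )
        A = _dense_forward(ops, slices, truth.shape)
        y = np.concatenate(
            [slices.excitation_data(e).ravel() for e in slices.layout.excitations]
        )
        n_v = slices.grad.n_volumes
        # dense Laplacian via operator application to unit vectors
        nvox = truth.size
        L = np.zeros((nvox, nvox))
        from shardrecon.recon import laplacian_apply

        for j in range(nvox):
            v = np.zeros(nvox)
            v[j] = 1.0
            L[:, j] = laplacian_apply(
                v.reshape(truth.shape), x0.voxel_size
            ).ravel()
        E = A.T @ A / n_v + cfg.lambda_**2 * (L.T @ L)
        rhs = A.T @ y / n_v
        expect = np.linalg.solve(E, rhs).reshape(truth.shape)
        rel = np.abs(x.coeffs - expect).max() / np.abs(expect).max()
        assert rel < 1e-5

    def test_consistent_system_recovery(self, tiny_problem):
        """Exact data with zero regularization recovers the generating
        coefficients."""
        slices, basis, kernel, affine, truth, _ = tiny_problem
        x0 = ReconVolume(np.zeros_like(truth), affine)
        poses = np.zeros((slices.layout.n_excitations, 6))
        cfg = ReconConfig(0.0, 0.0, 400, 1e-14)
        x, _, _ = solve_reconstruction(slices, poses, basis, cfg, x0, kernel)
        rel = np.abs(x.coeffs - truth).max() / np.abs(truth).max()
        assert rel < 1e-6

    def test_zero_weight_excitation_has_no_influence(self, tiny_problem):
        slices, basis, kernel, affine, truth, rng = tiny_problem
        x0 = ReconVolume(np.zeros_like(truth), affine)
        poses = np.zeros((slices.layout.n_excitations, 6))
        cfg = ReconConfig(1e-3, 0.0, 30)
        w = np.ones(slices.layout.n_excitations)
        w[7] = 0.0
        data2 = slices.data.copy()
        exc = slices.layout.excitations[7]
        data2[:, :, list(exc.slices), exc.volume] += rng.normal(
            0, 50.0, (6, 6, len(exc.slices))
        )
        s1 = ScatteredSliceSet(
            slices.data, slices.layout, slices.grad, slices.mask, w.copy()
        )
        s2 = ScatteredSliceSet(
            data2, slices.layout, slices.grad, slices.mask, w.copy()
        )
        x1, _, _ = solve_reconstruction(s1, poses, basis, cfg, x0, kernel)
        x2, _, _ = solve_reconstruction(s2, poses, basis, cfg, x0, kernel)
        assert np.allclose(x1.coeffs, x2.coeffs, atol=1e-12)

    def test_residual_norm_non_increasing(self, tiny_problem):
        slices, basis, kernel, affine, truth, _ = tiny_problem
        x0 = ReconVolume(np.zeros_like(truth), affine)
        poses = np.zeros((slices.layout.n_excitations, 6))
        cfg = ReconConfig(1e-3, 0.0, 25)
        _, _, hist = solve_reconstruction(slices, poses, basis, cfg, x0, kernel)
        hist = np.asarray(hist)
        assert np.all(np.diff(hist) <= 1e-8 * hist[0])

    def test_ordering_invariance(self, tiny_problem):
        """The solution does not depend on the excitation ordering."""
        slices, basis, kernel, affine, truth, _ = tiny_problem
        x0 = ReconVolume(np.zeros_like(truth), affine)
        cfg = ReconConfig(1e-3, 0.0, 20)
        poses = np.zeros((slices.layout.n_excitations, 6))
        x1, _, _ = solve_reconstruction(slices, poses, basis, cfg, x0, kernel)
        # reverse the excitation list (and weights accordingly)
        import copy

        layout2 = copy.deepcopy(slices.layout)
        layout2.excitations = layout2.excitations[::-1]
        s2 = ScatteredSliceSet(
            slices.data, layout2, slices.grad, slices.mask,
            slices.weights[::-1].copy(),
        )
        x2, _, _ = solve_reconstruction(s2, poses, basis, cfg, x0, kernel)
        assert np.allclose(x1.coeffs, x2.coeffs, atol=1e-10)

    def test_regularization_monotonicity(self, tiny_problem):
        """Raising lambda lowers the Laplacian energy of the solution."""
        slices, basis, kernel, affine, truth, _ = tiny_problem
        x0 = ReconVolume(np.zeros_like(truth), affine)
        poses = np.zeros((slices.layout.n_excitations, 6))
        energies = []
        for lam in (1e-3, 1e-1):
            cfg = ReconConfig(lam, 0.0, 60, 1e-12)
            x, _, _ = solve_reconstruction(slices, poses, basis, cfg, x0, kernel)
            energies.append(
                float(np.sum(laplacian_apply(x.coeffs, x0.voxel_size) ** 2))
            )
        assert energies[1] <= energies[0] + 1e-12

    def test_nonfinite_data_rejected(self, tiny_problem):
        slices, basis, kernel, affine, truth, _ = tiny_problem
        bad = slices.data.copy()
        bad[0, 0, 0, 0] = np.nan
        s = ScatteredSliceSet(bad, slices.layout, slices.grad, slices.mask)
        with pytest.raises(ValueError):
            solve_reconstruction(
                s, np.zeros((s.layout.n_excitations, 6)), basis,
                ReconConfig(), ReconVolume(np.zeros_like(truth), affine),
                kernel,
            )
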