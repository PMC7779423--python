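"""Epoch-based motion correction: reconstruction, basis refit,
registration, temporal filtering, and outlier reweighting.

One epoch performs, in order:

1. a few conjugate-gradient iterations of the regularized reconstruction
   (warm-started from the previous epoch),
2. a refit of the data-driven SHARD basis from the current
   reconstruction (the low-rank representation improves as the data
   become self-consistent),
3. registration of every volume (early epochs) or every multiband
   excitation (later epochs) against a rank-reduced, spatially smoothed
   prediction of its contrast — a multi-scale strategy in which the
   smoothing FWHM shrinks from 3 to 1 voxel across epochs,
4. two-stage temporal filtering of the pose trace, and
5. per-shell outlier reweighting from the reconstruction residuals.

The process starts from zero motion and uniform slice weights; a final
reconstruction with a larger CG budget produces the output coefficients.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .basis import (
    ShardBasis,
    fit_shard_basis,
    fit_shell_sh,
    project_to_basis,
    project_to_shells,
    qspace_row,
    rank_reduce,
)
from .geometry import (
    AcquisitionLayout,
    ReconVolume,
    ScatteredSliceSet,
    SliceProfile,
    build_layout,
    combined_kernel,
    interp_values,
    pose_matrix,
    reorient_gradient,
)
from .gradients import B0_THRESHOLD, GradientTable
from .motion import (
    MotionTrace,
    apply_prior_weights,
    excitation_rmse,
    fit_outlier_gmm,
    register_to_contrast,
    temporal_filter_stage1,
    temporal_filter_stage2,
)
from .recon import ReconConfig, solve_reconstruction

__all__ = [
    "PipelineConfig",
    "PipelineResult",
    "motion_correct",
    "predict_series",
    "load_nifti",
    "save_nifti",
]


@dataclass
class PipelineConfig:
    """Motion-correction schedule and model parameters.

    Defaults follow the reference schedule: 2 volume-level epochs, then 3
    excitation-level epochs, 3 CG iterations per epoch and 10 in the
    final reconstruction, 10 Levenberg–Marquardt iterations per
    registration, registration-target smoothing FWHM annealed from 3 to 1
    voxel, and lambda = zeta = 1e-3.
    """

    lmax_per_shell: tuple | None = None       # None: largest supported
    reg_components_per_band: tuple = (3, 2, 1)
    lambda_: float = 1e-3
    zeta: float = 1e-3
    n_volume_epochs: int = 2
    n_slice_epochs: int = 3
    cg_iter_epoch: int = 3
    cg_iter_final: int = 10
    lm_iter: int = 10
    smooth_fwhm_start: float = 3.0            # multiples of voxel size
    smooth_fwhm_end: float = 1.0
    multiband: int = 1
    interleave_factor: int = 1
    interleave_shift: int = 1
    prior_slice_weights: dict = field(default_factory=dict)
    assume_unwarped: bool = True              # EPI distortion handled upstream
    seed: int = 0


@dataclass
class PipelineResult:
    recon: ReconVolume
    basis: ShardBasis
    trace: MotionTrace
    weights: np.ndarray
    predicted: np.ndarray
    log: list

    def save_log(self, path) -> None:
        with open(path, "w") as fh:
            for rec in self.log:
                fh.write(json.dumps(rec) + "\n")


def _registration_row(basis_red: ShardBasis, shell: int, bval: float,
                      ghat) -> np.ndarray:
    """q-space row for registration targets; b=0 excitations register
    against the l=0 (spherical-mean-like) contrast only."""
    q = qspace_row(basis_red, shell, ghat)
    if bval <= B0_THRESHOLD and 0 in basis_red.bands:
        masked = np.zeros_like(q)
        sl = basis_red.band_slice(0)
        masked[sl] = q[sl]
        return masked
    return q


def _com_shift(data_vol, target, affine, mu_prev, center):
    """Translation seed from intensity centroids (world mm).

    The forward model samples the target at ``T(mu) q`` for scanner
    points q, so the predicted centroid sits at ``T(mu)^-1 ct``.
    Aligning it with the data centroid cd requires ``T(mu) cd = ct``;
    the residual ``ct - T(mu_prev) cd`` is the translation increment
    (translation is additive in the about-center parameterization).
    Returns None when either image carries no signal.
    """
    from scipy.ndimage import center_of_mass

    d = np.clip(data_vol, 0.0, None)
    t = np.clip(target, 0.0, None)
    if d.sum() <= 0 or t.sum() <= 0:
        return None
    cd = affine[:3, :3] @ np.asarray(center_of_mass(d)) + affine[:3, 3]
    ct = affine[:3, :3] @ np.asarray(center_of_mass(t)) + affine[:3, 3]
    Tp = pose_matrix(mu_prev, center)
    return ct - (Tp[:3, :3] @ cd + Tp[:3, 3])


def _clamped_reduction(basis: ShardBasis, requested) -> ShardBasis:
    """Registration basis: requested components clamped to availability.

    Bands whose requested count exceeds the number of radial components
    the protocol supports are truncated; the spherical-mean band always
    keeps at least one component.
    """
    req = list(requested)
    counts = []
    for i, ell in enumerate(basis.bands):
        want = req[i] if i < len(req) else 0
        counts.append(min(int(want), basis.n_components(ell)))
    if counts[0] < 1:
        counts[0] = 1
    return rank_reduce(basis, counts)


def motion_correct(
    dmri: np.ndarray,
    grad: GradientTable,
    mask: np.ndarray,
    cfg: PipelineConfig,
    ssp: SliceProfile,
    affine: np.ndarray | None = None,
) -> PipelineResult:
    """Run the full epoch schedule on a scattered-slice 4-D series.

    Deterministic for fixed inputs.  Returns the reconstructed
    coefficients, the learned basis, the per-excitation motion trace and
    slice weights, the motion-corrected predicted series (identity
    motion, input gradient table), and a per-epoch log.
    """
    dmri = np.asarray(dmri, dtype=float)
    if affine is None:
        affine = np.eye(4)
    mask = np.asarray(mask, dtype=bool)
    nz = dmri.shape[2]
    layout = build_layout(
        nz, cfg.multiband, cfg.interleave_factor, cfg.interleave_shift, grad
    )
    z_spacing = float(np.linalg.norm(affine[:3, 2]))
    kernel = combined_kernel(ssp, z_spacing)
    lmax = tuple(cfg.lmax_per_shell) if cfg.lmax_per_shell else None
    if lmax is None:
        from .simulate import default_lmax

        lmax = default_lmax(grad)
    # bootstrap: volume-wise SH fit of the raw data (validates direction
    # counts per shell, naming the offending shell on failure)
    sh = fit_shell_sh(dmri, grad, lmax)
    basis = fit_shard_basis(sh, mask)
    # warm start: the static-fit coefficients (zero-motion assumption);
    # the first CG solve refines these under the current trace
    x = ReconVolume(project_to_basis(sh, basis), affine)
    slices = ScatteredSliceSet(dmri, layout, grad, mask)
    trace = np.zeros((layout.n_excitations, 6))
    center = x.center_world
    voxel = x.voxel_size
    n_epochs = cfg.n_volume_epochs + cfg.n_slice_epochs
    log: list = []


    for epoch in range(n_epochs):
        rcfg = ReconConfig(cfg.lambda_, cfg.zeta, cfg.cg_iter_epoch)
        x, residuals, hist = solve_reconstruction(
            slices, trace, basis, rcfg, x, kernel
        )
        # outlier reweighting from this epoch's reconstruction residuals;
        # the updated weights drive both the temporal filter below and
        # the next reconstruction
        rmse = np.array(
            [
                excitation_rmse(residuals[e], slices.excitation_mask(exc))
                for e, exc in enumerate(layout.excitations)
            ]
        )
        weights = np.ones(layout.n_excitations)
        for s in range(grad.n_shells):
            sel = np.array(
                [i for i, e in enumerate(layout.excitations) if e.shell == s]
            )
            vals = rmse[sel]
            if np.sum(np.isfinite(vals) & (vals > 0)) >= 8:
                _, w = fit_outlier_gmm(vals, shell=s)
                weights[sel] = w
        weights = apply_prior_weights(weights, layout, cfg.prior_slice_weights)
        slices.weights = weights
        # refit the SHARD basis from the current reconstruction
        sh_cur = project_to_shells(x.coeffs, basis)
        basis = fit_shard_basis(sh_cur, mask)
        x = ReconVolume(project_to_basis(sh_cur, basis), affine)
        # rank-reduced, smoothed registration source
        red = _clamped_reduction(basis, cfg.reg_components_per_band)
        red_coeffs = project_to_basis(sh_cur, red)
        frac = epoch / max(n_epochs - 1, 1)
        fwhm_vox = (
            cfg.smooth_fwhm_start
            + (cfg.smooth_fwhm_end - cfg.smooth_fwhm_start) * frac
        )
        sigma = fwhm_vox / (2.0 * np.sqrt(2.0 * np.log(2.0)))
        # multi-scale registration with matched blur on both sides: the
        # source and the acquired slices are smoothed in-plane at the
        # same scale (slices cannot be smoothed through-plane; along z
        # both sides already carry the slice-profile blur, the source
        # through the forward operator)
        sm = gaussian_filter(red_coeffs, (sigma, sigma, 0.0, 0.0),
                             mode="nearest")
        data_sm = gaussian_filter(dmri, (sigma, sigma, 0.0, 0.0),
                                  mode="nearest")
        volume_level = epoch < cfg.n_volume_epochs
        new_trace = trace.copy()
        for v in range(grad.n_volumes):
            excs = layout.volume_excitations(v)
            idx = [e.t for e in excs]
            mu_prev = trace[idx].mean(axis=0)
            exc0 = excs[0]
            ghat = reorient_gradient(mu_prev, exc0.direction)
            q = _registration_row(red, exc0.shell, exc0.bval, ghat)
            target = np.tensordot(sm, q, axes=([3], [0]))
            if epoch == 0:
                # whole-FOV translation capture: seed from the intensity
                # centroids before local optimization
                shift = _com_shift(
                    data_sm[:, :, :, v], target, affine, mu_prev, center
                )
                if shift is not None:
                    mu_prev = mu_prev.copy()
                    mu_prev[:3] += shift
            if volume_level:
                all_slices = [
                    (z, weights[e.t]) for e in excs for z in e.slices
                ]
                all_slices.sort()
                zs = tuple(z for z, _ in all_slices)
                zw = np.array([w for _, w in all_slices])
                y = data_sm[:, :, list(zs), v]
                res = register_to_contrast(
                    y, target, affine, center, zs, kernel, mu_prev,
                    cfg.lm_iter,
                    dof="translation" if epoch == 0 else "full",
                    slice_weights=zw,
                )
                for t in idx:
                    new_trace[t] = res.mu
            else:
                for e in excs:
                    y = data_sm[:, :, list(e.slices), e.volume]
                    # a thin stack constrains 6 dof weakly: keep each
                    # refinement local to the temporally filtered init
                    res = register_to_contrast(
                        y, target, affine, center, e.slices, kernel,
                        trace[e.t], cfg.lm_iter,
                        max_shift=4.0, max_rot=0.05,
                    )
                    new_trace[e.t] = res.mu
        # temporal filtering with this epoch's slice weights
        if not np.all(slices.weights == 0):
            new_trace = temporal_filter_stage1(new_trace, slices.weights)
        new_trace = temporal_filter_stage2(new_trace, 5)
        trace = new_trace
        data_fit = float(
            sum(
                weights[e] * np.sum(residuals[e] ** 2)
                for e in range(layout.n_excitations)
            )
            / grad.n_volumes
        )
        log.append(
            {
                "epoch": epoch,
                "level": "volume" if volume_level else "slice",
                "data_fit": data_fit,
                "cg_residual": hist[-1],
                "mean_weight": float(weights.mean()),
                "trace_trans_rms_mm": float(
                    np.sqrt(np.mean(trace[:, :3] ** 2))
                ),
                "trace_rot_rms_deg": float(
                    np.degrees(np.sqrt(np.mean(trace[:, 3:] ** 2)))
                ),
            }
        )

    rcfg = ReconConfig(cfg.lambda_, cfg.zeta, cfg.cg_iter_final)
    x, residuals, hist = solve_reconstruction(
        slices, trace, basis, rcfg, x, kernel
    )
    log.append({"epoch": n_epochs, "level": "final", "cg_residual": hist[-1]})
    predicted = predict_series(x, basis, grad)
    return PipelineResult(
        x, basis, MotionTrace(trace), slices.weights, predicted, log
    )


def predict_series(
    x: ReconVolume,
    basis: ShardBasis,
    grad: GradientTable,
    trace=None,
    shell_b: np.ndarray | None = None,
) -> np.ndarray:
    """Render a dMRI series from the reconstruction.

    Evaluates the SHARD representation at every volume of `grad` on the
    reconstruction grid, with identity motion by default; a per-volume
    pose (mean over the volume's excitations) resamples the rendered
    contrast when a trace and layout-compatible poses are supplied as an
    ``(n_volumes, 6)`` array.  If `shell_b` (the basis' training shell
    b-values) is given, the requested shells are matched against it and
    an unmatched shell raises.
    """
    if shell_b is not None:
        shell_map = []
        for b in grad.shell_b:
            d = np.abs(np.asarray(shell_b, dtype=float) - b)
            if d.min() > 100.0:
                raise ValueError(f"no basis shell near b={b:.0f}")
            shell_map.append(int(d.argmin()))
    else:
        if grad.n_shells != basis.n_shells:
            raise ValueError(
                "gradient table shell count does not match the basis"
            )
        shell_map = list(range(grad.n_shells))
    poses = None
    if trace is not None:
        poses = np.atleast_2d(np.asarray(trace, dtype=float))
        if poses.shape[0] != grad.n_volumes:
            raise ValueError("need one pose per volume")
    out = np.zeros(x.shape + (grad.n_volumes,))
    inv = np.linalg.inv(x.affine)
    coords_cache = None
    for v in range(grad.n_volumes):
        mu = None if poses is None else poses[v]
        d = grad.bvecs[v]
        if mu is not None:
            d = reorient_gradient(mu, d)
        q = qspace_row(basis, shell_map[int(grad.shell_index[v])], d)
        vol = np.tensordot(x.coeffs, q, axes=([3], [0]))
        if mu is None or not np.any(mu):
            out[..., v] = vol
            continue
        if coords_cache is None:
            ii, jj, kk = np.meshgrid(
                *[np.arange(s) for s in x.shape], indexing="ij"
            )
            vox = np.column_stack(
                [ii.ravel(), jj.ravel(), kk.ravel()]
            ).astype(float)
            coords_cache = vox @ x.affine[:3, :3].T + x.affine[:3, 3]
        Tm = pose_matrix(mu, x.center_world)
        moved = coords_cache @ Tm[:3, :3].T + Tm[:3, 3]
        cc = moved @ inv[:3, :3].T + inv[:3, 3]
        out[..., v] = interp_values(vol, cc).reshape(x.shape)
    return out


# ---------------------------------------------------------------------------
# NIfTI I/O

def load_nifti(path):
    """Read a NIfTI image; returns (data, affine)."""
    import nibabel as nib

    img = nib.load(str(path))
    return np.asarray(img.get_fdata(), dtype=float), img.affine


def save_nifti(path, data, affine, description: str = "") -> None:
    import nibabel as nib

    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine)
    if description:
        img.header["descrip"] = description.encode()[:79]
    nib.save(img, str(path))
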