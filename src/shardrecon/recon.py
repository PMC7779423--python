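"""Regularized least-squares reconstruction of the SHARD coefficients.

Given scattered, weighted slice data and a fixed motion trace, the
reconstruction solves

    min_x  (1/n_v) sum_s w_s ||y_s - R_s x||^2
           + lambda^2 ||L x||^2 + zeta^2 ||Z x||^2

where ``R_s = B_s M(mu_s) Q_s`` is the per-excitation forward operator,
``L`` an isotropic Laplacian (stabilizes undersampled regions) and ``Z``
an 8th-order finite-difference filter along the slice axis (tames the
high frequencies amplified by slice-profile deconvolution).  The normal
equations are solved with a matrix-free conjugate-gradient method: the
system matrix is never materialized; only per-excitation sparse slice
operators and separable convolutions are applied.

The 1/n_v data-term normalization is folded into the operator so the
regularization weights keep their intended scale; weights enter the
normal equations linearly (w_s multiplying both R_s^T R_s and R_s^T y_s),
consistent with the weighted cost above.  Both regularizers use
reflective boundaries, which avoids penalizing tissue at the grid edge
and keeps the operators symmetric.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import correlate1d

from .geometry import (
    ReconVolume,
    ScatteredSliceSet,
    excitation_operator,
    reorient_gradient,
)
from .basis import qspace_row

__all__ = [
    "ReconConfig",
    "laplacian_apply",
    "zderiv8_apply",
    "ExcitationOperators",
    "normal_apply",
    "solve_reconstruction",
]

_Z8 = np.array([1.0, -8.0, 28.0, -56.0, 70.0, -56.0, 28.0, -8.0, 1.0])


@dataclass
class ReconConfig:
    """Reconstruction parameters.

    lambda_ : weight of the isotropic Laplacian penalty (default 1e-3).
    zeta : weight of the 8th-order z-derivative penalty (default 1e-3).
    max_cg_iter : conjugate-gradient iteration cap (primary stop).
    cg_tolerance : relative normal-residual threshold (safeguard stop).
    """

    lambda_: float = 1e-3
    zeta: float = 1e-3
    max_cg_iter: int = 10
    cg_tolerance: float = 1e-8

    def __post_init__(self) -> None:
        if self.lambda_ < 0 or self.zeta < 0:
            raise ValueError("regularization weights must be non-negative")
        if self.max_cg_iter < 1:
            raise ValueError("max_cg_iter must be at least 1")


def laplacian_apply(image: np.ndarray, voxel_size) -> np.ndarray:
    """7-point discrete Laplacian per coefficient channel (units mm^-2).

    Each axis contributes the [1, -2, 1] second-difference stencil scaled
    by 1/voxel_size^2, with reflective (half-sample symmetric) boundaries.
    """
    image = np.asarray(image, dtype=float)
    voxel_size = np.asarray(voxel_size, dtype=float).ravel()
    out = np.zeros_like(image)
    for ax in range(3):
        out += correlate1d(
            image, np.array([1.0, -2.0, 1.0]) / voxel_size[ax] ** 2,
            axis=ax, mode="reflect",
        )
    return out


def zderiv8_apply(image: np.ndarray) -> np.ndarray:
    """8th-order finite-difference filter along the slice (z) axis.

    Convolution with the binomial kernel [1,-8,28,-56,70,-56,28,-8,1]
    (annihilates polynomials of degree < 8), reflective boundaries.
    """
    image = np.asarray(image, dtype=float)
    if image.shape[2] < 9:
        raise ValueError("z-derivative filter needs depth >= 9 in z")
    return correlate1d(image, _Z8, axis=2, mode="reflect")


class ExcitationOperators:
    """Per-excitation sparse slice operators for a fixed motion trace.

    Holds, for every excitation, the q-space row for its reoriented
    encoding and the sparse ``B_s M(mu_s)`` matrix.  Building these once
    lets every CG iteration reduce to sparse mat-vecs.
    """

    def __init__(self, slices: ScatteredSliceSet, trace, basis, kernel,
                 affine, center):
        self.slices = slices
        self.basis = basis
        self.kernel = kernel
        self.affine = np.asarray(affine, dtype=float)
        self.center = center
        shape = slices.data.shape[:3]
        poses = np.asarray(trace, dtype=float)
        self.q_rows = []
        self.ops = []
        for e, exc in enumerate(slices.layout.excitations):
            mu = poses[e]
            ghat = reorient_gradient(mu, exc.direction)
            self.q_rows.append(qspace_row(basis, exc.shell, ghat))
            self.ops.append(
                excitation_operator(shape, self.affine, mu, exc.slices,
                                    kernel, center)
            )
        self.shape = shape

    def forward(self, e: int, coeffs: np.ndarray) -> np.ndarray:
        c = np.tensordot(coeffs, self.q_rows[e], axes=([3], [0]))
        y = self.ops[e] @ c.ravel(order="C")
        exc = self.slices.layout.excitations[e]
        nx, ny, _ = self.shape
        return y.reshape(len(exc.slices), nx, ny).transpose(1, 2, 0)

    def adjoint(self, e: int, residual: np.ndarray) -> np.ndarray:
        r = residual.transpose(2, 0, 1).ravel(order="C")
        g = (self.ops[e].T @ r).reshape(self.shape)
        return g[..., None] * self.q_rows[e]


def normal_apply(
    v: np.ndarray, ops: ExcitationOperators, cfg: ReconConfig, voxel_size,
    weights=None,
) -> np.ndarray:
    """Apply the normal-equation operator E to a coefficient image.

    ``E v = (1/n_v) sum_s w_s R_s^T R_s v + lambda^2 L^T L v
    + zeta^2 Z^T Z v``; symmetric positive semi-definite, matrix-free.
    """
    w = ops.slices.weights if weights is None else np.asarray(weights, float)
    n_v = ops.slices.grad.n_volumes
    out = np.zeros_like(v)
    for e in range(len(ops.ops)):
        if w[e] == 0.0:
            continue
        out += w[e] * ops.adjoint(e, ops.forward(e, v))
    out /= n_v
    if cfg.lambda_ > 0:
        out += cfg.lambda_**2 * laplacian_apply(
            laplacian_apply(v, voxel_size), voxel_size
        )
    if cfg.zeta > 0:
        out += cfg.zeta**2 * zderiv8_apply(zderiv8_apply(v))
    return out


def solve_reconstruction(
    slices: ScatteredSliceSet,
    trace,
    basis,
    cfg: ReconConfig,
    x_init: ReconVolume,
    kernel,
    ops: ExcitationOperators | None = None,
):
    """Conjugate-gradient solve of the normal equations.

    Runs CG from `x_init` for at most ``cfg.max_cg_iter`` iterations or
    until the relative normal-equation residual drops below
    ``cfg.cg_tolerance``.  Returns the solution `ReconVolume`, the
    per-excitation data residuals ``y_s - R_s x`` (for outlier scoring),
    and the normal-residual history.
    """
    if not np.all(np.isfinite(slices.data)):
        raise ValueError("non-finite values in slice data")
    poses = np.asarray(trace, dtype=float)
    if ops is None:
        ops = ExcitationOperators(
            slices, poses, basis, kernel, x_init.affine, x_init.center_world
        )
    voxel_size = x_init.voxel_size
    w = slices.weights
    n_v = slices.grad.n_volumes
    # right-hand side (1/n_v) sum_s w_s R_s^T y_s
    rhs = np.zeros_like(x_init.coeffs)
    for e, exc in enumerate(slices.layout.excitations):
        if w[e] == 0.0:
            continue
        rhs += w[e] * ops.adjoint(e, slices.excitation_data(exc))
    rhs /= n_v

    x = x_init.coeffs.copy()
    r = rhs - normal_apply(x, ops, cfg, voxel_size)
    p = r.copy()
    rs = float(np.vdot(r, r))
    rs0 = rs if rs > 0 else 1.0
    history = [np.sqrt(rs)]
    for _ in range(cfg.max_cg_iter):
        if np.sqrt(rs / rs0) < cfg.cg_tolerance:
            break
        Ep = normal_apply(p, ops, cfg, voxel_size)
        denom = float(np.vdot(p, Ep))
        if denom <= 0:
            break
        alpha = rs / denom
        x += alpha * p
        r -= alpha * Ep
        rs_new = float(np.vdot(r, r))
        history.append(np.sqrt(rs_new))
        p = r + (rs_new / rs) * p
        rs = rs_new
    residuals = [
        slices.excitation_data(exc) - ops.forward(e, x)
        for e, exc in enumerate(slices.layout.excitations)
    ]
    return ReconVolume(x, x_init.affine), residuals, history
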