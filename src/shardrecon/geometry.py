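"""Rigid motion, slice-profile kernels, and the scattered-slice forward model.

Conventions
-----------
* Rigid poses are 6-vectors ``mu = [tx, ty, tz, rx, ry, rz]`` in the Lie
  algebra se(3): translations in mm, rotations as the (dimensionless,
  radian-scaled) coefficients of the so(3) generators.  ``se3_exp`` maps a
  pose to a 4x4 homogeneous transform via the matrix exponential.
* ``T(mu)`` maps scanner coordinates to subject coordinates: a slice
  prediction samples the subject-space reconstruction at ``T(mu) p`` for
  every scanner grid point ``p``.  Gradient reorientation consequently
  uses the transpose rotation, expressing the scanner-fixed encoding
  direction in the subject frame.
* Rotations act about a stated center (by default the field-of-view
  center in world mm), which decouples rotation from translation
  numerically during registration.
* Interpolation uses the interpolating Keys cubic-convolution kernel
  (a = -1/2, 4-point support); samples outside the reconstruction grid
  are zero (air/masked background).
* The slice-selection operator ``B_s`` convolves along the scanner z-axis
  with the *combined* kernel — the continuous convolution of the cubic
  interpolation kernel and the slice sensitivity profile (SSP), sampled
  at the slice separation — and evaluates at the excitation's slice
  indices.  The combined kernel is normalized to unit sum so constant
  images keep their intensity scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from . import _fast
from .gradients import B0_THRESHOLD, GradientTable

__all__ = [
    "se3_exp",
    "se3_log",
    "mean_pose",
    "reorient_gradient",
    "pose_matrix",
    "SliceProfile",
    "combined_kernel",
    "AcquisitionLayout",
    "Excitation",
    "build_layout",
    "ScatteredSliceSet",
    "ReconVolume",
    "excitation_operator",
    "predict_excitation",
    "adjoint_excitation",
    "cubic_kernel",
    "interp_matrix",
    "interp_values",
    "interp_value_and_gradient",
]


# ---------------------------------------------------------------------------
# se(3)

def _skew(w: np.ndarray) -> np.ndarray:
    return np.array(
        [[0.0, -w[2], w[1]], [w[2], 0.0, -w[0]], [-w[1], w[0], 0.0]]
    )


def _vee(W: np.ndarray) -> np.ndarray:
    return np.array([W[2, 1], W[0, 2], W[1, 0]])


def se3_exp(mu) -> np.ndarray:
    """Matrix exponential of the se(3) generator of pose `mu` (4x4)."""
    mu = np.asarray(mu, dtype=float).ravel()
    if mu.shape != (6,):
        raise ValueError("pose must be a 6-vector")
    t, w = mu[:3], mu[3:]
    W = _skew(w)
    W2 = W @ W
    th = np.linalg.norm(w)
    if th < 1e-8:
        # series to O(th^4): exact enough at double precision
        R = np.eye(3) + W + 0.5 * W2
        V = np.eye(3) + 0.5 * W + W2 / 6.0
    else:
        a = np.sin(th) / th
        b = (1.0 - np.cos(th)) / th**2
        c = (th - np.sin(th)) / th**3
        R = np.eye(3) + a * W + b * W2
        V = np.eye(3) + b * W + c * W2
    T = np.eye(4)
    T[:3, :3] = R
    T[:3, 3] = V @ t
    return T


def se3_log(T) -> np.ndarray:
    """Principal matrix logarithm of a rigid transform, as a 6-vector.

    Inverse of `se3_exp` on the principal branch; a rotation angle of pi
    raises (branch ambiguity).
    """
    T = np.asarray(T, dtype=float)
    R = T[:3, :3]
    if np.abs(np.linalg.det(R) - 1.0) > 1e-6 or np.max(
        np.abs(R.T @ R - np.eye(3))
    ) > 1e-6:
        raise ValueError("transform is not rigid")
    cos_th = np.clip((np.trace(R) - 1.0) / 2.0, -1.0, 1.0)
    th = np.arccos(cos_th)
    if th > np.pi - 1e-6:
        raise ValueError("rotation angle at pi: logarithm branch ambiguous")
    if th < 1e-8:
        w = _vee((R - R.T) / 2.0)
        W = _skew(w)
        Vinv = np.eye(3) - 0.5 * W + (W @ W) / 12.0
    else:
        w = th / (2.0 * np.sin(th)) * _vee(R - R.T)
        W = _skew(w)
        coef = (1.0 - th * np.cos(th / 2.0) / (2.0 * np.sin(th / 2.0))) / th**2
        Vinv = np.eye(3) - 0.5 * W + coef * (W @ W)
    t = Vinv @ T[:3, 3]
    return np.concatenate([t, w])


def mean_pose(poses) -> np.ndarray:
    """Arithmetic mean of se(3) pose vectors (linearized manifold mean)."""
    p = np.atleast_2d(np.asarray(poses, dtype=float))
    if p.size == 0:
        raise ValueError("empty motion trace")
    return p.mean(axis=0)


def reorient_gradient(mu, direction) -> np.ndarray:
    """Express a scanner-fixed encoding direction in the subject frame.

    Returns ``R^T d`` where R is the rotation block of ``se3_exp(mu)``.
    """
    R = se3_exp(mu)[:3, :3]
    return R.T @ np.asarray(direction, dtype=float)


def pose_matrix(mu, center=None) -> np.ndarray:
    """World-space rigid transform of pose `mu` acting about `center` (mm)."""
    T = se3_exp(mu)
    if center is not None:
        c = np.asarray(center, dtype=float)
        T = T.copy()
        T[:3, 3] += c - T[:3, :3] @ c
    return T


def compose_pose(delta, mu) -> np.ndarray:
    """Left-compose an increment: pose of ``exp(delta) exp(mu)``."""
    return se3_log(se3_exp(delta) @ se3_exp(mu))


# ---------------------------------------------------------------------------
# Slice profile and combined kernel

@dataclass
class SliceProfile:
    """Through-plane slice sensitivity profile (SSP).

    Either a Gaussian of given FWHM (mm) or a sampled profile on a stated
    z-grid (mm).  The profile is normalized to unit integral before use.
    """

    mode: str = "gaussian"
    fwhm: float = 0.0
    sample_z: np.ndarray | None = None
    samples: np.ndarray | None = None
    slice_thickness: float | None = None
    slice_spacing: float | None = None

    @classmethod
    def gaussian(cls, fwhm: float, **kw) -> "SliceProfile":
        if fwhm < 0:
            raise ValueError("FWHM must be non-negative")
        return cls(mode="gaussian", fwhm=float(fwhm), **kw)

    @classmethod
    def sampled(cls, z, values, **kw) -> "SliceProfile":
        z = np.asarray(z, dtype=float)
        v = np.asarray(values, dtype=float)
        if z.shape != v.shape or z.ndim != 1:
            raise ValueError("sampled profile needs matching 1-D z and values")
        if np.any(v < 0):
            raise ValueError("profile must be non-negative")
        return cls(mode="sampled", sample_z=z, samples=v, **kw)


def cubic_kernel(x) -> np.ndarray:
    """Keys cubic-convolution kernel with a = -1/2 (interpolating)."""
    ax = np.abs(np.asarray(x, dtype=float))
    out = np.zeros_like(ax)
    m1 = ax <= 1.0
    out[m1] = (1.5 * ax[m1] - 2.5) * ax[m1] ** 2 + 1.0
    m2 = (ax > 1.0) & (ax < 2.0)
    out[m2] = ((-0.5 * ax[m2] + 2.5) * ax[m2] - 4.0) * ax[m2] + 2.0
    return out


def cubic_kernel_deriv(x) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    s = np.sign(x)
    ax = np.abs(x)
    out = np.zeros_like(ax)
    m1 = ax <= 1.0
    out[m1] = (4.5 * ax[m1] - 5.0) * ax[m1]
    m2 = (ax > 1.0) & (ax < 2.0)
    out[m2] = (-1.5 * ax[m2] + 5.0) * ax[m2] - 4.0
    return s * out


def _ssp_fine(profile: SliceProfile):
    """Sampled SSP on a fine symmetric grid (u, d(u), du)."""
    if profile.mode == "gaussian":
        fwhm = max(profile.fwhm, 0.0)
        sigma = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0))) if fwhm > 0 else 0.0
        if sigma == 0.0:
            return None  # exact delta
        U = 4.5 * sigma
        n = 4001
        u = np.linspace(-U, U, n)
        d = np.exp(-0.5 * (u / sigma) ** 2)
    elif profile.mode == "sampled":
        z = profile.sample_z
        v = profile.samples
        U = max(np.max(np.abs(z)), 1e-9)
        n = max(4001, 8 * z.size)
        u = np.linspace(-U, U, n)
        d = np.interp(u, z, v, left=0.0, right=0.0)
    else:
        raise ValueError(f"unknown profile mode {profile.mode!r}")
    du = u[1] - u[0]
    integral = np.trapezoid(d, dx=du)
    if integral <= 0:
        raise ValueError("slice profile has non-positive integral")
    return u, d / integral, du


def combined_kernel(profile: SliceProfile, grid_spacing: float) -> np.ndarray:
    """Discrete through-plane kernel: cubic kernel convolved with the SSP.

    The continuous convolution of the Keys cubic interpolation kernel
    (width in units of `grid_spacing`) with the unit-integral SSP, sampled
    at integer multiples of `grid_spacing`.  Returned as an odd-length
    array normalized to unit sum; entry ``len(k)//2`` is the center tap.
    """
    if grid_spacing <= 0:
        raise ValueError("grid spacing must be positive")
    fine = _ssp_fine(profile)
    if fine is None:
        # delta SSP: the interpolating cubic sampled at integers
        return np.array([1.0])
    u, d, du = fine
    U = u[-1]
    K = int(np.ceil(2.0 + U / grid_spacing))
    taps = np.arange(-K, K + 1)
    # k(n*D) = int d(u) * b((n*D - u)/D) du
    arg = (taps[:, None] * grid_spacing - u[None, :]) / grid_spacing
    k = np.trapezoid(d[None, :] * cubic_kernel(arg), dx=du, axis=1)
    k[np.abs(k) < 1e-5 * np.abs(k).max()] = 0.0
    nz = np.flatnonzero(k)
    if nz.size:
        h = max(abs(taps[nz[0]]), abs(taps[nz[-1]]))
        k = k[K - h : K + h + 1]
    s = k.sum()
    if s <= 0:
        raise ValueError("combined kernel has non-positive sum")
    return k / s


# ---------------------------------------------------------------------------
# Acquisition layout

@dataclass
class Excitation:
    """One multiband excitation: the atomic unit of subject motion."""

    t: int                  # acquisition time index
    volume: int             # volume the slices belong to
    slices: tuple           # z-indices of the simultaneously excited group
    shell: int              # shell index in the gradient table
    bval: float
    direction: np.ndarray   # scanner-frame unit encoding direction


@dataclass
class AcquisitionLayout:
    n_slices: int
    multiband: int
    interleave_factor: int
    interleave_shift: int
    n_volumes: int
    excitations: list = field(default_factory=list)

    @property
    def n_excitations(self) -> int:
        return len(self.excitations)

    @property
    def excitations_per_volume(self) -> int:
        return self.n_slices // self.multiband

    def by_time(self) -> list:
        return sorted(self.excitations, key=lambda e: e.t)

    def volume_excitations(self, volume: int) -> list:
        return [e for e in self.excitations if e.volume == volume]


def _interleave_offsets(interleave: int, shift: int) -> list:
    offs = []
    for i in range(interleave):
        o = (i * shift) % interleave
        if o not in offs:
            offs.append(o)
    for o in range(interleave):  # degenerate shift: fill remaining in order
        if o not in offs:
            offs.append(o)
    return offs


def build_layout(
    n_slices: int,
    multiband: int,
    interleave_factor: int,
    interleave_shift: int,
    grad: GradientTable,
) -> AcquisitionLayout:
    """Deterministic temporally ordered excitation list.

    Slices are grouped into multiband groups of evenly spaced slices
    (group g holds slices ``g, g + n_groups, ...``).  Within each volume
    the groups are acquired interleaved: first groups ``0, f, 2f, ...``,
    then the offset advanced by `interleave_shift` (mod f), and so on.
    Volumes are acquired sequentially.
    """
    if n_slices % multiband:
        raise ValueError("n_slices must be divisible by the multiband factor")
    n_groups = n_slices // multiband
    if interleave_factor < 1 or interleave_factor > n_groups:
        raise ValueError("invalid interleave factor")
    offs = _interleave_offsets(interleave_factor, interleave_shift)
    group_order = [
        g for o in offs for g in range(o, n_groups, interleave_factor)
    ]
    layout = AcquisitionLayout(
        n_slices, multiband, interleave_factor, interleave_shift, grad.n_volumes
    )
    t = 0
    for v in range(grad.n_volumes):
        for g in group_order:
            slices = tuple(g + i * n_groups for i in range(multiband))
            layout.excitations.append(
                Excitation(
                    t=t,
                    volume=v,
                    slices=slices,
                    shell=int(grad.shell_index[v]),
                    bval=float(grad.bvals[v]),
                    direction=grad.bvecs[v].copy(),
                )
            )
            t += 1
    return layout


@dataclass
class ScatteredSliceSet:
    """Acquired slice data plus layout, gradients, mask and slice weights."""

    data: np.ndarray          # (nx, ny, nz, n_volumes)
    layout: AcquisitionLayout
    grad: GradientTable
    mask: np.ndarray          # (nx, ny, nz) boolean
    weights: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4 or self.data.shape[2] != self.layout.n_slices:
            raise ValueError("data shape inconsistent with layout")
        if self.data.shape[3] != self.grad.n_volumes:
            raise ValueError("data volume count inconsistent with gradients")
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.weights is None:
            self.weights = np.ones(self.layout.n_excitations)
        self.weights = np.asarray(self.weights, dtype=float)
        if np.any((self.weights < 0) | (self.weights > 1)):
            raise ValueError("weights must lie in [0, 1]")

    def excitation_data(self, exc: Excitation) -> np.ndarray:
        return self.data[:, :, list(exc.slices), exc.volume]

    def excitation_mask(self, exc: Excitation) -> np.ndarray:
        return self.mask[:, :, list(exc.slices)]


@dataclass
class ReconVolume:
    """4-D grid of SHARD coefficients with world affine."""

    coeffs: np.ndarray    # (nx, ny, nz, r)
    affine: np.ndarray    # voxel-to-world, 4x4

    def __post_init__(self) -> None:
        self.coeffs = np.asarray(self.coeffs, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.coeffs.ndim != 4:
            raise ValueError("coefficients must be a 4-D array")
        if self.affine.shape != (4, 4) or abs(np.linalg.det(self.affine)) < 1e-12:
            raise ValueError("affine must be an invertible 4x4 matrix")

    @property
    def shape(self) -> tuple:
        return self.coeffs.shape[:3]

    @property
    def voxel_size(self) -> np.ndarray:
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def center_world(self) -> np.ndarray:
        c = (np.asarray(self.shape, dtype=float) - 1.0) / 2.0
        return self.affine[:3, :3] @ c + self.affine[:3, 3]


# ---------------------------------------------------------------------------
# Keys cubic interpolation (values, gradients, sparse operator)

_OFFS = np.array([-1, 0, 1, 2])


def _cr_weights(t: np.ndarray) -> np.ndarray:
    """Catmull-Rom weights of the 4 neighbors at offsets -1..2 for
    fractional position t in [0, 1); closed form of the Keys a=-1/2
    kernel evaluated at t+1, t, 1-t, 2-t."""
    t2 = t * t
    t3 = t2 * t
    w = np.empty(t.shape + (4,))
    w[..., 0] = 0.5 * (-t3 + 2.0 * t2 - t)
    w[..., 1] = 0.5 * (3.0 * t3 - 5.0 * t2 + 2.0)
    w[..., 2] = 0.5 * (-3.0 * t3 + 4.0 * t2 + t)
    w[..., 3] = 0.5 * (t3 - t2)
    return w


def _cr_weights_deriv(t: np.ndarray) -> np.ndarray:
    t2 = t * t
    d = np.empty(t.shape + (4,))
    d[..., 0] = 0.5 * (-3.0 * t2 + 4.0 * t - 1.0)
    d[..., 1] = 0.5 * (9.0 * t2 - 10.0 * t)
    d[..., 2] = 0.5 * (-9.0 * t2 + 8.0 * t + 1.0)
    d[..., 3] = 0.5 * (3.0 * t2 - 2.0 * t)
    return d


def _stencil(shape, coords, deriv: bool = False):
    """4x4x4 neighborhood columns and weights for each sample point.

    Returns flattened column indices (n, 64) into the C-ordered volume
    and the separable weight products; out-of-grid neighbors get weight
    zero (and a clamped, unused index).  With `deriv`, also returns the
    three weight products differentiated along each axis.
    """
    nx, ny, nz = shape
    coords = np.asarray(coords, dtype=float)
    base = np.floor(coords).astype(np.int64)
    frac = coords - base
    ix = base[:, 0, None] + _OFFS
    iy = base[:, 1, None] + _OFFS
    iz = base[:, 2, None] + _OFFS
    wx = _cr_weights(frac[:, 0])
    wy = _cr_weights(frac[:, 1])
    wz = _cr_weights(frac[:, 2])
    valid = (
        ((ix >= 0) & (ix < nx))[:, :, None, None]
        & ((iy >= 0) & (iy < ny))[:, None, :, None]
        & ((iz >= 0) & (iz < nz))[:, None, None, :]
    )
    cols = (
        (np.clip(ix, 0, nx - 1)[:, :, None, None] * ny
         + np.clip(iy, 0, ny - 1)[:, None, :, None]) * nz
        + np.clip(iz, 0, nz - 1)[:, None, None, :]
    )
    n = coords.shape[0]
    w = np.where(
        valid,
        wx[:, :, None, None] * wy[:, None, :, None] * wz[:, None, None, :],
        0.0,
    ).reshape(n, 64)
    cols = cols.reshape(n, 64)
    if not deriv:
        return cols, w
    dwx = _cr_weights_deriv(frac[:, 0])
    dwy = _cr_weights_deriv(frac[:, 1])
    dwz = _cr_weights_deriv(frac[:, 2])
    dw = [
        np.where(valid, a[:, :, None, None] * b[:, None, :, None]
                 * c[:, None, None, :], 0.0).reshape(n, 64)
        for a, b, c in ((dwx, wy, wz), (wx, dwy, wz), (wx, wy, dwz))
    ]
    return cols, w, dw


def interp_values(vol: np.ndarray, coords: np.ndarray) -> np.ndarray:
    """Keys cubic interpolation of `vol` at voxel coordinates (n, 3).

    Points sampling outside the grid contribute zero.
    """
    coords = np.ascontiguousarray(coords, dtype=float)
    if _fast.HAVE_NUMBA:
        out = np.empty(coords.shape[0])
        _fast.nb_interp(np.ascontiguousarray(vol, dtype=float), coords, out)
        return out
    cols, w = _stencil(vol.shape, coords)
    return np.einsum("nk,nk->n", w, vol.ravel()[cols])


def interp_value_and_gradient(vol: np.ndarray, coords: np.ndarray):
    """Interpolated values and their gradient w.r.t. voxel coordinates."""
    coords = np.ascontiguousarray(coords, dtype=float)
    if _fast.HAVE_NUMBA:
        out = np.empty(coords.shape[0])
        grad = np.empty((coords.shape[0], 3))
        _fast.nb_interp_grad(
            np.ascontiguousarray(vol, dtype=float), coords, out, grad
        )
        return out, grad
    cols, w, dw = _stencil(vol.shape, coords, deriv=True)
    v = vol.ravel()[cols]
    out = np.einsum("nk,nk->n", w, v)
    grad = np.stack([np.einsum("nk,nk->n", d, v) for d in dw], axis=1)
    return out, grad


def interp_matrix(shape, coords) -> sp.csr_matrix:
    """Sparse matrix mapping a flattened volume to cubic samples at `coords`."""
    coords = np.ascontiguousarray(coords, dtype=float)
    n = coords.shape[0]
    if _fast.HAVE_NUMBA:
        cols = np.empty((n, 64), dtype=np.int64)
        w = np.empty((n, 64))
        _fast.nb_stencil(coords, *map(int, shape), cols, w)
    else:
        cols, w = _stencil(shape, coords)
    indptr = np.arange(0, 64 * (n + 1), 64)
    A = sp.csr_matrix(
        (w.ravel(), cols.ravel(), indptr), shape=(n, int(np.prod(shape)))
    )
    # clamped out-of-grid neighbors carry weight zero; removing them also
    # removes any duplicate column indices
    A.eliminate_zeros()
    return A


# ---------------------------------------------------------------------------
# Forward / adjoint excitation operators

def _plane_coords(shape, affine, mu, center, planes):
    """Subject-space voxel coordinates of scanner grid points on z-planes."""
    nx, ny, _ = shape
    ii, jj, kk = np.meshgrid(
        np.arange(nx), np.arange(ny), np.asarray(planes), indexing="ij"
    )
    vox = np.column_stack(
        [ii.ravel(order="C"), jj.ravel(order="C"), kk.ravel(order="C")]
    ).astype(float)
    # scanner voxel -> world -> subject -> reconstruction voxel
    world = vox @ affine[:3, :3].T + affine[:3, 3]
    Tm = pose_matrix(mu, center)
    subj = world @ Tm[:3, :3].T + Tm[:3, 3]
    inv = np.linalg.inv(affine)
    return subj @ inv[:3, :3].T + inv[:3, 3]


def _slice_plane_weights(slices, planes, kernel):
    """(n_slices, n_planes) matrix of combined-kernel taps."""
    K = len(kernel) // 2
    W = np.zeros((len(slices), len(planes)))
    pindex = {p: a for a, p in enumerate(planes)}
    for si, z in enumerate(slices):
        for k in range(-K, K + 1):
            p = z + k
            if p in pindex:
                W[si, pindex[p]] = kernel[k + K]
    return W


def _needed_planes(slices, nz, kernel):
    K = len(kernel) // 2
    planes = sorted(
        {z + k for z in slices for k in range(-K, K + 1) if 0 <= z + k < nz}
    )
    return planes


def excitation_operator(
    shape, affine, mu, slices, kernel, center=None
) -> sp.csr_matrix:
    """Sparse ``B_s M(mu_s)`` for one slice group.

    Maps a flattened 3-D contrast volume to the predicted slice stack
    (rows ordered slice-major, then x, then y).  The combined kernel acts
    along scanner z after the motion resampling, exactly in operator
    order; planes falling outside the grid contribute zero.
    """
    nx, ny, nz = shape
    planes = _needed_planes(slices, nz, kernel)
    if not planes:
        return sp.csr_matrix((len(slices) * nx * ny, nx * ny * nz))
    coords = _plane_coords(shape, affine, mu, center, planes)
    M = interp_matrix(shape, coords)  # ((nx*ny*P), nxyz), plane-minor order
    # rows of M are ordered (x, y, plane); regroup plane-major for B
    P = len(planes)
    perm = (
        np.arange(nx * ny * P)
        .reshape(nx, ny, P)
        .transpose(2, 0, 1)
        .ravel()
    )
    M = M[perm]
    W = _slice_plane_weights(slices, planes, kernel)
    B = sp.kron(sp.csr_matrix(W), sp.identity(nx * ny, format="csr"))
    return (B @ M).tocsr()


def predict_excitation(
    x: ReconVolume, basis, mu, exc: Excitation, kernel, operator=None
) -> np.ndarray:
    """Forward model for one excitation: ``B_s M(mu_s) Q_s(mu_s) x``.

    Returns the predicted multiband slice stack, shape
    ``(nx, ny, len(exc.slices))``.  Linear in the coefficients.
    """
    from .basis import qspace_row

    ghat = reorient_gradient(mu, exc.direction)
    q = qspace_row(basis, exc.shell, ghat)
    c = np.tensordot(x.coeffs, q, axes=([3], [0]))
    A = operator if operator is not None else excitation_operator(
        x.shape, x.affine, mu, exc.slices, kernel, x.center_world
    )
    y = A @ c.ravel(order="C")
    nx, ny, _ = x.shape
    return y.reshape(len(exc.slices), nx, ny).transpose(1, 2, 0)


def adjoint_excitation(
    residual: np.ndarray, x: ReconVolume, basis, mu, exc: Excitation,
    kernel, operator=None,
) -> np.ndarray:
    """Exact adjoint of `predict_excitation` as a linear map in x.

    Spreads a slice-stack residual back into coefficient space:
    ``Q_s^T M^T B_s^T residual``.
    """
    from .basis import qspace_row

    ghat = reorient_gradient(mu, exc.direction)
    q = qspace_row(basis, exc.shell, ghat)
    A = operator if operator is not None else excitation_operator(
        x.shape, x.affine, mu, exc.slices, kernel, x.center_world
    )
    r = residual.transpose(2, 0, 1).ravel(order="C")
    g = (A.T @ r).reshape(x.shape)
    return g[..., None] * q
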