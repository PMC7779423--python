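"""Spherical harmonics and the SHARD multi-shell signal basis.

Multi-shell diffusion data are represented per shell in a real, even-order,
orthonormal spherical-harmonics (SH) basis and linked across shells by a
data-driven radial decomposition: for each even SH band ``l``, the per-shell
band coefficients of all voxels are stacked into an ``(n_shells, n_voxels *
(2l+1))`` matrix whose leading left singular vectors form an orthonormal
radial basis over shells.  The resulting representation — Spherical
Harmonics And Radial Decomposition (SHARD) — is an orthogonal, low-rank
basis for the complete multi-shell signal, with total rank

    r = sum_l n_l * (2l + 1),

where ``n_l`` is the number of radial components retained in band ``l``.
A voxel's ``r`` coefficients can be projected to the predicted signal at
any (shell, direction) pair, which is what makes the basis usable inside a
scattered-slice forward model.

SH convention
-------------
Real, even-order, orthonormal over the sphere, with columns ordered by
``l`` ascending and, within a band, ``m = -l .. l``.  For ``m < 0`` the
function is ``sqrt(2) * Im(Y_l^|m|)``, for ``m = 0`` it is ``Y_l^0``, and
for ``m > 0`` it is ``sqrt(2) * Re(Y_l^m)`` (MRtrix-compatible ordering).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import sph_harm_y

__all__ = [
    "n_sh_coeffs",
    "sh_matrix",
    "sh_band",
    "ShardBasis",
    "fit_shard_basis",
    "fit_shell_sh",
    "qspace_row",
    "qspace_matrix",
    "rank_reduce",
    "project_to_shells",
    "project_to_basis",
]


def n_sh_coeffs(lmax: int) -> int:
    """Number of real even-order SH coefficients up to order `lmax`.

    Equals ``(lmax + 1) (lmax + 2) / 2``.
    """
    lmax = int(lmax)
    if lmax < 0 or lmax % 2:
        raise ValueError(f"lmax must be even and non-negative, got {lmax}")
    return (lmax + 1) * (lmax + 2) // 2


def _check_directions(directions: np.ndarray) -> np.ndarray:
    d = np.atleast_2d(np.asarray(directions, dtype=float))
    if d.shape[-1] != 3:
        raise ValueError("directions must be 3-vectors")
    nrm = np.linalg.norm(d, axis=-1)
    if np.any(np.abs(nrm - 1.0) > 1e-4):
        raise ValueError("directions must be unit-norm")
    return d


def sh_band(directions, ell: int) -> np.ndarray:
    """Evaluate the 2l+1 real even SH of band `ell` at unit directions.

    Returns an ``(n_dirs, 2*ell+1)`` matrix with m ordered ``-l .. l``.
    """
    if ell < 0 or ell % 2:
        raise ValueError("band order must be even and non-negative")
    d = _check_directions(directions)
    theta = np.arccos(np.clip(d[:, 2], -1.0, 1.0))  # polar angle
    phi = np.arctan2(d[:, 1], d[:, 0])
    out = np.empty((d.shape[0], 2 * ell + 1))
    for m in range(-ell, ell + 1):
        y = sph_harm_y(ell, abs(m), theta, phi)
        if m < 0:
            out[:, m + ell] = np.sqrt(2.0) * y.imag
        elif m == 0:
            out[:, ell] = y.real
        else:
            out[:, m + ell] = np.sqrt(2.0) * y.real
    return out


def sh_matrix(directions, lmax: int) -> np.ndarray:
    """Real even-order orthonormal SH design matrix.

    Shape ``(n_dirs, n_sh_coeffs(lmax))``, columns ordered (l asc,
    m = -l..l).  Antipodally symmetric since only even l are included.
    """
    n_sh_coeffs(lmax)  # validates lmax
    d = _check_directions(directions)
    return np.concatenate([sh_band(d, ell) for ell in range(0, lmax + 1, 2)], axis=1)


@dataclass
class ShardBasis:
    """The SHARD multi-shell basis: per-band orthonormal radial matrices.

    Attributes
    ----------
    lmax_per_shell : tuple of even int
        SH order used in each shell (shells ordered by increasing b).
    radial : dict[int, ndarray]
        For each even band l, an ``(n_shells, n_l)`` matrix with
        orthonormal columns; rows of shells whose lmax < l are zero.

    Coefficient ordering is (l ascending, radial component j, m = -l..l);
    total rank ``r = sum_l n_l * (2l+1)``.
    """

    lmax_per_shell: tuple
    radial: dict

    def __post_init__(self) -> None:
        self.lmax_per_shell = tuple(int(l) for l in self.lmax_per_shell)
        self.radial = {
            int(l): np.asarray(v, dtype=float) for l, v in self.radial.items()
        }
        ns = len(self.lmax_per_shell)
        for ell, mat in self.radial.items():
            if mat.shape[0] != ns:
                raise ValueError("radial matrix rows must equal n_shells")
            avail = sum(1 for lm in self.lmax_per_shell if lm >= ell)
            if mat.shape[1] > avail:
                raise ValueError(
                    f"band {ell}: {mat.shape[1]} components requested but only "
                    f"{avail} shells reach this order"
                )

    @property
    def n_shells(self) -> int:
        return len(self.lmax_per_shell)

    @property
    def bands(self) -> list:
        return sorted(ell for ell, m in self.radial.items() if m.shape[1] > 0)

    def n_components(self, ell: int) -> int:
        mat = self.radial.get(ell)
        return 0 if mat is None else mat.shape[1]

    @property
    def rank(self) -> int:
        return sum(self.n_components(l) * (2 * l + 1) for l in self.bands)

    def band_slice(self, ell: int) -> slice:
        """Slice of the coefficient vector covered by band `ell`."""
        start = 0
        for l in self.bands:
            width = self.n_components(l) * (2 * l + 1)
            if l == ell:
                return slice(start, start + width)
            start += width
        raise KeyError(f"band {ell} not in basis")


def fit_shell_sh(data: np.ndarray, grad, lmax_per_shell) -> list:
    """Per-shell unweighted linear least-squares SH fit of a 4-D series.

    Parameters
    ----------
    data : (nx, ny, nz, n_volumes) array
    grad : GradientTable
    lmax_per_shell : sequence of even int, one per shell

    Returns
    -------
    list of ``(nx, ny, nz, n_sh_coeffs(lmax_s))`` coefficient arrays.
    """
    lmax_per_shell = tuple(int(l) for l in lmax_per_shell)
    if len(lmax_per_shell) != grad.n_shells:
        raise ValueError("one lmax per shell required")
    out = []
    for s, lmax in enumerate(lmax_per_shell):
        vols = grad.shell_volumes(s)
        ncoef = n_sh_coeffs(lmax)
        if vols.size < ncoef:
            raise ValueError(
                f"shell {s} (b={grad.shell_b[s]:.0f}): {vols.size} directions "
                f"cannot support lmax={lmax} ({ncoef} coefficients)"
            )
        B = sh_matrix(grad.bvecs[vols], lmax)
        y = data[..., vols]
        coef, *_ = np.linalg.lstsq(B, y.reshape(-1, vols.size).T, rcond=None)
        out.append(coef.T.reshape(data.shape[:3] + (ncoef,)))
    return out


def fit_shard_basis(
    sh_coeffs_per_shell, mask, n_components_per_band=None
) -> ShardBasis:
    """Learn the radial SHARD basis from per-shell SH coefficient images.

    For each even band l, the band coefficients of all in-mask voxels are
    stacked across shells into an ``(n_shells, n_voxels*(2l+1))`` matrix
    (zero rows for shells whose lmax < l); the leading ``n_l`` left
    singular vectors of its SVD form the band's radial basis.  Signs are
    fixed so each column's largest-magnitude entry is positive.

    Parameters
    ----------
    sh_coeffs_per_shell : list of (..., n_coeffs_s) arrays
    mask : boolean array broadcastable to the spatial shape
    n_components_per_band : dict[l, n_l] or sequence over bands; None keeps
        every component available (full rank).
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    n_shells = len(sh_coeffs_per_shell)
    lmax_per_shell = tuple(
        _lmax_from_ncoeffs(c.shape[-1]) for c in sh_coeffs_per_shell
    )
    bands = list(range(0, max(lmax_per_shell) + 1, 2))
    if n_components_per_band is None:
        n_req = {l: sum(1 for lm in lmax_per_shell if lm >= l) for l in bands}
    elif isinstance(n_components_per_band, dict):
        n_req = {l: int(n_components_per_band.get(l, 0)) for l in bands}
    else:
        seq = list(n_components_per_band)
        n_req = {l: (int(seq[i]) if i < len(seq) else 0) for i, l in enumerate(bands)}
    radial = {}
    for ell in bands:
        avail = sum(1 for lm in lmax_per_shell if lm >= ell)
        if n_req[ell] > avail:
            raise ValueError(
                f"band {ell}: requested {n_req[ell]} components, only "
                f"{avail} shells reach this order"
            )
        rows = []
        for s in range(n_shells):
            if lmax_per_shell[s] >= ell:
                lo = n_sh_coeffs(ell) - (2 * ell + 1)
                band = sh_coeffs_per_shell[s][..., lo : lo + 2 * ell + 1]
                rows.append(band[mask].ravel())
            else:
                rows.append(None)
        width = next(r.size for r in rows if r is not None)
        stack = np.zeros((n_shells, width))
        for s, r in enumerate(rows):
            if r is not None:
                stack[s] = r
        u, _, _ = np.linalg.svd(stack, full_matrices=False)
        u = u[:, : n_req[ell]]
        radial[ell] = _fix_signs(u)
    return ShardBasis(lmax_per_shell, radial)


def _lmax_from_ncoeffs(n: int) -> int:
    lmax = 0
    while n_sh_coeffs(lmax) < n:
        lmax += 2
    if n_sh_coeffs(lmax) != n:
        raise ValueError(f"{n} is not a valid even-SH coefficient count")
    return lmax


def _fix_signs(u: np.ndarray) -> np.ndarray:
    out = u.copy()
    for j in range(out.shape[1]):
        i = np.argmax(np.abs(out[:, j]))
        if out[i, j] < 0:
            out[:, j] = -out[:, j]
    return out


def qspace_matrix(basis: ShardBasis, shell: int, directions) -> np.ndarray:
    """q-space projection rows for several directions at one shell.

    Row ``i`` maps a voxel's ``r`` coefficients to its predicted signal at
    ``(shell, directions[i])``; entry for (l, j, m) is
    ``radial[l][shell, j] * Y_lm(direction)``.
    """
    if not 0 <= shell < basis.n_shells:
        raise IndexError(f"shell index {shell} out of range")
    d = _check_directions(directions)
    blocks = []
    for ell in basis.bands:
        Y = sh_band(d, ell)  # (n, 2l+1)
        w = basis.radial[ell][shell]  # (n_l,)
        blocks.append((w[None, :, None] * Y[:, None, :]).reshape(d.shape[0], -1))
    return np.concatenate(blocks, axis=1)


def qspace_row(basis: ShardBasis, shell: int, direction) -> np.ndarray:
    """The 1 x r q-space projection row for one (shell, direction)."""
    return qspace_matrix(basis, shell, np.atleast_2d(direction))[0]


def rank_reduce(basis: ShardBasis, components_per_band) -> ShardBasis:
    """Keep the leading radial components per band; rank is recomputed.

    `components_per_band` is a sequence over the basis bands (l ascending)
    or a dict keyed by l.  Requests beyond availability raise.
    """
    bands = basis.bands
    if isinstance(components_per_band, dict):
        req = {l: int(components_per_band.get(l, 0)) for l in bands}
    else:
        seq = list(components_per_band)
        req = {l: (int(seq[i]) if i < len(seq) else 0) for i, l in enumerate(bands)}
    radial = {}
    for ell in bands:
        n = req[ell]
        if n > basis.n_components(ell):
            raise ValueError(
                f"band {ell}: requested {n} of {basis.n_components(ell)} components"
            )
        if n > 0:
            radial[ell] = basis.radial[ell][:, :n]
    return ShardBasis(basis.lmax_per_shell, radial)


def project_to_shells(coeffs: np.ndarray, basis: ShardBasis) -> list:
    """Map SHARD coefficients back to per-shell SH coefficient images.

    Inverse of `project_to_basis` for full-rank bases.  Input shape
    ``(..., r)``; output is one ``(..., n_sh_coeffs(lmax_s))`` array per
    shell (bands above the basis content are zero-filled).
    """
    coeffs = np.asarray(coeffs)
    out = []
    for s, lmax in enumerate(basis.lmax_per_shell):
        sh = np.zeros(coeffs.shape[:-1] + (n_sh_coeffs(lmax),))
        for ell in basis.bands:
            if ell > lmax:
                continue
            nl = basis.n_components(ell)
            band = coeffs[..., basis.band_slice(ell)].reshape(
                coeffs.shape[:-1] + (nl, 2 * ell + 1)
            )
            lo = n_sh_coeffs(ell) - (2 * ell + 1)
            sh[..., lo : lo + 2 * ell + 1] = np.tensordot(
                band, basis.radial[ell][s], axes=([-2], [0])
            )
        out.append(sh)
    return out


def project_to_basis(sh_coeffs_per_shell, basis: ShardBasis) -> np.ndarray:
    """Project per-shell SH coefficient images onto a SHARD basis.

    Uses the orthonormality of the radial columns: the coefficient of
    radial component j in band l is the inner product of the per-shell
    band coefficients with ``radial[l][:, j]`` over shells.
    """
    spatial = sh_coeffs_per_shell[0].shape[:-1]
    out = np.zeros(spatial + (basis.rank,))
    for ell in basis.bands:
        nl = basis.n_components(ell)
        lo = n_sh_coeffs(ell) - (2 * ell + 1)
        stack = np.zeros(spatial + (basis.n_shells, 2 * ell + 1))
        for s, lmax in enumerate(basis.lmax_per_shell):
            if lmax >= ell:
                stack[..., s, :] = sh_coeffs_per_shell[s][..., lo : lo + 2 * ell + 1]
        proj = np.tensordot(stack, basis.radial[ell], axes=([-2], [0]))
        # proj: (..., 2l+1, n_l) -> order (j, m)
        out[..., basis.band_slice(ell)] = np.swapaxes(proj, -1, -2).reshape(
            spatial + (nl * (2 * ell + 1),)
        )
    return out
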