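"""Synthetic validation data: phantom, motion traces, and slice corruption.

The generator mirrors a motion-corruption validation study: a clean
multi-shell phantom with anisotropic structure stands in for a
motion-free scan; a random-walk motion trace with intermittent bursts
emulates slowly drifting subjects with sudden movements; every multiband
excitation is rendered through the *same* forward model used by the
reconstruction (gradient reorientation and slice-profile convolution
included), a random subset of excitations is attenuated by smooth
multiplicative in-plane bias fields (slice dropout / spin history), and
i.i.d. Gaussian noise is added.  Ground truth (trace, dropout labels,
clean series) is retained so reconstruction accuracy can be quantified.

The clean reference series is the phantom's own representation in the
full-rank SHARD basis fitted to it — the corruption renders excitations
from exactly this representation, so it is the generating ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .basis import (
    ShardBasis,
    fit_shard_basis,
    fit_shell_sh,
    n_sh_coeffs,
    project_to_basis,
    qspace_matrix,
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
    predict_excitation,
    se3_exp,
)
from .gradients import B0_THRESHOLD, GradientTable
from .motion import MotionTrace

__all__ = [
    "PhantomSpec",
    "CorruptionSpec",
    "CorruptionResult",
    "RecoveryReport",
    "make_phantom",
    "simulate_trace",
    "corrupt",
    "evaluate_recovery",
    "default_lmax",
    "uniform_directions",
]


@dataclass
class PhantomSpec:
    """Multi-shell phantom geometry and composition.

    Two anisotropic fiber compartments (a circumferential bundle and a
    through-plane bundle with smoothly varying mixing) plus an isotropic
    compartment, on an ellipsoidal support.  Diffusivities in mm^2/s.
    """

    shape: tuple = (24, 24, 24)
    voxel_size: float = 1.5
    shells: tuple = ((0.0, 4), (1000.0, 16), (2600.0, 24))
    s0: float = 100.0
    lambda_par: float = 1.7e-3
    lambda_perp: float = 0.25e-3
    d_iso: float = 0.8e-3


@dataclass
class CorruptionSpec:
    """Motion, dropout, and noise levels for the synthetic corruption.

    Defaults are the validation study conditions: per-excitation
    random-walk steps of 0.3 mm / 0.3 deg, 4x bursts seeded at rate 0.05,
    10% dropout excitations with smooth bias in [0.1, 0.8], and Gaussian
    noise at 0.5% of the mean b=0 signal.
    """

    trace_sigma_trans: float = 0.3   # mm per excitation
    trace_sigma_rot: float = 0.3     # deg per excitation
    burst_rate: float = 0.05         # probability per excitation
    burst_scale: float = 4.0
    burst_length: int = 3            # mean excitations per burst
    reversion: float = 0.02          # per-step pull toward the rest pose
    dropout_rate: float = 0.1
    dropout_bias_smoothness: float = 6.0  # mm, in-plane
    dropout_bias_range: tuple = (0.1, 0.8)
    noise_sigma: float = 0.005       # fraction of mean in-mask b=0 signal
    seed: int = 1

    def __post_init__(self) -> None:
        for r in (self.burst_rate, self.dropout_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        if self.trace_sigma_trans < 0 or self.trace_sigma_rot < 0:
            raise ValueError("sigmas must be non-negative")


def uniform_directions(n: int, rng=None) -> np.ndarray:
    """Near-uniform unit directions on the hemisphere (golden-angle spiral),
    optionally randomly rotated as a set."""
    i = np.arange(n) + 0.5
    z = i / n                       # upper hemisphere
    phi = i * np.pi * (3.0 - np.sqrt(5.0))
    s = np.sqrt(1.0 - z**2)
    d = np.column_stack([s * np.cos(phi), s * np.sin(phi), z])
    if rng is not None:
        mu = np.concatenate([np.zeros(3), rng.normal(0, 1.0, 3)])
        R = se3_exp(mu)[:3, :3]
        d = d @ R.T
    return d


def _interleave_volumes(shells) -> list:
    """Spread volumes of each shell evenly through the series."""
    entries = []
    for s, (b, n) in enumerate(shells):
        for i in range(n):
            entries.append(((i + 0.5) / n, s, i))
    entries.sort(key=lambda e: (e[0], e[1]))
    return [(s, i) for _, s, i in entries]


def make_phantom(spec: PhantomSpec, seed: int = 0):
    """Generate a clean multi-shell dMRI series, gradient table and mask.

    Per-voxel multi-tensor signal ``S(b, g) = s0 * sum_i f_i *
    exp(-b g^T D_i g)`` with compartment fractions summing to one;
    deterministic for a given seed (the seed rotates the per-shell
    direction sets).  b=0 volumes equal s0 inside the mask.
    """
    rng = np.random.default_rng(seed)
    nx, ny, nz = spec.shape
    # gradient table: per-shell uniform directions, shells interleaved
    dirsets = []
    for b, n in spec.shells:
        if b <= B0_THRESHOLD:
            dirsets.append(np.tile([0.0, 0.0, 1.0], (n, 1)))
        else:
            dirsets.append(uniform_directions(n, rng))
    order = _interleave_volumes(spec.shells)
    bvals = np.array([spec.shells[s][0] for s, _ in order])
    bvecs = np.array([dirsets[s][i] for s, i in order])
    grad = GradientTable(bvals, bvecs)

    ii, jj, kk = np.meshgrid(
        np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
    )
    cx, cy, cz = (nx - 1) / 2.0, (ny - 1) / 2.0, (nz - 1) / 2.0
    dx, dy, dz = ii - cx, jj - cy, kk - cz
    # distinct radii and an off-center support: brains are not
    # rotationally symmetric, and a symmetric phantom would make
    # in-plane rotation nearly unidentifiable during registration
    rx, ry, rz = 0.40 * nx, 0.33 * ny, 0.37 * nz
    rho = np.sqrt(
        ((dx - 0.04 * nx) / rx) ** 2
        + ((dy + 0.03 * ny) / ry) ** 2
        + ((dz - 0.02 * nz) / rz) ** 2
    )
    # the signal rolls off smoothly over ~2 voxels outside the brain
    # mask (continuous images have no binary edge); the mask marks the
    # full-signal interior used for fitting and evaluation
    mask = rho <= 1.0
    taper = np.ones_like(rho)
    edge = (rho > 1.0) & (rho < 1.25)
    taper[edge] = np.cos(0.5 * np.pi * (rho[edge] - 1.0) / 0.25) ** 2
    taper[rho >= 1.25] = 0.0

    # orientation fields of the two fiber compartments: a gently curving
    # bundle along x and a tilted through-plane bundle
    u1 = np.stack(
        [np.ones_like(dx, dtype=float),
         0.45 * np.sin(np.pi * dy / ny),
         0.25 * np.cos(np.pi * dx / nx)], axis=-1,
    )
    u1 /= np.linalg.norm(u1, axis=-1, keepdims=True)
    u2 = np.stack(
        [0.35 * np.sin(2 * np.pi * ii / nx),
         0.3 * np.cos(np.pi * jj / ny),
         np.ones_like(dx, dtype=float)], axis=-1,
    )
    u2 /= np.linalg.norm(u2, axis=-1, keepdims=True)

    # ventricle-like isotropic pockets at asymmetric positions: dark in
    # the diffusion-weighted shells, bright at b=0 — the kind of coarse
    # structural landmarks that anchor rigid registration in real brains
    def blob(px, py, pz, wx, wy, wz):
        return np.exp(
            -(
                ((dx - px * nx) / (wx * nx)) ** 2
                + ((dy - py * ny) / (wy * ny)) ** 2
                + ((dz - pz * nz) / (wz * nz)) ** 2
            )
        )

    pockets = (
        blob(-0.12, 0.10, -0.05, 0.10, 0.12, 0.18)
        + blob(0.16, -0.02, 0.08, 0.09, 0.08, 0.14)
        + 0.7 * blob(0.02, -0.16, -0.10, 0.12, 0.08, 0.12)
    )
    f_iso = 0.10 + 0.08 * np.cos(np.pi * (dz - 0.1 * nz) / nz) ** 2
    f_iso = np.clip(f_iso + 0.8 * pockets, 0.0, 0.92)
    g_mix = 0.5 + 0.4 * np.cos(np.pi * (dx - 0.18 * nx) / nx) * np.cos(
        np.pi * (dy + 0.12 * ny) / ny
    )
    g_mix = np.clip(g_mix, 0.0, 1.0)
    f1 = (1.0 - f_iso) * g_mix
    f2 = (1.0 - f_iso) * (1.0 - g_mix)
    total = f_iso + f1 + f2
    if np.max(np.abs(total - 1.0)) > 1e-10:
        raise ValueError("compartment fractions do not sum to 1")

    # proton-density variation: a smooth asymmetric gradient plus
    # folding-scale texture (a few voxels wide, like cortical structure)
    # shared across all shells and directions — real brains carry this
    # fine structural contrast, which is what anchors rigid registration
    from scipy.ndimage import gaussian_filter as _gf

    tex = _gf(rng.standard_normal(spec.shape), 1.1, mode="nearest")
    tex *= 0.18 / max(tex.std(), 1e-12)
    density = (
        1.0
        + 0.15 * np.sin(np.pi * (dx + 0.3 * dy) / nx)
        + 0.12 * np.cos(np.pi * (dy - 0.4 * dz) / ny + 0.7)
        + tex
    )

    lp, lt, di = spec.lambda_par, spec.lambda_perp, spec.d_iso
    data = np.zeros(spec.shape + (grad.n_volumes,))
    for v in range(grad.n_volumes):
        b = grad.bvals[v]
        g = grad.bvecs[v]
        if b <= B0_THRESHOLD:
            sig = np.ones(spec.shape)
        else:
            c1 = np.tensordot(u1, g, axes=([3], [0]))
            c2 = np.tensordot(u2, g, axes=([3], [0]))
            a1 = np.exp(-b * (lt + (lp - lt) * c1**2))
            a2 = np.exp(-b * (lt + (lp - lt) * c2**2))
            sig = f_iso * np.exp(-b * di) + f1 * a1 + f2 * a2
        data[..., v] = spec.s0 * density * sig * taper
    return data, grad, mask


def simulate_trace(n_excitations: int, spec: CorruptionSpec, seed: int):
    """Burst-augmented mean-reverting se(3) walk, one pose per excitation.

    Gaussian per-step increments (sigma from the spec; rotations drawn in
    degrees and stored as radians) accumulate over time; steps inside
    burst intervals — seeded at `burst_rate` per excitation, geometric
    mean length `burst_length` — are scaled by `burst_scale`.  A weak
    per-step pull toward the rest pose (`reversion`) bounds the total
    excursion the way sleeping subjects return to rest, so the trace
    reproduces both reference statistics of observed motion: the
    slice-to-slice stdev (set by sigma) and an excursion stdev a few
    times larger, rather than the unbounded drift of a pure random walk.
    Returns the trace and physical-unit summaries: the standard deviation
    of the mean-removed trace and of its forward difference (translation
    in mm, rotation in degrees, per-component RMS).
    """
    if n_excitations < 1:
        raise ValueError("need at least one excitation")
    rng = np.random.default_rng(seed)
    sig = np.array(
        [spec.trace_sigma_trans] * 3 + [np.radians(spec.trace_sigma_rot)] * 3
    )
    steps = rng.normal(0.0, 1.0, (n_excitations, 6)) * sig
    burst_left = 0
    for t in range(n_excitations):
        if burst_left > 0:
            steps[t] *= spec.burst_scale
            burst_left -= 1
        elif spec.burst_rate > 0 and rng.random() < spec.burst_rate:
            burst_left = rng.geometric(1.0 / max(spec.burst_length, 1))
            steps[t] *= spec.burst_scale
            burst_left -= 1
    poses = np.empty((n_excitations, 6))
    cur = np.zeros(6)
    for t in range(n_excitations):
        cur = (1.0 - spec.reversion) * cur + steps[t]
        poses[t] = cur
    trace = MotionTrace(poses)
    centered = poses - poses.mean(axis=0)
    d = np.diff(poses, axis=0) if n_excitations > 1 else np.zeros((1, 6))
    summary = {
        "stdev_trans_mm": float(np.sqrt(np.mean(centered[:, :3] ** 2))),
        "stdev_rot_deg": float(
            np.degrees(np.sqrt(np.mean(centered[:, 3:] ** 2)))
        ),
        "stdev_dtrans_mm": float(np.sqrt(np.mean(d[:, :3] ** 2))),
        "stdev_drot_deg": float(np.degrees(np.sqrt(np.mean(d[:, 3:] ** 2)))),
    }
    return trace, summary


def default_lmax(grad: GradientTable, cap: int = 8) -> tuple:
    """Largest even per-shell SH order supported by the direction count."""
    out = []
    for s in range(grad.n_shells):
        if grad.shell_b[s] <= B0_THRESHOLD:
            out.append(0)
            continue
        n = grad.shell_volumes(s).size
        lmax = 0
        while lmax + 2 <= cap and n_sh_coeffs(lmax + 2) <= n:
            lmax += 2
        out.append(lmax)
    return tuple(out)


@dataclass
class CorruptionResult:
    slices: ScatteredSliceSet
    dropout_labels: np.ndarray        # boolean per excitation
    bias_fields: dict                 # excitation index -> (nx, ny) field
    truth: ReconVolume                # generating SHARD coefficients
    basis: ShardBasis
    clean_series: np.ndarray          # rendered truth at identity motion
    layout: AcquisitionLayout = field(default=None)  # type: ignore


def corrupt(
    dmri: np.ndarray,
    grad: GradientTable,
    trace: MotionTrace,
    layout: AcquisitionLayout,
    profile: SliceProfile,
    spec: CorruptionSpec,
    seed: int,
    affine: np.ndarray | None = None,
    mask: np.ndarray | None = None,
    voxel_size: float = 1.5,
) -> CorruptionResult:
    """Render motion-scattered, dropout-biased, noisy slices.

    The clean series is first projected into a full-rank SHARD basis
    (per-shell SH fit + radial decomposition); every excitation is then
    rendered through the forward model at its pose, with gradient
    reorientation and slice-profile convolution, before dropout bias and
    Gaussian noise are applied.
    """
    rng = np.random.default_rng(seed)
    if affine is None:
        affine = np.diag([voxel_size, voxel_size, voxel_size, 1.0])
    if mask is None:
        mask = np.any(dmri > 0, axis=-1)
    poses = np.asarray(trace, dtype=float)
    if poses.shape[0] != layout.n_excitations:
        raise ValueError("trace length must match the excitation count")

    lmax = default_lmax(grad)
    sh = fit_shell_sh(dmri, grad, lmax)
    basis = fit_shard_basis(sh, mask)
    x = ReconVolume(project_to_basis(sh, basis), affine)
    kernel = combined_kernel(profile, float(np.linalg.norm(affine[:3, 2])))
    # the ground truth is itself a motion-free regularized reconstruction,
    # mirroring validation against reconstructed scans: simulate the
    # motion-free acquisition (slice-profile blur included), reconstruct
    # it, and render all corrupted excitations from that representation
    from .recon import ReconConfig, solve_reconstruction

    zero_trace = np.zeros((layout.n_excitations, 6))
    y_clean = np.zeros_like(dmri)
    for exc in layout.excitations:
        y_clean[:, :, list(exc.slices), exc.volume] = predict_excitation(
            x, basis, zero_trace[0], exc, kernel
        )
    clean_set = ScatteredSliceSet(y_clean, layout, grad, mask)
    rcfg = ReconConfig(max_cg_iter=30)
    x, _, _ = solve_reconstruction(
        clean_set, zero_trace, basis, rcfg, x, kernel
    )

    data = np.zeros_like(dmri)
    for e, exc in enumerate(layout.excitations):
        pred = predict_excitation(x, basis, poses[e], exc, kernel)
        data[:, :, list(exc.slices), exc.volume] = pred

    labels = rng.random(layout.n_excitations) < spec.dropout_rate
    lo, hi = spec.dropout_bias_range
    sigma_vox = spec.dropout_bias_smoothness / voxel_size
    bias_fields = {}
    for e in np.flatnonzero(labels):
        exc = layout.excitations[e]
        f = gaussian_filter(
            rng.normal(0.0, 1.0, dmri.shape[:2]), sigma_vox, mode="reflect"
        )
        fmin, fmax = f.min(), f.max()
        if fmax - fmin < 1e-12:
            field_ = np.full(dmri.shape[:2], 0.5 * (lo + hi))
        else:
            field_ = lo + (hi - lo) * (f - fmin) / (fmax - fmin)
        bias_fields[int(e)] = field_
        data[:, :, list(exc.slices), exc.volume] *= field_[:, :, None]

    b0 = grad.bvals <= B0_THRESHOLD
    s0ref = float(dmri[mask][:, b0].mean()) if b0.any() else float(
        dmri[mask].mean()
    )
    if spec.noise_sigma > 0:
        data += rng.normal(0.0, spec.noise_sigma * s0ref, data.shape)

    clean = render_series(x, basis, grad)
    slices = ScatteredSliceSet(data, layout, grad, mask)
    return CorruptionResult(slices, labels, bias_fields, x, basis, clean,
                            layout)


def render_series(x: ReconVolume, basis: ShardBasis, grad: GradientTable
                  ) -> np.ndarray:
    """Render a 4-D series from coefficients at identity motion (no blur)."""
    out = np.zeros(x.shape + (grad.n_volumes,))
    for v in range(grad.n_volumes):
        q = qspace_matrix(basis, int(grad.shell_index[v]),
                          grad.bvecs[v][None, :])[0]
        out[..., v] = np.tensordot(x.coeffs, q, axes=([3], [0]))
    return out


@dataclass
class RecoveryReport:
    trans_rmse_mm: float
    rot_rmse_deg: float
    recon_rmse: float
    recon_rmse_rel: float       # fraction of mean in-mask b=0 signal
    stdev_trans_mm: float
    stdev_rot_deg: float
    stdev_dtrans_mm: float
    stdev_drot_deg: float


def evaluate_recovery(
    truth_trace,
    est_trace,
    truth_dmri: np.ndarray,
    pred_dmri: np.ndarray,
    mask: np.ndarray,
    grad: GradientTable | None = None,
    affine: np.ndarray | None = None,
) -> RecoveryReport:
    """Motion-trace and reconstruction accuracy against ground truth.

    Trace RMSE is computed per component in the Lie algebra after
    removing each trace's global mean pose (gauge freedom between
    independent reconstructions).  Reconstruction RMSE is evaluated over
    in-mask voxels and volumes; when `affine` is given, the prediction is
    first rigidly re-aligned by the recovered-vs-true mean pose before
    comparison.  The relative RMSE is normalized to the mean in-mask b=0
    signal (1/SNR units).
    """
    pt = np.atleast_2d(np.asarray(truth_trace, dtype=float))
    pe = np.atleast_2d(np.asarray(est_trace, dtype=float))
    if pt.shape != pe.shape:
        raise ValueError("trace length mismatch")
    mt, me = pt.mean(axis=0), pe.mean(axis=0)
    d = (pe - me) - (pt - mt)
    trans_rmse = float(np.sqrt(np.mean(d[:, :3] ** 2)))
    rot_rmse = float(np.degrees(np.sqrt(np.mean(d[:, 3:] ** 2))))

    if truth_dmri.shape != pred_dmri.shape:
        raise ValueError("series shape mismatch")
    pred = pred_dmri
    if affine is not None and np.max(np.abs(me - mt)) > 1e-12:
        # truth(p) ~ pred evaluated at T(me) T(mt)^-1 p  (about FOV center)
        shape = truth_dmri.shape[:3]
        c = np.asarray(shape, dtype=float)
        center = affine[:3, :3] @ ((c - 1) / 2.0) + affine[:3, 3]
        G = pose_matrix(me, center) @ np.linalg.inv(pose_matrix(mt, center))
        ii, jj, kk = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
        vox = np.column_stack(
            [ii.ravel(), jj.ravel(), kk.ravel()]
        ).astype(float)
        world = vox @ affine[:3, :3].T + affine[:3, 3]
        moved = world @ G[:3, :3].T + G[:3, 3]
        inv = np.linalg.inv(affine)
        coords = moved @ inv[:3, :3].T + inv[:3, 3]
        pred = np.stack(
            [interp_values(pred_dmri[..., v], coords).reshape(shape)
             for v in range(pred_dmri.shape[-1])], axis=-1,
        )
    m = np.asarray(mask, dtype=bool)
    resid = (pred - truth_dmri)[m]
    rmse = float(np.sqrt(np.mean(resid**2)))
    if grad is not None:
        b0 = grad.bvals <= B0_THRESHOLD
        ref = float(truth_dmri[m][:, b0].mean())
    else:
        ref = float(truth_dmri[m].mean())
    centered_t = pt - mt
    dtr = np.diff(pt, axis=0) if pt.shape[0] > 1 else np.zeros((1, 6))
    return RecoveryReport(
        trans_rmse_mm=trans_rmse,
        rot_rmse_deg=rot_rmse,
        recon_rmse=rmse,
        recon_rmse_rel=rmse / ref,
        stdev_trans_mm=float(np.sqrt(np.mean(centered_t[:, :3] ** 2))),
        stdev_rot_deg=float(np.degrees(np.sqrt(np.mean(centered_t[:, 3:] ** 2)))),
        stdev_dtrans_mm=float(np.sqrt(np.mean(dtr[:, :3] ** 2))),
        stdev_drot_deg=float(np.degrees(np.sqrt(np.mean(dtr[:, 3:] ** 2)))),
    )
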