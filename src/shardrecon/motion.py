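"""Slice-to-volume registration, temporal filtering, and outlier weighting.

Registration solves, per excitation (or per volume in early epochs),

    min_{mu, alpha} || y_s - alpha * B_s M(mu) c ||^2

where ``c`` is a rank-reduced prediction of the excitation's dMRI
contrast held fixed during the optimization, and ``alpha`` is a
closed-form intensity scale absorbing partial-saturation effects (used
for alignment only, never in the reconstruction).  The minimization runs
on the SE(3) manifold with a Levenberg–Marquardt scheme: the Jacobian of
the predicted slices w.r.t. a left-composed se(3) increment is assembled
analytically from the spatial image gradient and the generator action on
the sampled points, and the damped normal system is solved per step.

Estimated traces are filtered in two stages: an exact tridiagonal solve
that replaces low-weight poses by their temporal neighbors' average, and
a running median (window 5) for edge-preserving smoothing.

Outlier weights come from a two-class Gaussian mixture on the log-RMSE
of the per-excitation reconstruction residuals, fitted per shell with
EM; the inlier-class posterior becomes the slice weight in the next
reconstruction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .geometry import (
    AcquisitionLayout,
    Excitation,
    ReconVolume,
    compose_pose,
    interp_value_and_gradient,
    interp_values,
    pose_matrix,
    reorient_gradient,
    _needed_planes,
    _slice_plane_weights,
)

__all__ = [
    "MotionTrace",
    "OutlierModel",
    "RegistrationResult",
    "optimal_scale",
    "register_to_contrast",
    "register_excitation",
    "temporal_filter_stage1",
    "temporal_filter_stage2",
    "excitation_rmse",
    "fit_outlier_gmm",
    "apply_prior_weights",
    "motion_metrics",
    "summary_metric",
]


@dataclass
class MotionTrace:
    """Time-ordered se(3) pose vectors, one per multiband excitation."""

    poses: np.ndarray  # (n_excitations, 6)

    def __post_init__(self) -> None:
        self.poses = np.atleast_2d(np.asarray(self.poses, dtype=float))
        if self.poses.shape[1] != 6:
            raise ValueError("poses must be (n, 6)")
        if not np.all(np.isfinite(self.poses)):
            raise ValueError("non-finite pose entries")

    def __len__(self) -> int:
        return self.poses.shape[0]

    def __array__(self, dtype=None, copy=None):
        return np.array(self.poses, dtype=dtype)

    @classmethod
    def zeros(cls, n: int) -> "MotionTrace":
        return cls(np.zeros((n, 6)))

    def save_tsv(self, path) -> None:
        n = len(self)
        tab = np.column_stack([np.arange(n), self.poses])
        np.savetxt(
            path, tab, delimiter="\t",
            header="t\ttx\tty\ttz\trx\try\trz", comments="",
            fmt=["%d"] + ["%.10g"] * 6,
        )

    @classmethod
    def load_tsv(cls, path) -> "MotionTrace":
        tab = np.atleast_2d(np.loadtxt(path, skiprows=1, delimiter="\t"))
        return cls(tab[:, 1:7])


@dataclass
class RegistrationResult:
    mu: np.ndarray
    alpha: float
    cost: float
    flagged: bool = False  # True when the prediction carried no signal


def optimal_scale(y: np.ndarray, yhat: np.ndarray) -> float:
    """Closed-form least-squares intensity scale <y, yhat>/<yhat, yhat>."""
    denom = float(np.vdot(yhat, yhat))
    if denom == 0.0:
        return 1.0
    return float(np.vdot(y, yhat)) / denom


def _predict_slices(target, affine, inv_affine, mu, center, slices, kernel,
                    with_jacobian: bool):
    """Predict (and optionally differentiate) slices of `target` at pose mu."""
    nx, ny, nz = target.shape
    planes = _needed_planes(slices, nz, kernel)
    npix = nx * ny
    if not planes:
        shape = (len(slices) * npix,)
        zero = np.zeros(shape)
        return (zero, np.zeros(shape + (6,))) if with_jacobian else zero
    ii, jj, kk = np.meshgrid(
        np.arange(nx), np.arange(ny), np.asarray(planes), indexing="ij"
    )
    vox = np.column_stack([ii.ravel(), jj.ravel(), kk.ravel()]).astype(float)
    world = vox @ affine[:3, :3].T + affine[:3, 3]
    Tm = pose_matrix(mu, center)
    subj = world @ Tm[:3, :3].T + Tm[:3, 3]
    coords = subj @ inv_affine[:3, :3].T + inv_affine[:3, 3]
    P = len(planes)
    perm = np.arange(npix * P).reshape(nx, ny, P).transpose(2, 0, 1).ravel()
    W = _slice_plane_weights(slices, planes, kernel)  # (S, P)
    if not with_jacobian:
        vals = interp_values(target, coords)[perm].reshape(P, npix)
        return (W @ vals).ravel()
    vals, gvox = interp_value_and_gradient(target, coords)
    # gradient w.r.t. subject-space world coordinates
    gw = gvox @ inv_affine[:3, :3]
    v = subj - (center if center is not None else 0.0)
    J = np.empty((coords.shape[0], 6))
    J[:, :3] = gw
    J[:, 3:] = np.cross(v, gw)
    vals = vals[perm].reshape(P, npix)
    J = J[perm].reshape(P, npix, 6)
    pred = (W @ vals).ravel()
    Js = np.tensordot(W, J, axes=([1], [0])).reshape(-1, 6)
    return pred, Js


def register_to_contrast(
    y: np.ndarray,
    target: np.ndarray,
    affine: np.ndarray,
    center,
    slices,
    kernel,
    mu_init,
    n_iter: int = 10,
    dof: str = "full",
    slice_weights=None,
    max_shift: float = 8.0,
    max_rot: float = 0.12,
) -> RegistrationResult:
    """Rigid volume-to-slice alignment by Levenberg–Marquardt on se(3).

    `y` is the acquired slice stack ``(nx, ny, len(slices))``; `target`
    the fixed 3-D contrast prediction in the subject frame.  Returns the
    refined pose and the closed-form intensity scale.  The cost is
    non-increasing across accepted LM steps (damping x10 on reject, /10
    on accept).  ``dof='translation'`` freezes the rotation parameters
    (used for coarse whole-volume capture).  `slice_weights` (one value
    in [0, 1] per slice of the stack) downweights outlier slices in the
    alignment cost — essential when registering whole volumes that
    contain dropout slices.

    `max_shift` (mm) and `max_rot` (rad) bound the total excursion from
    the initial pose: thin slice stacks offer few constraints per pose
    parameter, and an unconstrained descent can overfit noise at a
    distant optimum; poses beyond the trust region are handled by the
    temporal filter and later epochs instead.
    """
    cols = np.arange(3) if dof == "translation" else np.arange(6)
    inv_affine = np.linalg.inv(affine)
    yf = y.transpose(2, 0, 1).ravel()
    rw = None
    if slice_weights is not None:
        sw = np.sqrt(np.clip(np.asarray(slice_weights, dtype=float), 0, 1))
        if sw.size != len(slices):
            raise ValueError("one weight per slice required")
        rw = np.repeat(sw, y.shape[0] * y.shape[1])
        yf = rw * yf
    mu = np.asarray(mu_init, dtype=float).copy()
    pred, J = _predict_slices(
        target, affine, inv_affine, mu, center, slices, kernel, True
    )
    if rw is not None:
        pred = rw * pred
        J = rw[:, None] * J
    if not np.any(pred):
        return RegistrationResult(mu, 1.0, float(np.vdot(yf, yf)), True)
    alpha = optimal_scale(yf, pred)
    resid = yf - alpha * pred
    cost = float(np.vdot(resid, resid))
    lam = 1e-3
    for _ in range(int(n_iter)):
        Jw = alpha * J[:, cols]
        H = Jw.T @ Jw
        g = Jw.T @ resid
        # floor the damping diagonal at a fraction of the largest
        # curvature: keeps steps bounded along nearly flat pose
        # directions (e.g. rotations of close-to-symmetric contrasts)
        dmax = float(np.max(np.diag(H)))
        floor = 1e-3 * dmax if dmax > 0 else 1.0
        D = np.diag(np.maximum(np.diag(H), floor))
        try:
            step = np.linalg.solve(H + lam * D, g)
        except np.linalg.LinAlgError:
            lam *= 10.0
            continue
        delta = np.zeros(6)
        delta[cols] = step
        if (
            np.linalg.norm(delta[3:]) > 0.3
            or np.linalg.norm(delta[:3]) > 20.0
        ):
            lam *= 10.0
            continue
        mu_t = compose_pose(delta, mu)
        excursion = mu_t - np.asarray(mu_init, dtype=float)
        if (
            np.linalg.norm(excursion[:3]) > max_shift
            or np.linalg.norm(excursion[3:]) > max_rot
        ):
            lam *= 10.0
            continue
        pred_t = _predict_slices(
            target, affine, inv_affine, mu_t, center, slices, kernel, False
        )
        if rw is not None:
            pred_t = rw * pred_t
        alpha_t = optimal_scale(yf, pred_t)
        resid_t = yf - alpha_t * pred_t
        cost_t = float(np.vdot(resid_t, resid_t))
        if cost_t < cost:
            mu, alpha, cost = mu_t, alpha_t, cost_t
            resid = resid_t
            _, J = _predict_slices(
                target, affine, inv_affine, mu, center, slices, kernel, True
            )
            if rw is not None:
                J = rw[:, None] * J
            lam = max(lam / 10.0, 1e-6)
        else:
            lam *= 10.0
    return RegistrationResult(mu, alpha, cost, False)


def register_excitation(
    y_s: np.ndarray,
    x_reduced: ReconVolume,
    basis_reduced,
    mu_init,
    exc: Excitation,
    kernel,
    n_iter: int = 10,
) -> RegistrationResult:
    """Register one excitation against a rank-reduced reconstruction.

    The registration target is the 3-D contrast predicted from
    `x_reduced` at the excitation's shell and its encoding direction
    reoriented by the *initial* pose (the previous epoch's estimate);
    it is held fixed while the pose and intensity scale are optimized.
    """
    from .basis import qspace_row

    ghat = reorient_gradient(mu_init, exc.direction)
    q = qspace_row(basis_reduced, exc.shell, ghat)
    target = np.tensordot(x_reduced.coeffs, q, axes=([3], [0]))
    return register_to_contrast(
        y_s, target, x_reduced.affine, x_reduced.center_world,
        exc.slices, kernel, mu_init, n_iter,
    )


# ---------------------------------------------------------------------------
# Temporal filtering

def temporal_filter_stage1(trace, w) -> np.ndarray:
    """Weight-driven neighbor averaging, solved exactly.

    Solves, per pose component, the tridiagonal system

        mu'_t - (1 - w_t)/2 * (mu'_{t-1} + mu'_{t+1}) = w_t mu_t

    with endpoints using their single available neighbor.  Poses with
    full weight pass through unchanged; zero-weight poses are replaced by
    the average of their filtered neighbors.
    """
    poses = np.atleast_2d(np.asarray(trace, dtype=float))
    w = np.asarray(w, dtype=float).ravel()
    n = poses.shape[0]
    if w.size != n:
        raise ValueError("one weight per excitation required")
    if np.any((w < 0) | (w > 1)):
        raise ValueError("weights must lie in [0, 1]")
    if np.all(w == 0):
        raise ValueError("all weights zero: filter system is singular")
    if n == 1:
        return poses.copy()
    ab = np.zeros((3, n))
    ab[1, :] = 1.0
    # superdiagonal entries ab[0, 1:] hold A[t, t+1]
    ab[0, 1:] = -(1.0 - w[:-1]) / 2.0
    ab[2, :-1] = -(1.0 - w[1:]) / 2.0
    ab[0, 1] = -(1.0 - w[0])       # first row: single neighbor
    ab[2, n - 2] = -(1.0 - w[-1])  # last row: single neighbor
    rhs = w[:, None] * poses
    return scipy.linalg.solve_banded((1, 1), ab, rhs)


def temporal_filter_stage2(trace, window: int = 5) -> np.ndarray:
    """Componentwise running median with shrinking windows at the edges."""
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    poses = np.atleast_2d(np.asarray(trace, dtype=float))
    n = poses.shape[0]
    half = window // 2
    out = np.empty_like(poses)
    for t in range(n):
        h = min(half, t, n - 1 - t)
        out[t] = np.median(poses[t - h : t + h + 1], axis=0)
    return out


# ---------------------------------------------------------------------------
# Outlier reweighting

@dataclass
class OutlierModel:
    """Two-class log-normal mixture of per-excitation RMSE for one shell."""

    inlier_mean: float
    inlier_sd: float
    outlier_mean: float
    outlier_sd: float
    mixing: float          # inlier proportion
    shell: int = -1
    degenerate: bool = False


def excitation_rmse(residuals, mask_slices) -> float:
    """RMSE of one excitation's residual slices over in-mask voxels.

    Returns NaN (sentinel, excluded from the mixture fit) when the mask
    does not intersect the excitation's slices.
    """
    m = np.asarray(mask_slices, dtype=bool)
    if not m.any():
        return float("nan")
    r = np.asarray(residuals, dtype=float)[m]
    return float(np.sqrt(np.mean(r**2)))


def _norm_logpdf(x, mean, sd):
    return -0.5 * ((x - mean) / sd) ** 2 - np.log(sd * np.sqrt(2.0 * np.pi))


def fit_outlier_gmm(rmse, shell: int = -1, max_iter: int = 100,
                    tol: float = 1e-8):
    """EM fit of a two-class Gaussian mixture to log-RMSE values.

    Initialization: inlier class at the (median, MAD) of the log-RMSE;
    outlier class at median + log 3 (the 3x-RMSE rule on the log scale)
    with the same spread; mixing proportions 0.9/0.1.  After convergence
    the classes are re-sorted so the higher-mean class is the outlier,
    and each excitation's weight is its inlier-class posterior.

    Returns ``(OutlierModel, weights)``; degenerate spread (MAD = 0)
    yields all-one weights.
    """
    rmse = np.asarray(rmse, dtype=float).ravel()
    finite = np.isfinite(rmse) & (rmse > 0)
    if finite.sum() < 8:
        raise ValueError("need at least 8 finite positive RMSE values")
    x = np.log(rmse[finite])
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    weights = np.ones(rmse.size)
    if mad == 0.0:
        model = OutlierModel(med, 0.0, med + np.log(3.0), 0.0, 1.0, shell,
                             degenerate=True)
        return model, weights
    m = np.array([med, med + np.log(3.0)])
    s = np.array([mad, mad])
    pi = np.array([0.9, 0.1])
    ll_old = -np.inf
    for _ in range(max_iter):
        logp = np.stack(
            [np.log(pi[c]) + _norm_logpdf(x, m[c], s[c]) for c in range(2)]
        )
        mx = logp.max(axis=0)
        lse = mx + np.log(np.exp(logp - mx).sum(axis=0))
        resp = np.exp(logp - lse)
        ll = float(lse.sum())
        nk = resp.sum(axis=1)
        nk = np.maximum(nk, 1e-12)
        m = (resp @ x) / nk
        s = np.sqrt(
            np.maximum(
                np.array([
                    (resp[c] * (x - m[c]) ** 2).sum() / nk[c] for c in range(2)
                ]),
                1e-12,
            )
        )
        pi = nk / nk.sum()
        if abs(ll - ll_old) < tol:
            break
        ll_old = ll
    if m[0] > m[1]:  # re-sort: class 0 = inlier (lower mean)
        m, s, pi = m[::-1], s[::-1], pi[::-1]
    # bimodality guard: when the fitted components overlap heavily the
    # distribution is unimodal (no detectable outlier class) and EM has
    # merely split one cluster; report full weights instead
    ashman_d = np.sqrt(2.0) * (m[1] - m[0]) / np.sqrt(s[0] ** 2 + s[1] ** 2)
    if ashman_d < 2.0:
        model = OutlierModel(m[0], s[0], m[1], s[1], float(pi[0]), shell,
                             degenerate=True)
        return model, weights
    logp = np.stack(
        [np.log(np.maximum(pi[c], 1e-300)) + _norm_logpdf(x, m[c], s[c])
         for c in range(2)]
    )
    mx = logp.max(axis=0)
    post_in = np.exp(logp[0] - (mx + np.log(np.exp(logp - mx).sum(axis=0))))
    weights[finite] = post_in
    model = OutlierModel(m[0], s[0], m[1], s[1], float(pi[0]), shell)
    return model, weights


def apply_prior_weights(weights, layout: AcquisitionLayout, priors) -> np.ndarray:
    """Multiply excitation weights by per-slice-position prior inlier
    probabilities (an excitation takes the minimum prior over its member
    slices).  `priors` is a dict mapping slice index to a multiplier in
    [0, 1], or an array over slice positions; missing entries default 1.
    """
    w = np.asarray(weights, dtype=float).copy()
    if isinstance(priors, dict):
        pr = np.ones(layout.n_slices)
        for k, v in priors.items():
            pr[int(k)] = v
    else:
        pr = np.asarray(priors, dtype=float)
        if pr.size != layout.n_slices:
            raise ValueError("one prior per slice position required")
    if np.any((pr < 0) | (pr > 1)):
        raise ValueError("priors must lie in [0, 1]")
    for e, exc in enumerate(layout.excitations):
        w[e] *= min(pr[z] for z in exc.slices)
    return w


# ---------------------------------------------------------------------------
# Motion metrics

def motion_metrics(trace, weights, layout: AcquisitionLayout):
    """Scan-level motion summary.

    Translation metric: RMS forward difference of the translation
    components, scaled by excitations-per-volume (mean intra-volume
    translation, mm).  Rotation metric analogous, in degrees.  Outlier
    ratio: one minus the mean slice weight.
    """
    poses = np.atleast_2d(np.asarray(trace, dtype=float))
    if poses.shape[0] < 2:
        raise ValueError("trace must have at least 2 excitations")
    d = np.diff(poses, axis=0)
    epv = layout.excitations_per_volume
    trans = float(np.sqrt(np.mean(np.sum(d[:, :3] ** 2, axis=1)))) * epv
    rot = float(np.sqrt(np.mean(np.sum(d[:, 3:] ** 2, axis=1)))) * epv
    rot_deg = np.degrees(rot)
    outlier_ratio = float(1.0 - np.mean(np.asarray(weights, dtype=float)))
    return trans, rot_deg, outlier_ratio


def summary_metric(metrics, cohort) -> float:
    """Dimensionless per-scan motion score.

    Each of the (translation, rotation, outlier-ratio) metrics is divided
    by its median across the cohort; the summary is the RMS of the three
    rescaled values, so a scan at the cohort median of all three scores 1.
    """
    m = np.asarray(metrics, dtype=float).ravel()
    cohort = np.atleast_2d(np.asarray(cohort, dtype=float))
    if m.size != 3 or cohort.shape[1] != 3:
        raise ValueError("metrics are (translation, rotation, outlier) triples")
    med = np.median(cohort, axis=0)
    if np.any(med <= 0):
        raise ValueError("cohort medians must be positive")
    return float(np.sqrt(np.mean((m / med) ** 2)))
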