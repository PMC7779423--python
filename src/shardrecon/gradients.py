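"""Diffusion gradient tables: shell clustering and file I/O.

A gradient table holds one (b-value, direction) pair per acquired volume.
Multi-shell acquisitions sample a small number of discrete b-values
("shells"); many downstream steps (per-shell spherical-harmonics fits, the
radial SHARD decomposition, per-shell outlier models) require each volume
to be assigned to exactly one shell.  Directions are unit vectors in the
scanner frame; the direction of a b=0 volume carries no information and is
stored as-is but never interpreted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GradientTable",
    "cluster_shells",
    "load_bvals_bvecs",
    "load_scheme",
    "save_scheme",
]

#: b-values closer than this (s/mm^2) to zero are treated as b=0.
B0_THRESHOLD = 50.0


@dataclass
class GradientTable:
    """Per-volume diffusion encoding, clustered into shells.

    Attributes
    ----------
    bvals : (n,) array
        Diffusion weighting per volume in s/mm^2.
    bvecs : (n, 3) array
        Unit encoding directions in the scanner frame (arbitrary for b=0).
    shell_index : (n,) int array
        Shell membership of each volume.
    shell_b : (n_shells,) array
        Representative (mean) b-value per shell, strictly increasing.
    """

    bvals: np.ndarray
    bvecs: np.ndarray
    shell_index: np.ndarray = field(default=None)  # type: ignore[assignment]
    shell_b: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.bvals = np.asarray(self.bvals, dtype=float).ravel()
        self.bvecs = np.asarray(self.bvecs, dtype=float)
        if self.bvecs.shape != (self.bvals.size, 3):
            raise ValueError(
                f"bvecs shape {self.bvecs.shape} inconsistent with "
                f"{self.bvals.size} b-values"
            )
        if np.any(self.bvals < 0):
            raise ValueError("negative b-values")
        nrm = np.linalg.norm(self.bvecs, axis=1)
        dw = self.bvals > B0_THRESHOLD
        if np.any(np.abs(nrm[dw] - 1.0) > 1e-4):
            raise ValueError("non-unit direction for diffusion-weighted volume")
        if self.shell_index is None or self.shell_b is None:
            self.shell_index, self.shell_b = cluster_shells(self.bvals)

    @property
    def n_volumes(self) -> int:
        return self.bvals.size

    @property
    def n_shells(self) -> int:
        return self.shell_b.size

    def shell_volumes(self, shell: int) -> np.ndarray:
        """Indices of the volumes belonging to one shell."""
        return np.flatnonzero(self.shell_index == shell)

    @property
    def is_b0_shell(self) -> np.ndarray:
        return self.shell_b <= B0_THRESHOLD


def cluster_shells(
    b_values, tolerance: float = 100.0
) -> tuple[np.ndarray, np.ndarray]:
    """Group b-values into shells by greedy 1-D clustering.

    Scanning the sorted b-values from low to high, a value joins the
    current shell if it lies within `tolerance` of the running shell mean,
    otherwise it seeds a new shell.  A value equidistant to two shells is
    therefore absorbed by the lower one.

    Returns
    -------
    shell_index : (n,) int array
    shell_b : (n_shells,) array of per-shell mean b-values
    """
    b = np.asarray(b_values, dtype=float).ravel()
    if b.size == 0:
        raise ValueError("empty b-value list")
    if np.any(b < 0):
        raise ValueError("negative b-values")
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    order = np.argsort(b, kind="stable")
    shell_index = np.empty(b.size, dtype=int)
    means: list[float] = []
    counts: list[int] = []
    for i in order:
        if means and (b[i] - means[-1]) < tolerance:
            k = len(means) - 1
            means[k] = (means[k] * counts[k] + b[i]) / (counts[k] + 1)
            counts[k] += 1
        else:
            means.append(b[i])
            counts.append(1)
            k = len(means) - 1
        shell_index[i] = k
    return shell_index, np.asarray(means)


def _normalize(bvecs: np.ndarray, bvals: np.ndarray) -> np.ndarray:
    out = np.array(bvecs, dtype=float)
    nrm = np.linalg.norm(out, axis=1)
    ok = nrm > 0
    out[ok] /= nrm[ok, None]
    out[~ok] = np.array([0.0, 0.0, 1.0])
    return out


def load_bvals_bvecs(bvals_path, bvecs_path) -> GradientTable:
    """Read an FSL-style bvals/bvecs pair (bvecs stored as 3 rows)."""
    bvals = np.loadtxt(bvals_path).ravel()
    bvecs = np.loadtxt(bvecs_path)
    if bvecs.shape[0] == 3 and bvecs.shape != (3, 3):
        bvecs = bvecs.T
    elif bvecs.ndim == 1:
        bvecs = bvecs[None, :]
    if bvecs.shape != (bvals.size, 3):
        raise ValueError("bvals/bvecs size mismatch")
    return GradientTable(bvals, _normalize(bvecs, bvals))


def load_scheme(path) -> GradientTable:
    """Read a 4-column scheme file: x y z b per line."""
    tab = np.atleast_2d(np.loadtxt(path))
    if tab.shape[1] != 4:
        raise ValueError("scheme file must have 4 columns (x y z b)")
    bvals = tab[:, 3]
    return GradientTable(bvals, _normalize(tab[:, :3], bvals))


def save_scheme(path, grad: GradientTable) -> None:
    """Write a 4-column (x y z b) scheme file."""
    tab = np.column_stack([grad.bvecs, grad.bvals])
    np.savetxt(path, tab, fmt="%.10g")
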