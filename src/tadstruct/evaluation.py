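"""Structure superposition (Kabsch) and RMSD comparison."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .hic_io import Structure3D

__all__ = [
    "SuperpositionResult",
    "kabsch_superpose",
    "pairwise_structure_rmsd",
    "recovery_rmsd",
]


@dataclass
class SuperpositionResult:
    """Optimal rigid (or similarity) transform of mobile onto reference.

    ``transform`` applies ``x -> scale * rotation @ x + translation``.
    """

    rotation: np.ndarray  # 3x3, proper (det = +1)
    translation: np.ndarray  # length 3
    scale: float  # 1.0 unless allow_scale
    rmsd: float
    collinear: bool = False

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return self.scale * coords @ self.rotation.T + self.translation


def _coords(x) -> np.ndarray:
    if isinstance(x, Structure3D):
        x = x.coords
    x = np.asarray(x, dtype=float)
    if x.ndim != 2 or x.shape[1] != 3:
        raise ValueError(f"expected n x 3 coordinates, got shape {x.shape}")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite coordinates")
    return x


def kabsch_superpose(mobile, reference, allow_scale: bool = False) -> SuperpositionResult:
    """Least-squares superposition of ``mobile`` onto ``reference``.

    Reflections are excluded by flipping the sign of the smallest singular
    value when needed, so the rotation is always proper.  With
    ``allow_scale`` an optimal global scale (similarity transform) is fit as
    well, which is the right mode when the two structures' length units are
    arbitrary.  Collinear point sets are still solved but flagged.
    """
    a = _coords(mobile)
    b = _coords(reference)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    n = a.shape[0]
    if n < 3:
        raise ValueError("need at least 3 beads to superpose")
    mu_a = a.mean(axis=0)
    mu_b = b.mean(axis=0)
    ac = a - mu_a
    bc = b - mu_b
    h = ac.T @ bc
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    d = 1.0 if d == 0 else d
    flip = np.array([1.0, 1.0, d])
    rot = vt.T @ np.diag(flip) @ u.T
    if allow_scale:
        var_a = float((ac**2).sum())
        scale = float((s * flip).sum() / var_a) if var_a > 0 else 1.0
    else:
        scale = 1.0
    translation = mu_b - scale * rot @ mu_a
    fitted = scale * ac @ rot.T
    rmsd = float(np.sqrt(((fitted - bc) ** 2).sum() / n))
    collinear = bool(
        np.linalg.matrix_rank(ac, tol=1e-12 * max(1.0, np.abs(ac).max())) < 2
    )
    return SuperpositionResult(rot, translation, scale, rmsd, collinear)


def recovery_rmsd(reconstructed, truth, allow_scale: bool = True) -> float:
    """RMSD of a reconstruction against ground truth, up to mirror symmetry.

    Pairwise distances determine a structure only up to a rigid motion plus
    a reflection, so distance-based reconstruction cannot observe chirality;
    recovery is scored as the better of the structure and its mirror image,
    each superposed with a proper rotation (and, by default, a scale, since
    the distance unit is a free parameter).
    """
    a = _coords(reconstructed)
    mirrored = a * np.array([1.0, 1.0, -1.0])
    return min(
        kabsch_superpose(a, truth, allow_scale=allow_scale).rmsd,
        kabsch_superpose(mirrored, truth, allow_scale=allow_scale).rmsd,
    )


def pairwise_structure_rmsd(
    structures: Sequence, allow_scale: bool = False
) -> np.ndarray:
    """Symmetric matrix of minimum RMSDs between every pair of structures."""
    coords = [_coords(s) for s in structures]
    k = len(coords)
    ns = {c.shape[0] for c in coords}
    if len(ns) > 1:
        raise ValueError(f"structures have mismatched bead counts: {sorted(ns)}")
    out = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            r = kabsch_superpose(coords[i], coords[j], allow_scale=allow_scale).rmsd
            out[i, j] = out[j, i] = r
    return out
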