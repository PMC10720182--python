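"""Left-ventricular coordinate frame, helix angles, tensor downsampling.

Helix-angle convention (stated once, used everywhere): the frame's
``long_axis`` points *towards the base* (+z in the package axis
convention).  The helix angle is the signed angle, in (-90, +90], between
the fiber's projection onto the local (circumferential, longitudinal)
tangent plane and the circumferential direction, positive when the fiber
tilts towards the base.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .core import (
    EmptyMaskError,
    MyoarchError,
    ScalarVolume,
    TensorField,
    fa_from_eigenvalues,
)

__all__ = ["LVFrame", "fit_lv_frame", "helix_angle", "downsample_tensors_logE"]

#: Tangent-plane projection norm below which the helix angle is undefined.
RADIAL_FIBER_TOLERANCE = 0.2


@dataclass
class LVFrame:
    """LV coordinate frame: long axis (towards the base), origin, and the
    per-point circumferential / radial directions derived from either
    cylindrical coordinates about the axis (whole-heart style) or a fixed
    transmural normal (wedge/slab style).
    """

    long_axis: np.ndarray                 # unit 3-vector, world, towards base
    origin: np.ndarray                    # mm point on the axis
    slab_normal: np.ndarray | None = None  # fixed transmural direction (slab mode)
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.long_axis = np.asarray(self.long_axis, dtype=float)
        self.long_axis = self.long_axis / np.linalg.norm(self.long_axis)
        self.origin = np.asarray(self.origin, dtype=float)
        if self.slab_normal is not None:
            n = np.asarray(self.slab_normal, dtype=float)
            n = n - (n @ self.long_axis) * self.long_axis
            self.slab_normal = n / np.linalg.norm(n)

    def directions(self, points: np.ndarray):
        """Unit (circumferential, radial, longitudinal) triads at ``points``.

        Cylindrical mode: radial points outward from the axis,
        circumferential = long_axis x radial (right-handed).  Slab mode:
        radial is the fixed transmural normal.
        """
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        longdir = np.broadcast_to(self.long_axis, pts.shape)
        if self.slab_normal is not None:
            radial = np.broadcast_to(self.slab_normal, pts.shape)
        else:
            rel = pts - self.origin
            rel = rel - np.outer(rel @ self.long_axis, self.long_axis)
            norms = np.linalg.norm(rel, axis=-1, keepdims=True)
            radial = np.divide(rel, norms, out=np.zeros_like(rel), where=norms > 1e-12)
        circ = np.cross(longdir, radial)
        norms = np.linalg.norm(circ, axis=-1, keepdims=True)
        circ = np.divide(circ, norms, out=np.zeros_like(circ), where=norms > 1e-12)
        return circ, radial, np.asarray(longdir)

    def to_dict(self) -> dict:
        return {
            "long_axis": self.long_axis.tolist(),
            "origin": self.origin.tolist(),
            "slab_normal": None if self.slab_normal is None else self.slab_normal.tolist(),
        }


def fit_lv_frame(mask: np.ndarray, affine: np.ndarray) -> LVFrame:
    """Fit the LV long axis from a binary mask.

    The axis is the principal (largest-eigenvalue) axis of the mask's
    second-moment tensor; the origin is the mask centroid.  The sign is
    chosen so the axis points towards the end with the larger
    cross-section (the base, by the heuristic that basal slices are wider
    than apical ones).  Masks without a dominant axis (eigenvalue ratio
    < 1.1) trigger an ambiguity warning and default to +z.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise EmptyMaskError("cannot fit an LV frame to an empty mask")
    idx = np.argwhere(mask).astype(float)
    world = idx @ np.asarray(affine)[:3, :3].T + np.asarray(affine)[:3, 3]
    centroid = world.mean(axis=0)
    rel = world - centroid
    cov = rel.T @ rel / len(rel)
    evals, evecs = np.linalg.eigh(cov)
    if evals[1] <= 0 or evals[2] / max(evals[1], 1e-30) < 1.1:
        warnings.warn(
            "mask has no dominant axis (eigenvalue ratio < 1.1); "
            "defaulting long axis to +z",
            stacklevel=2,
        )
        return LVFrame(long_axis=np.array([0.0, 0.0, 1.0]), origin=centroid,
                       meta={"ambiguous": True})
    axis = evecs[:, 2]
    # base disambiguation: wider cross-section end = base; axis points there
    proj = rel @ axis
    span = proj.max() - proj.min()
    hi = (proj >= proj.max() - 0.1 * span).sum()
    lo = (proj <= proj.min() + 0.1 * span).sum()
    if lo > hi:
        axis = -axis
    return LVFrame(long_axis=axis, origin=centroid,
                   meta={"eigenvalues": evals.tolist(), "ambiguous": False})


def helix_angle(
    fibers: np.ndarray,
    frame: LVFrame,
    mask: np.ndarray,
    affine: np.ndarray,
) -> ScalarVolume:
    """Per-voxel helix angle in degrees; NaN where undefined or unmasked.

    The fiber is projected onto the local (circumferential, longitudinal)
    tangent plane; voxels whose projection norm falls below
    ``RADIAL_FIBER_TOLERANCE`` (near-radial fibers) are flagged NaN.
    """
    mask = np.asarray(mask, dtype=bool)
    fibers = np.asarray(fibers, dtype=float)
    affine = np.asarray(affine, dtype=float)
    idx = np.argwhere(mask).astype(float)
    pts = idx @ affine[:3, :3].T + affine[:3, 3]
    circ, _, longdir = frame.directions(pts)
    f = fibers[mask]
    fc = (f * circ).sum(-1)
    fl = (f * longdir).sum(-1)
    # antipodal rectification: representative with nonnegative circumferential
    flip = (fc < 0) | ((fc == 0) & (fl < 0))
    fc = np.where(flip, -fc, fc)
    fl = np.where(flip, -fl, fl)
    pnorm = np.hypot(fc, fl)
    ha = np.degrees(np.arctan2(fl, fc))
    ha = np.where(pnorm < RADIAL_FIBER_TOLERANCE, np.nan, ha)
    out = np.full(mask.shape, np.nan)
    out[mask] = ha
    return ScalarVolume(out, affine.copy())


def _matrix_log_spd(tensors: np.ndarray) -> np.ndarray:
    evals, evecs = np.linalg.eigh(tensors)
    if np.any(evals <= 0):
        raise MyoarchError(
            "non-SPD tensor encountered in log-Euclidean resampling "
            "(upstream clamping failed)"
        )
    return np.einsum("...ij,...j,...kj->...ik", evecs, np.log(evals), evecs)


def _matrix_exp_sym(tensors: np.ndarray) -> np.ndarray:
    evals, evecs = np.linalg.eigh(tensors)
    return np.einsum("...ij,...j,...kj->...ik", evecs, np.exp(evals), evecs)


def _box_weights(n_in: int, factor: float):
    """Overlap weights of output cells of width ``factor`` input voxels."""
    n_out = int(np.ceil(n_in / factor - 1e-9))
    W = np.zeros((n_out, n_in))
    for o in range(n_out):
        lo, hi = o * factor, (o + 1) * factor
        i0, i1 = int(np.floor(lo)), min(int(np.ceil(hi)), n_in)
        for i in range(i0, i1):
            W[o, i] = max(0.0, min(hi, i + 1) - max(lo, i))
    return W


def downsample_tensors_logE(tf: TensorField, target_spacing) -> TensorField:
    """Downsample a tensor field by averaging in the log-Euclidean space.

    Per output voxel, the matrix logarithms of contributing source tensors
    are averaged with box-footprint (partial-volume) weights and
    exponentiated -- emulating scanner partial-volume averaging while
    guaranteeing an SPD result.  Masked-out source voxels are excluded
    from the average; an output voxel is masked out when less than 50% of
    its footprint is covered by masked-in tissue.
    """
    target_spacing = np.broadcast_to(np.asarray(target_spacing, dtype=float), (3,))
    src_spacing = tf.spacing
    if np.any(target_spacing < src_spacing - 1e-9):
        raise ValueError("target spacing must be >= source spacing on every axis")
    factors = target_spacing / src_spacing

    logs = np.zeros_like(tf.tensors)
    if tf.mask.any():
        logs[tf.mask] = _matrix_log_spd(tf.symmetrized()[tf.mask])
    w = tf.mask.astype(float)
    num = logs * w[..., None, None]

    Ws = [_box_weights(tf.shape[a], factors[a]) for a in range(3)]
    full = [Wa.sum(axis=1) for Wa in Ws]

    def _apply(arr):
        arr = np.tensordot(Ws[0], arr, axes=(1, 0))
        arr = np.moveaxis(np.tensordot(Ws[1], np.moveaxis(arr, 1, 0), axes=(1, 0)), 0, 1)
        arr = np.moveaxis(np.tensordot(Ws[2], np.moveaxis(arr, 2, 0), axes=(1, 0)), 0, 2)
        return arr

    num_ds = _apply(num)
    w_ds = _apply(w)
    footprint = (
        full[0][:, None, None] * full[1][None, :, None] * full[2][None, None, :]
    )
    out_mask = w_ds >= 0.5 * footprint
    out_mask &= w_ds > 0

    mean_log = np.zeros_like(num_ds)
    mean_log[out_mask] = num_ds[out_mask] / w_ds[out_mask, None, None]
    out = np.zeros_like(mean_log)
    if out_mask.any():
        out[out_mask] = _matrix_exp_sym(mean_log[out_mask])

    lin = tf.affine[:3, :3] @ np.diag(factors)
    shift = tf.affine[:3, :3] @ (factors / 2.0 - 0.5) + tf.affine[:3, 3]
    new_affine = np.eye(4)
    new_affine[:3, :3] = lin
    new_affine[:3, 3] = shift
    return TensorField(
        tensors=out,
        mask=out_mask,
        affine=new_affine,
        metadata={**tf.metadata, "downsample_factors": factors.tolist()},
    )


def logE_mean(tensors: np.ndarray, weights=None) -> np.ndarray:
    """Weighted log-Euclidean mean of a stack of SPD tensors (n, 3, 3)."""
    tensors = np.asarray(tensors, dtype=float)
    logs = _matrix_log_spd(tensors)
    if weights is None:
        mean = logs.mean(axis=0)
    else:
        w = np.asarray(weights, dtype=float)
        mean = (logs * w[:, None, None]).sum(0) / w.sum()
    return _matrix_exp_sym(mean)


def fa_of_tensor(t: np.ndarray) -> float:
    """FA of a single 3x3 symmetric tensor."""
    evals = np.linalg.eigvalsh(np.asarray(t, dtype=float))
    return float(fa_from_eigenvalues(evals))
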