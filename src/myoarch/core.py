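"""Shared containers, eigensystem utilities, conventions, and error types.

Axis conventions used throughout the package (documented once, here):

* world coordinates are in millimetres, RAS-like, voxel-centre convention,
  0-based indices internally; NIfTI-style 4x4 affines map voxel indices to
  world mm and are the single source of geometric truth;
* ``x`` is the circumferential direction, ``y`` the transmural direction,
  ``z`` the left-ventricular long axis (+z points towards the base);
* eigenvalues are ordered descending; eigenvector sign is fixed by the
  antipodal convention v.z >= 0 (ties broken by y, then x, nonnegative).
"""

from __future__ import annotations

from dataclasses import dataclass, field
import zlib

import numpy as np

__all__ = [
    "MyoarchError",
    "DimensionError",
    "SchemeError",
    "EmptyMaskError",
    "EmptyResultError",
    "ConfigError",
    "StabilityError",
    "ScalarVolume",
    "TensorField",
    "affine_from_spacing",
    "fix_antipodal_sign",
    "fa_from_eigenvalues",
    "sorted_eigh",
    "substream",
]


class MyoarchError(Exception):
    """Base class for all package-specific errors."""


class DimensionError(MyoarchError):
    """A geometric object does not fit the grid or volume it was asked to."""


class SchemeError(MyoarchError):
    """Invalid diffusion acquisition scheme (directions / b-values)."""


class EmptyMaskError(MyoarchError):
    """A segmentation or delineation produced an empty mask."""


class EmptyResultError(MyoarchError):
    """A thresholding operation produced an empty result."""


class ConfigError(MyoarchError):
    """Invalid pipeline configuration."""


class StabilityError(MyoarchError):
    """Explicit time integration became unstable."""


def affine_from_spacing(spacing, origin=(0.0, 0.0, 0.0)) -> np.ndarray:
    """Build a diagonal voxel->world affine from per-axis spacing (mm)."""
    spacing = np.broadcast_to(np.asarray(spacing, dtype=float), (3,))
    aff = np.eye(4)
    aff[:3, :3] = np.diag(spacing)
    aff[:3, 3] = np.asarray(origin, dtype=float)
    return aff


@dataclass
class ScalarVolume:
    """A 3D voxel grid with a voxel->world affine (mm).

    Carries anatomy-like intensities, FA, track-density counts, activation
    times -- any scalar quantity living on a regular grid.
    """

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self):
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3:
            raise DimensionError(f"ScalarVolume expects 3D data, got shape {self.data.shape}")
        if self.affine.shape != (4, 4):
            raise DimensionError("affine must be 4x4")

    @property
    def shape(self):
        return self.data.shape

    @property
    def spacing(self) -> np.ndarray:
        """Per-axis voxel size in mm (norm of the affine columns)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def voxel_volume(self) -> float:
        """Voxel volume in mm^3."""
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def index_to_world(self, idx) -> np.ndarray:
        idx = np.atleast_2d(np.asarray(idx, dtype=float))
        return idx @ self.affine[:3, :3].T + self.affine[:3, 3]

    def world_to_index(self, pts) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        inv = np.linalg.inv(self.affine[:3, :3])
        return (pts - self.affine[:3, 3]) @ inv.T


@dataclass
class TensorField:
    """Symmetric 3x3 tensor per voxel (diffusion mm^2/s or structure a.u.^2).

    ``tensors`` has shape (nx, ny, nz, 3, 3); ``mask`` marks voxels where the
    tensor is meaningful.  ``metadata`` records provenance such as the
    eigenvalue clamping floor and clamp counts.
    """

    tensors: np.ndarray
    mask: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.tensors = np.asarray(self.tensors, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.tensors.shape[-2:] != (3, 3):
            raise DimensionError("tensors must have trailing shape (3, 3)")
        if self.tensors.shape[:-2] != self.mask.shape:
            raise DimensionError("mask shape must match tensor grid")

    @property
    def shape(self):
        return self.mask.shape

    @property
    def spacing(self) -> np.ndarray:
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def voxel_volume(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def symmetrized(self) -> np.ndarray:
        return 0.5 * (self.tensors + np.swapaxes(self.tensors, -1, -2))

    def eigensystem(self):
        """Descending eigenvalues and sign-fixed eigenvectors.

        Returns ``(evals, evecs)`` with ``evals[..., 0] >= evals[..., 1] >=
        evals[..., 2]`` and ``evecs[..., i]`` the i-th unit eigenvector.
        """
        return sorted_eigh(self.symmetrized())


def fix_antipodal_sign(vecs: np.ndarray) -> np.ndarray:
    """Resolve the +/-v ambiguity of eigenvectors.

    The sign is chosen so that v.z >= 0; if v.z == 0 then v.y >= 0; if both
    vanish then v.x >= 0.  Operates on the last axis (length 3).
    """
    vecs = np.asarray(vecs, dtype=float)
    x, y, z = vecs[..., 0], vecs[..., 1], vecs[..., 2]
    flip = (z < 0) | ((z == 0) & (y < 0)) | ((z == 0) & (y == 0) & (x < 0))
    return np.where(flip[..., None], -vecs, vecs)


def sorted_eigh(tensors: np.ndarray):
    """Batched symmetric eigendecomposition, descending, sign-fixed.

    Degenerate eigenvalue pairs inherit LAPACK's deterministic ordering, so
    results are reproducible for identical inputs.
    """
    evals, evecs = np.linalg.eigh(tensors)
    evals = evals[..., ::-1]
    evecs = evecs[..., :, ::-1]
    # sign convention applied per eigenvector (columns of evecs)
    evecs = np.swapaxes(fix_antipodal_sign(np.swapaxes(evecs, -1, -2)), -1, -2)
    return np.ascontiguousarray(evals), np.ascontiguousarray(evecs)


def fa_from_eigenvalues(evals: np.ndarray) -> np.ndarray:
    """Fractional anisotropy sqrt(3/2) * ||lam - MD|| / ||lam||.

    A zero tensor has FA = 0 by convention (not an error).
    """
    evals = np.asarray(evals, dtype=float)
    md = evals.mean(axis=-1, keepdims=True)
    num = np.linalg.norm(evals - md, axis=-1)
    den = np.linalg.norm(evals, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5) * num / den
    return np.where(den > 0, fa, 0.0)


def substream(seed: int, name: str) -> np.random.Generator:
    """Named, reproducible RNG substream derived from a single global seed.

    The stream key is the CRC-32 of ``name``, so every stage draws from an
    independent, documented stream of the same root seed.
    """
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=(key,)))
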