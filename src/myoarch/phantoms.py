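"""Synthetic phantoms emulating an ex-vivo ventricular-wedge dataset.

The generators produce (a) a wedge of circumferentially oriented myocytes
containing a transmural, triangle-sectioned bundle of apex--base-oriented
myocytes with an abrupt orientation discontinuity at its border, (b) 6+
direction diffusion-weighted signal volumes with Rician noise, and (c) a
microCT-like laminar intensity texture aligned with the fiber field.  Every
downstream stage of the package (tensor fitting, structure-tensor
orientation, tractography, electrophysiology) is testable against the
ground truth stored here.

Axis conventions: see :mod:`myoarch.core` -- x circumferential, y
transmural, z long axis (base at +z).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

from .core import (
    DimensionError,
    ScalarVolume,
    SchemeError,
    affine_from_spacing,
    substream,
)

__all__ = [
    "FiberPhantom",
    "AcquisitionScheme",
    "default_scheme",
    "make_fiber_phantom",
    "make_annulus_phantom",
    "simulate_dwi",
    "make_microct_phantom",
    "DEFAULT_EIGENVALUES",
    "FLUID_DIFFUSIVITY",
]

#: Default diffusion eigenvalues (mm^2/s) for myocardial tissue.  Chosen to
#: give an FA of ~0.31, in the range reported for fixed ex-vivo myocardium.
DEFAULT_EIGENVALUES = (1.0e-3, 0.65e-3, 0.55e-3)

#: Isotropic diffusivity (mm^2/s) of the fluid surrounding the wedge
#: (residual fixative), used to give background voxels a hyperintense trace.
FLUID_DIFFUSIVITY = 2.2e-3

# label semantics
LABEL_BACKGROUND = 0
LABEL_MYOCARDIUM = 1
LABEL_BUNDLE = 2
LABEL_INTERFACE = 3


@dataclass
class FiberPhantom:
    """Ground-truth fiber field on a regular grid.

    ``labels``: 0 background, 1 circumferential myocardium, 2 bundle
    (the "singularity"), 3 one-voxel interface shell around the bundle.
    ``cavity_labels``: 0 none, 1 RV-side cavity surface, 2 LV-side cavity
    surface -- proxies for the ventricular cavities used by morphometry.
    """

    fibers: np.ndarray          # (nx, ny, nz, 3) unit vectors, 0 outside
    labels: np.ndarray          # (nx, ny, nz) uint8
    cavity_labels: np.ndarray   # (nx, ny, nz) uint8
    spacing: np.ndarray         # (3,) mm
    wedge_dims: np.ndarray      # (3,) mm
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    meta: dict = field(default_factory=dict)

    @property
    def shape(self):
        return self.labels.shape

    @property
    def myocardium(self) -> np.ndarray:
        """Boolean mask of all tissue voxels (labels 1, 2, 3)."""
        return self.labels > 0

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))


@dataclass
class AcquisitionScheme:
    """Diffusion acquisition: b-values (s/mm^2), unit directions, noise.

    ``snr`` is the Rician signal-to-noise ratio at b = 0, defined as
    S0 / sigma_gaussian; ``np.inf`` means noiseless.
    """

    bvalues: np.ndarray
    directions: np.ndarray
    S0: float = 1000.0
    snr: float = np.inf
    seed: int = 0

    def __post_init__(self):
        self.bvalues = np.asarray(self.bvalues, dtype=float)
        self.directions = np.asarray(self.directions, dtype=float)
        if self.directions.shape != (self.bvalues.size, 3):
            raise SchemeError(
                f"directions shape {self.directions.shape} does not match "
                f"{self.bvalues.size} b-values"
            )
        nz = self.bvalues > 0
        norms = np.linalg.norm(self.directions[nz], axis=1)
        if nz.sum() and not np.allclose(norms, 1.0, atol=1e-6):
            raise SchemeError("nonzero-b directions must be unit norm")
        if (~nz).sum() < 1:
            raise SchemeError("at least one b = 0 volume is required")
        if nz.sum() >= 6:
            g = self.directions[nz]
            design = np.column_stack(
                [g[:, 0] ** 2, g[:, 1] ** 2, g[:, 2] ** 2,
                 2 * g[:, 0] * g[:, 1], 2 * g[:, 0] * g[:, 2], 2 * g[:, 1] * g[:, 2]]
            )
            if np.linalg.matrix_rank(design) < 6:
                raise SchemeError("diffusion directions are collinear (rank-deficient design)")
        else:
            raise SchemeError("at least 6 noncollinear nonzero-b directions are required")


#: The classic icosahedral-style 6-direction encoding set.
_SIX_DIRECTIONS = np.array(
    [
        [1.0, 1.0, 0.0],
        [1.0, -1.0, 0.0],
        [1.0, 0.0, 1.0],
        [1.0, 0.0, -1.0],
        [0.0, 1.0, 1.0],
        [0.0, 1.0, -1.0],
    ]
) / np.sqrt(2.0)


def default_scheme(b: float = 1000.0, S0: float = 1000.0, snr: float = np.inf,
                   seed: int = 0) -> AcquisitionScheme:
    """One b = 0 volume plus six noncollinear directions at the given b."""
    bvals = np.concatenate([[0.0], np.full(6, float(b))])
    dirs = np.vstack([[0.0, 0.0, 0.0], _SIX_DIRECTIONS])
    return AcquisitionScheme(bvalues=bvals, directions=dirs, S0=S0, snr=snr, seed=seed)


def _triangle_mask_2d(x_mm, y_mm, cx, y0, base_width, depth):
    """Triangle in the x (circumferential) - y (transmural) plane.

    Base of width ``base_width`` at transmural position ``y0`` (RV side),
    apex at ``y0 + depth`` mid-wall; half-width shrinks linearly with depth.
    """
    t = (y_mm - y0) / depth
    half = 0.5 * base_width * (1.0 - t)
    inside = (t >= 0.0) & (t <= 1.0) & (np.abs(x_mm - cx) <= half)
    return inside


def make_fiber_phantom(
    wedge_dims: Sequence[float] = (30.0, 20.0, 30.0),
    spacing: float | Sequence[float] = 0.6,
    triangle_params: dict | None = None,
    discontinuity_angle: float = 90.0,
    seed: int = 0,
    pad_voxels: int = 2,
) -> FiberPhantom:
    """Build the ventricular-wedge fiber phantom with the triangular bundle.

    Parameters
    ----------
    wedge_dims : (3,) mm
        Extent of the myocardial slab along (x, y, z).
    spacing : mm
        Isotropic or per-axis voxel size.
    triangle_params : dict
        ``base_width`` (mm, along x at the RV-side wall), ``depth`` (mm,
        transmural extent along y), ``apex_extent`` (mm, length along the
        long axis z).  Defaults emulate a bundle with a ~2 cm long-axis
        extent embedded in the basal part of the wedge.
    discontinuity_angle : degrees
        Angle between the bundle fibers and the surrounding circumferential
        fibers.  90 deg (default) makes the bundle purely apex--base.
    seed : int
        Reserved for reproducibility bookkeeping; the geometry itself is
        deterministic.
    pad_voxels : int
        Background (fluid) padding around the slab on every axis.
    """
    wedge_dims = np.asarray(wedge_dims, dtype=float)
    spacing = np.broadcast_to(np.asarray(spacing, dtype=float), (3,)).copy()
    if np.any(wedge_dims <= 0):
        raise DimensionError("wedge_dims must be positive")
    if triangle_params is None:
        triangle_params = {}
    base_width = float(triangle_params.get("base_width", 8.0))
    depth = float(triangle_params.get("depth", 10.0))
    apex_extent = float(triangle_params.get("apex_extent", 18.0))
    # optional standoffs from the wedge surfaces (used when the wedge is an
    # ROI crop with the bundle in its interior rather than wall-attached)
    base_offset = float(triangle_params.get("base_offset", 0.0))
    depth_offset = float(triangle_params.get("depth_offset", 0.0))
    if not (0.0 <= discontinuity_angle <= 90.0):
        raise ValueError("discontinuity_angle must be in [0, 90] degrees")

    for value, name, axis in [
        (base_width, "base_width", "x"),
        (depth, "depth", "y"),
        (apex_extent, "apex_extent", "z"),
    ]:
        if value < 0:
            raise DimensionError(f"{name} must be nonnegative")
        if value > wedge_dims["xyz".index(axis)]:
            raise DimensionError(
                f"triangle {name} = {value} mm does not fit the wedge along axis "
                f"{axis} ({wedge_dims['xyz'.index(axis)]} mm)"
            )

    n_wedge = np.round(wedge_dims / spacing).astype(int)
    shape = tuple(n_wedge + 2 * pad_voxels)
    affine = affine_from_spacing(spacing)

    labels = np.zeros(shape, dtype=np.uint8)
    sl = tuple(slice(pad_voxels, pad_voxels + n) for n in n_wedge)
    labels[sl] = LABEL_MYOCARDIUM

    # voxel-centre world coordinates, wedge-local (origin at wedge corner)
    idx = np.indices(shape).astype(float)
    coords = np.stack(
        [(idx[a] - pad_voxels + 0.5) * spacing[a] for a in range(3)], axis=-1
    )
    x_mm, y_mm, z_mm = coords[..., 0], coords[..., 1], coords[..., 2]

    degenerate = base_width == 0.0 or depth == 0.0 or apex_extent == 0.0
    if not degenerate:
        cx = 0.5 * wedge_dims[0]
        y0 = depth_offset  # triangle base at/near the RV-side wall surface
        z_hi = wedge_dims[2] - base_offset  # bundle starts at the base (+z)
        z_lo = z_hi - apex_extent           # ... and dives towards the apex
        if z_lo < 0 or y0 + depth > wedge_dims[1]:
            raise DimensionError(
                "triangle offsets push the bundle outside the wedge along "
                f"axis {'z' if z_lo < 0 else 'y'}"
            )
        tri = _triangle_mask_2d(x_mm, y_mm, cx, y0, base_width, depth)
        tri &= (z_mm >= z_lo) & (z_mm <= z_hi)
        tri &= labels == LABEL_MYOCARDIUM
        labels[tri] = LABEL_BUNDLE

    # one-voxel interface shell: myocardium voxels 26-adjacent to the bundle
    bundle = labels == LABEL_BUNDLE
    if bundle.any():
        shell = ndimage.binary_dilation(bundle, structure=np.ones((3, 3, 3), bool))
        shell &= labels == LABEL_MYOCARDIUM
        labels[shell] = LABEL_INTERFACE

    theta = np.deg2rad(discontinuity_angle)
    bundle_dir = np.array([np.cos(theta), 0.0, np.sin(theta)])
    fibers = np.zeros(shape + (3,), dtype=float)
    fibers[labels == LABEL_MYOCARDIUM] = [1.0, 0.0, 0.0]
    fibers[labels == LABEL_INTERFACE] = [1.0, 0.0, 0.0]
    fibers[labels == LABEL_BUNDLE] = bundle_dir

    # cavity proxies: fluid slabs on the two transmural faces
    cavity = np.zeros(shape, dtype=np.uint8)
    cavity[:, :pad_voxels, :] = 1  # RV side (triangle base side)
    cavity[:, pad_voxels + n_wedge[1]:, :] = 2  # LV side
    cavity[labels > 0] = 0

    return FiberPhantom(
        fibers=fibers,
        labels=labels,
        cavity_labels=cavity,
        spacing=spacing,
        wedge_dims=wedge_dims,
        affine=affine,
        meta={
            "triangle_params": {
                "base_width": base_width,
                "depth": depth,
                "apex_extent": apex_extent,
            },
            "discontinuity_angle": discontinuity_angle,
            "pad_voxels": pad_voxels,
            "seed": seed,
        },
    )


def ep_wedge_phantom(spacing: float = 0.3, seed: int = 0) -> FiberPhantom:
    """The ROI wedge used by the electrophysiology comparison study.

    A 12 x 9 x 18 mm block at the upsampled DTI resolution (0.3 mm) with
    the triangular bundle fully interior (3 mm below the basal face,
    1.5 mm off the RV-side wall) so surface pacing never stimulates the
    bundle directly; the bundle is ~5% of the tissue, as in an ROI around
    the insertion point.
    """
    return make_fiber_phantom(
        wedge_dims=(12.0, 9.0, 18.0),
        spacing=spacing,
        triangle_params={
            "base_width": 5.0, "depth": 5.0, "apex_extent": 8.0,
            "base_offset": 3.0, "depth_offset": 1.5,
        },
        seed=seed,
        pad_voxels=1,
    )


def make_annulus_phantom(
    outer_radius: float = 12.0,
    inner_radius: float = 6.0,
    height: float = 20.0,
    spacing: float = 0.6,
    helix_endo: float = 60.0,
    helix_epi: float = -60.0,
    pad_voxels: int = 2,
) -> FiberPhantom:
    """Cylindrical-annulus phantom with a linear transmural helix-angle ramp.

    Used to exercise the LV frame fit and helix-angle mapping on a geometry
    where the analytic helix angle is known at every voxel.
    """
    spacing3 = np.full(3, float(spacing))
    n_xy = int(np.ceil(2 * outer_radius / spacing)) + 2 * pad_voxels
    n_z = int(np.ceil(height / spacing)) + 2 * pad_voxels
    shape = (n_xy, n_xy, n_z)
    affine = affine_from_spacing(spacing3)
    centre = (np.array(shape) / 2.0) * spacing3

    idx = np.indices(shape).astype(float)
    coords = np.stack([(idx[a] + 0.5) * spacing3[a] for a in range(3)], axis=-1)
    dx = coords[..., 0] - centre[0]
    dy = coords[..., 1] - centre[1]
    r = np.hypot(dx, dy)
    z = coords[..., 2]
    in_z = (z >= centre[2] - height / 2) & (z <= centre[2] + height / 2)
    ring = (r >= inner_radius) & (r <= outer_radius) & in_z

    labels = np.where(ring, LABEL_MYOCARDIUM, LABEL_BACKGROUND).astype(np.uint8)

    with np.errstate(invalid="ignore", divide="ignore"):
        circ = np.stack([-dy / r, dx / r, np.zeros_like(r)], axis=-1)
    circ = np.nan_to_num(circ)
    depth = np.clip((r - inner_radius) / max(outer_radius - inner_radius, 1e-9), 0, 1)
    ha = np.deg2rad(helix_endo + (helix_epi - helix_endo) * depth)
    fibers = (np.cos(ha)[..., None] * circ)
    fibers[..., 2] += np.sin(ha)
    fibers[~ring] = 0.0
    norms = np.linalg.norm(fibers, axis=-1, keepdims=True)
    fibers = np.divide(fibers, norms, out=np.zeros_like(fibers), where=norms > 0)

    return FiberPhantom(
        fibers=fibers,
        labels=labels,
        cavity_labels=np.zeros(shape, dtype=np.uint8),
        spacing=spacing3,
        wedge_dims=np.array([2 * outer_radius, 2 * outer_radius, height]),
        affine=affine,
        meta={"kind": "annulus", "helix_endo": helix_endo, "helix_epi": helix_epi,
              "inner_radius": inner_radius, "outer_radius": outer_radius,
              "centre": centre.tolist()},
    )


def _tensor_from_fiber(fibers: np.ndarray, eigenvalues) -> np.ndarray:
    """Axially symmetric diffusion tensor with principal axis = fiber.

    The secondary/tertiary axes form a deterministic orthonormal frame
    (cross products with z-hat, falling back to x-hat for fibers along z).
    """
    lam1, lam2, lam3 = eigenvalues
    f = np.asarray(fibers, dtype=float)
    ref = np.broadcast_to(np.array([0.0, 0.0, 1.0]), f.shape).copy()
    parallel = np.abs((f * ref).sum(-1)) > 0.9
    ref[parallel] = [1.0, 0.0, 0.0]
    e2 = np.cross(f, ref)
    n2 = np.linalg.norm(e2, axis=-1, keepdims=True)
    e2 = np.divide(e2, n2, out=np.zeros_like(e2), where=n2 > 0)
    e3 = np.cross(f, e2)
    return (
        lam1 * f[..., :, None] * f[..., None, :]
        + lam2 * e2[..., :, None] * e2[..., None, :]
        + lam3 * e3[..., :, None] * e3[..., None, :]
    )


def ground_truth_tensors(phantom: FiberPhantom,
                         eigenvalues=DEFAULT_EIGENVALUES) -> np.ndarray:
    """Per-voxel diffusion tensors implied by the phantom fiber field.

    Tissue voxels get the axially symmetric tensor along the local fiber;
    background voxels get isotropic free-fluid diffusion.
    """
    D = _tensor_from_fiber(phantom.fibers, eigenvalues)
    iso = FLUID_DIFFUSIVITY * np.eye(3)
    D[~phantom.myocardium] = iso
    return D


def simulate_dwi(phantom: FiberPhantom,
                 eigenvalues=DEFAULT_EIGENVALUES,
                 scheme: AcquisitionScheme | None = None):
    """Forward-simulate DW volumes: S = S0 exp(-b g^T D g), Rician noise.

    Returns a :class:`myoarch.dti.DWIDataset`.  Noise is the magnitude of a
    complex Gaussian perturbation with sigma = S0 / snr, applied per volume;
    deterministic for a fixed scheme seed.
    """
    from .dti import DWIDataset  # local import to avoid a cycle

    lam1, lam2, lam3 = eigenvalues
    if not (lam1 >= lam2 >= lam3 > 0):
        raise ValueError("eigenvalues must satisfy lam1 >= lam2 >= lam3 > 0")
    if scheme is None:
        scheme = default_scheme()
    D = ground_truth_tensors(phantom, eigenvalues)
    nvol = scheme.bvalues.size
    data = np.empty(phantom.shape + (nvol,), dtype=float)
    for i in range(nvol):
        b = scheme.bvalues[i]
        g = scheme.directions[i]
        if b == 0:
            data[..., i] = scheme.S0
        else:
            bDg = np.einsum("...ij,i,j->...", D, g, g)
            data[..., i] = scheme.S0 * np.exp(-b * bDg)
    if np.isfinite(scheme.snr):
        rng = substream(scheme.seed, "phantoms.simulate_dwi")
        sigma = scheme.S0 / scheme.snr
        n1 = rng.normal(0.0, sigma, size=data.shape)
        n2 = rng.normal(0.0, sigma, size=data.shape)
        data = np.sqrt((data + n1) ** 2 + n2 ** 2)
    return DWIDataset(
        data=data,
        bvalues=scheme.bvalues.copy(),
        directions=scheme.directions.copy(),
        affine=phantom.affine.copy(),
    )


def upsample_phantom(phantom: FiberPhantom, factor: int) -> FiberPhantom:
    """Nearest-neighbour refinement of the phantom grid by an integer factor.

    Emulates imaging the same specimen at a finer voxel size (the microCT
    grid is much finer than the DW grid); fine voxel (i, j, k) corresponds
    to coarse voxel (i // factor, ...).
    """
    factor = int(factor)
    if factor < 1:
        raise ValueError("factor must be >= 1")
    if factor == 1:
        return phantom

    def _rep(arr):
        out = arr
        for a in range(3):
            out = np.repeat(out, factor, axis=a)
        return out

    scale = np.eye(4)
    scale[:3, :3] /= factor
    affine = phantom.affine @ scale
    affine[:3, 3] = phantom.affine[:3, :3] @ np.full(3, 0.5 / factor - 0.5) \
        + phantom.affine[:3, 3]
    return FiberPhantom(
        fibers=_rep(phantom.fibers),
        labels=_rep(phantom.labels),
        cavity_labels=_rep(phantom.cavity_labels),
        spacing=phantom.spacing / factor,
        wedge_dims=phantom.wedge_dims.copy(),
        affine=affine,
        meta={**phantom.meta, "upsampled_by": factor},
    )


def make_microct_phantom(
    phantom: FiberPhantom,
    stripe_period: float = 6.0,
    contrast: float = 100.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    offset: float = 500.0,
    upsample: int = 1,
) -> ScalarVolume:
    """MicroCT-like laminar texture aligned with the phantom fiber field.

    Intensity varies sinusoidally only in the plane perpendicular to the
    local fiber and is invariant along the fiber itself: a strong carrier
    along the lamination normal (alternating myocyte sheets and cleavage
    planes) plus a weaker one along the in-sheet transverse direction
    (myocyte packing), so the structure tensor has two nonzero eigenvalues
    and a unique smallest-eigenvalue eigenvector.  ``stripe_period`` is in
    voxels.  Additive Gaussian noise with standard deviation ``noise_sd``;
    deterministic for a fixed seed.
    """
    if stripe_period < 3:
        raise ValueError("stripe_period must be >= 3 voxels")
    if upsample > 1:
        phantom = upsample_phantom(phantom, upsample)
    shape = phantom.shape
    spacing = phantom.spacing
    idx = np.indices(shape).astype(float)
    coords = np.stack([(idx[a] + 0.5) * spacing[a] for a in range(3)], axis=-1)

    f = phantom.fibers
    zhat = np.broadcast_to(np.array([0.0, 0.0, 1.0]), f.shape)
    n1 = np.cross(f, zhat)
    norms = np.linalg.norm(n1, axis=-1, keepdims=True)
    # fibers parallel to z (the bundle): laminae stacked transmurally
    fallback = np.broadcast_to(np.array([0.0, 1.0, 0.0]), f.shape)
    n1 = np.where(norms > 1e-6,
                  np.divide(n1, norms, out=np.zeros_like(n1), where=norms > 0),
                  fallback)
    n2 = np.cross(f, n1)

    period_mm = stripe_period * float(np.min(spacing))
    phase1 = (coords * n1).sum(-1) / period_mm
    phase2 = (coords * n2).sum(-1) / period_mm
    intensity = offset + contrast * (
        np.sin(2 * np.pi * phase1) + 0.5 * np.sin(2 * np.pi * phase2)
    )
    intensity[~phantom.myocardium] = 0.0
    if noise_sd > 0:
        rng = substream(seed, "phantoms.microct")
        intensity = intensity + rng.normal(0.0, noise_sd, size=shape)
    return ScalarVolume(data=intensity, affine=phantom.affine.copy())
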