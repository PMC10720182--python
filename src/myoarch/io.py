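"""Readers and writers for the standard formats used by the pipeline.

Volumes travel as NIfTI (via nibabel); diffusion data as 4D NIfTI plus
plain-text bval/bvec tables in the FSL dialect (one row per quantity /
axis, one column per volume); tensor fields as 4D NIfTI with six
components in lower-triangular order (Dxx, Dxy, Dyy, Dxz, Dyz, Dzz);
tractograms in TCK format.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np

from .core import MyoarchError, ScalarVolume, SchemeError, TensorField
from .dti import DWIDataset
from .tracto import Tractogram

__all__ = [
    "read_volume", "write_volume",
    "read_dwi", "write_dwi",
    "read_tensor_field", "write_tensor_field",
    "read_tractogram", "write_tractogram",
    "write_fiber_field",
]

_LOWER_TRI = [(0, 0), (0, 1), (1, 1), (0, 2), (1, 2), (2, 2)]


class FormatError(MyoarchError):
    """Malformed file content."""


def read_volume(path) -> ScalarVolume:
    try:
        img = nib.load(str(path))
        data = np.asarray(img.dataobj)
    except Exception as exc:  # noqa: BLE001 - surface nibabel's diagnosis
        raise FormatError(f"cannot read NIfTI volume {path}: {exc}") from exc
    if data.ndim != 3:
        raise FormatError(f"{path}: expected a 3D volume, got shape {data.shape}")
    return ScalarVolume(data=data, affine=np.asarray(img.affine))


def write_volume(vol: ScalarVolume, path, dtype=None) -> None:
    data = vol.data if dtype is None else vol.data.astype(dtype)
    nib.save(nib.Nifti1Image(data, vol.affine), str(path))


def write_fiber_field(fibers: np.ndarray, affine: np.ndarray, path) -> None:
    """3-vector field as a 4D volume, x/y/z components in the 4th dim."""
    nib.save(nib.Nifti1Image(np.asarray(fibers, dtype=np.float32), affine), str(path))


def write_dwi(dwi: DWIDataset, prefix) -> tuple[Path, Path, Path]:
    """Write 4D NIfTI + FSL-dialect .bval/.bvec next to ``prefix``."""
    prefix = Path(prefix)
    nii = prefix.with_suffix(".nii.gz")
    nib.save(nib.Nifti1Image(dwi.data.astype(np.float32), dwi.affine), str(nii))
    bval = prefix.with_suffix(".bval")
    bvec = prefix.with_suffix(".bvec")
    np.savetxt(bval, dwi.bvalues[None, :], fmt="%.6g")
    np.savetxt(bvec, dwi.directions.T, fmt="%.8f")
    return nii, bval, bvec


def read_dwi(nii_path, bval_path, bvec_path) -> DWIDataset:
    try:
        img = nib.load(str(nii_path))
        data = np.asarray(img.dataobj)
    except Exception as exc:  # noqa: BLE001
        raise FormatError(f"cannot read DW NIfTI {nii_path}: {exc}") from exc
    if data.ndim != 4:
        raise FormatError(f"{nii_path}: expected 4D DW data, got shape {data.shape}")
    bvals = np.atleast_1d(np.loadtxt(bval_path).ravel())
    bvecs = np.atleast_2d(np.loadtxt(bvec_path))
    if bvecs.shape[0] != 3:
        raise SchemeError(f"{bvec_path}: expected 3 rows (x/y/z), got {bvecs.shape[0]}")
    if bvecs.shape[1] != data.shape[-1] or bvals.size != data.shape[-1]:
        raise SchemeError(
            f"bval/bvec column count ({bvals.size}/{bvecs.shape[1]}) does not "
            f"match {data.shape[-1]} volumes"
        )
    return DWIDataset(data=data, bvalues=bvals, directions=bvecs.T,
                      affine=np.asarray(img.affine))


def write_tensor_field(tf: TensorField, path) -> None:
    comps = np.stack([tf.tensors[..., i, j] for i, j in _LOWER_TRI], axis=-1)
    nib.save(nib.Nifti1Image(comps.astype(np.float32), tf.affine), str(path))


def read_tensor_field(path, mask=None) -> TensorField:
    try:
        img = nib.load(str(path))
        comps = np.asarray(img.dataobj)
    except Exception as exc:  # noqa: BLE001
        raise FormatError(f"cannot read tensor NIfTI {path}: {exc}") from exc
    if comps.ndim != 4 or comps.shape[-1] != 6:
        raise FormatError(f"{path}: expected 6 tensor components in the 4th dim")
    tens = np.zeros(comps.shape[:3] + (3, 3))
    for k, (i, j) in enumerate(_LOWER_TRI):
        tens[..., i, j] = comps[..., k]
        tens[..., j, i] = comps[..., k]
    if mask is None:
        mask = np.any(comps != 0, axis=-1)
    return TensorField(tensors=tens, mask=mask, affine=np.asarray(img.affine))


def write_tractogram(t: Tractogram, path) -> None:
    sl = [np.asarray(s, dtype=np.float32) for s in t.streamlines]
    tg = nib.streamlines.Tractogram(sl, affine_to_rasmm=np.eye(4))
    nib.streamlines.save(tg, str(path))


def read_tractogram(path) -> Tractogram:
    try:
        tf = nib.streamlines.load(str(path))
    except Exception as exc:  # noqa: BLE001
        raise FormatError(f"cannot read tractogram {path}: {exc}") from exc
    streamlines = [np.asarray(s, dtype=float) for s in tf.streamlines]
    return Tractogram(streamlines=streamlines)
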