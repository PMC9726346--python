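"""NIfTI-1 read/write helpers for phantoms, DWI and derived maps."""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np

from .phantom import DWIVolume
from .scheme import AcquisitionScheme, read_bval_bvec, write_bval_bvec
from .tensorfit import TensorField

__all__ = [
    "save_nifti",
    "load_nifti",
    "save_dwi",
    "load_dwi",
    "save_tensor_field",
    "load_tensor_field",
]


def save_nifti(data: np.ndarray, affine: np.ndarray, path) -> None:
    img = nib.Nifti1Image(np.asarray(data), np.asarray(affine, dtype=float))
    nib.save(img, str(path))


def load_nifti(path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asarray(img.get_fdata()), np.asarray(img.affine)


def save_dwi(dwi: DWIVolume, stem: Path) -> dict[str, str]:
    """Write <stem>.nii.gz plus FSL-style <stem>.bval / <stem>.bvec."""
    stem = Path(stem)
    nii = stem.with_suffix(".nii.gz")
    save_nifti(dwi.data.astype(np.float32), dwi.affine, nii)
    bval, bvec = stem.with_suffix(".bval"), stem.with_suffix(".bvec")
    write_bval_bvec(dwi.scheme, bval, bvec)
    return {"dwi": str(nii), "bval": str(bval), "bvec": str(bvec)}


def load_dwi(nii_path, bval_path, bvec_path) -> DWIVolume:
    data, affine = load_nifti(nii_path)
    scheme = read_bval_bvec(bval_path, bvec_path)
    return DWIVolume(data=data, affine=affine, scheme=scheme)


def save_tensor_field(field: TensorField, out_dir) -> dict[str, str]:
    """Write the 6-component tensor and derived scalar/RGB maps."""
    from .tensorfit import color_fa

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    items = {
        "tensor": field.tensor.astype(np.float32),
        "fa": field.fa.astype(np.float32),
        "md": field.md.astype(np.float32),
        "dxx": field.tensor[..., 0].astype(np.float32),
        "dyy": field.tensor[..., 1].astype(np.float32),
        "dzz": field.tensor[..., 2].astype(np.float32),
        "color_fa": color_fa(field).astype(np.float32),
        "s0": field.s0.astype(np.float32),
        "flags": field.flags.astype(np.uint8),
        "mask": field.mask.astype(np.uint8),
    }
    for name, data in items.items():
        p = out_dir / f"{name}.nii.gz"
        save_nifti(data, field.affine, p)
        paths[name] = str(p)
    return paths


def load_tensor_field(in_dir) -> TensorField:
    """Reconstruct a :class:`TensorField` from a saved map directory.

    The eigensystem is recomputed from the stored tensor components.
    """
    in_dir = Path(in_dir)
    tensor, affine = load_nifti(in_dir / "tensor.nii.gz")
    fa, _ = load_nifti(in_dir / "fa.nii.gz")
    md, _ = load_nifti(in_dir / "md.nii.gz")
    s0, _ = load_nifti(in_dir / "s0.nii.gz")
    flags, _ = load_nifti(in_dir / "flags.nii.gz")
    mask, _ = load_nifti(in_dir / "mask.nii.gz")

    D = np.zeros(tensor.shape[:3] + (3, 3))
    D[..., 0, 0] = tensor[..., 0]
    D[..., 1, 1] = tensor[..., 1]
    D[..., 2, 2] = tensor[..., 2]
    D[..., 0, 1] = D[..., 1, 0] = tensor[..., 3]
    D[..., 0, 2] = D[..., 2, 0] = tensor[..., 4]
    D[..., 1, 2] = D[..., 2, 1] = tensor[..., 5]
    evals_asc, evecs_asc = np.linalg.eigh(D)
    evals = np.clip(evals_asc[..., ::-1], 0.0, None)
    evecs = evecs_asc[..., :, ::-1]
    return TensorField(
        tensor=tensor, evals=evals, evecs=evecs, fa=fa, md=md, s0=s0,
        mask=mask.astype(bool), flags=flags.astype(bool), affine=affine,
    )
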