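"""NIfTI, bval/bvec, config and table I/O for the pipeline."""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from .alps import AlpsRoiSpec
from .forward import DWIVolume
from .scheme import AcquisitionScheme, read_bval_bvec, write_bval_bvec

__all__ = ["read_nifti", "write_nifti", "write_dwi", "read_dwi",
           "load_roi_spec", "save_roi_spec", "load_config", "save_config"]


def write_nifti(volume: np.ndarray, path, *, voxel_size_mm: float = 2.0,
                affine: np.ndarray | None = None) -> None:
    """Write an array as NIfTI-1, default affine = diag(voxel size)."""
    if affine is None:
        affine = np.diag([voxel_size_mm] * 3 + [1.0])
    img = nib.Nifti1Image(np.asarray(volume), affine)
    nib.save(img, str(path))


def read_nifti(path):
    """Return (data, affine); dtype is preserved as stored."""
    img = nib.load(str(path))
    return np.asarray(img.dataobj), img.affine


def write_dwi(dwi: DWIVolume, out_dir, stem: str = "dwi", *,
              voxel_size_mm: float = 2.0) -> dict:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {"nifti": out_dir / f"{stem}.nii",
             "bval": out_dir / f"{stem}.bval",
             "bvec": out_dir / f"{stem}.bvec"}
    write_nifti(dwi.signal, paths["nifti"], voxel_size_mm=voxel_size_mm)
    write_bval_bvec(dwi.scheme, paths["bval"], paths["bvec"])
    return paths


def read_dwi(nifti_path, bval_path, bvec_path) -> DWIVolume:
    """Read a 4-D DWI and its sidecars, checking volume counts agree."""
    data, _ = read_nifti(nifti_path)
    scheme = read_bval_bvec(bval_path, bvec_path)
    if data.ndim != 4:
        raise ValueError(f"expected a 4-D DWI, got shape {data.shape}")
    if data.shape[-1] != scheme.n_volumes:
        raise ValueError(
            f"DWI has {data.shape[-1]} volumes but sidecars describe "
            f"{scheme.n_volumes}")
    return DWIVolume(signal=np.asarray(data, float), scheme=scheme,
                     s0=float(np.max(data, initial=0.0)), noise_sigma=0.0)


def save_roi_spec(roi: AlpsRoiSpec, path) -> None:
    doc = {"units": "voxel", "edge_mm": roi.edge_mm,
           "voxel_size_mm": roi.voxel_size_mm, "hemisphere": roi.hemisphere,
           "proj_center": list(map(int, roi.proj_center)),
           "assoc_center": list(map(int, roi.assoc_center))}
    Path(path).write_text(yaml.safe_dump(doc))


def load_roi_spec(path) -> AlpsRoiSpec:
    doc = yaml.safe_load(Path(path).read_text())
    units = doc.get("units", "voxel")
    vox = float(doc.get("voxel_size_mm", 2.0))
    proj = doc["proj_center"]
    assoc = doc["assoc_center"]
    if units == "mm":
        proj = [round(c / vox) for c in proj]
        assoc = [round(c / vox) for c in assoc]
    elif units != "voxel":
        raise ValueError(f"ROI units must be 'voxel' or 'mm', got {units!r}")
    return AlpsRoiSpec(proj_center=tuple(int(c) for c in proj),
                       assoc_center=tuple(int(c) for c in assoc),
                       edge_mm=float(doc.get("edge_mm", 3.0)),
                       voxel_size_mm=vox,
                       hemisphere=doc.get("hemisphere", "left"))


def save_config(config: dict, path) -> None:
    Path(path).write_text(yaml.safe_dump(config, sort_keys=False))


def load_config(path) -> dict:
    return yaml.safe_load(Path(path).read_text())
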