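"""Diffusion-along-the-perivascular-space (ALPS) index.

At the level of the lateral-ventricle body, projection fibers run
inferior–superior (z) and association fibers anterior–posterior (y), while
the perivascular space runs left–right (x), perpendicular to both.  Water
movement along the perivascular space therefore shows up as x-axis
diffusivity in both fiber areas, and the index

    ALPS = mean(Dxx_proj, Dxx_assoc) / mean(Dyy_proj, Dzz_assoc)

isolates it from the fiber-parallel diffusivities.  A higher index indicates
better glymphatic function.  ROI placement is supplied by configuration in a
common space (cubical ROIs, left hemisphere = lower x-index half).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tensorfit import TensorField

__all__ = ["AlpsRoiSpec", "AlpsResult", "axis_diffusivities", "alps_index",
           "alps_subject", "alps_cohort"]


def _edge_voxels(edge_mm: float, voxel_size_mm: float) -> int:
    """Odd voxel count whose physical extent is closest to ``edge_mm``.

    A 3 mm cube at 2 mm spacing rounds to a single voxel: candidate odd
    counts n have extent n·voxel_size, and 1 voxel (2 mm) is nearer 3 mm
    than 3 voxels (6 mm).
    """
    if edge_mm <= 0:
        raise ValueError("edge_mm must be positive")
    candidates = np.arange(1, 2 * int(np.ceil(edge_mm / voxel_size_mm)) + 2, 2)
    return int(candidates[np.argmin(np.abs(candidates * voxel_size_mm - edge_mm))])


@dataclass(frozen=True)
class AlpsRoiSpec:
    """Two cubical ROIs (projection- and association-fiber areas)."""

    proj_center: tuple          # voxel indices (x, y, z)
    assoc_center: tuple
    edge_mm: float = 3.0
    voxel_size_mm: float = 2.0
    hemisphere: str = "left"

    def roi_slices(self, which: str):
        center = self.proj_center if which == "proj" else self.assoc_center
        half = _edge_voxels(self.edge_mm, self.voxel_size_mm) // 2
        return tuple(slice(int(c) - half, int(c) + half + 1) for c in center)

    def roi_mask(self, which: str, grid_shape) -> np.ndarray:
        sl = self.roi_slices(which)
        for s, n in zip(sl, grid_shape):
            if s.start < 0 or s.stop > n:
                raise ValueError(
                    f"ROI '{which}' {sl} does not fit inside grid {grid_shape}")
        m = np.zeros(grid_shape, dtype=bool)
        m[sl] = True
        return m


@dataclass
class AlpsResult:
    d_x_proj: float
    d_x_assoc: float
    d_y_proj: float
    d_z_assoc: float
    index: float


def axis_diffusivities(tensor_field: TensorField, roi_mask: np.ndarray):
    """Mean (Dxx, Dyy, Dzz) over the ROI; Daa = eₐᵀ·D·eₐ per voxel.

    Image axes are used directly (x = left–right).  ROI voxels falling
    outside the tensor field's fitted mask are an error.
    """
    roi_mask = np.asarray(roi_mask, bool)
    if roi_mask.shape != tensor_field.fa_map.shape:
        raise ValueError("ROI mask shape does not match tensor field")
    outside = roi_mask & ~tensor_field.mask
    if np.any(outside):
        vox = [tuple(int(c) for c in v) for v in np.argwhere(outside)[:10]]
        raise ValueError(
            f"ROI overlaps {int(outside.sum())} unfitted voxels, e.g. {vox}")
    t = tensor_field.tensors[roi_mask]
    return tuple(float(t[:, a, a].mean()) for a in range(3))


def alps_index(d_x_proj: float, d_x_assoc: float, d_y_proj: float,
               d_z_assoc: float) -> float:
    """mean(Dxproj, Dxassoc) / mean(Dyproj, Dzassoc); all inputs > 0."""
    vals = (d_x_proj, d_x_assoc, d_y_proj, d_z_assoc)
    if any(v <= 0 for v in vals):
        raise ValueError(
            f"axis diffusivities must be positive (got {vals}); "
            "a non-positive value signals an invalid tensor fit")
    return (d_x_proj + d_x_assoc) / (d_y_proj + d_z_assoc)


def alps_subject(tensor_field: TensorField, roi: AlpsRoiSpec) -> AlpsResult:
    grid = tensor_field.fa_map.shape
    dxx_p, dyy_p, _ = axis_diffusivities(tensor_field, roi.roi_mask("proj", grid))
    dxx_a, _, dzz_a = axis_diffusivities(tensor_field, roi.roi_mask("assoc", grid))
    return AlpsResult(
        d_x_proj=dxx_p, d_x_assoc=dxx_a, d_y_proj=dyy_p, d_z_assoc=dzz_a,
        index=alps_index(dxx_p, dxx_a, dyy_p, dzz_a))


def alps_cohort(subject_tensor_fields: dict, roi: AlpsRoiSpec) -> pd.DataFrame:
    """Per-subject ALPS table under one common-space ROI spec.

    ``subject_tensor_fields`` maps subject id -> TensorField.  Subjects whose
    fit fails inside the ROIs are excluded and listed in the ``error``
    column, never silently dropped.
    """
    rows = []
    for sid, tf in subject_tensor_fields.items():
        try:
            r = alps_subject(tf, roi)
            rows.append(dict(subject=sid, d_x_proj=r.d_x_proj,
                             d_x_assoc=r.d_x_assoc, d_y_proj=r.d_y_proj,
                             d_z_assoc=r.d_z_assoc, alps_index=r.index,
                             error=""))
        except ValueError as exc:
            rows.append(dict(subject=sid, d_x_proj=np.nan, d_x_assoc=np.nan,
                             d_y_proj=np.nan, d_z_assoc=np.nan,
                             alps_index=np.nan, error=str(exc)))
    return pd.DataFrame(rows)
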