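"""Multi-shell acquisition schemes and FSL-style bval/bvec text I/O."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["AcquisitionScheme", "default_scheme", "sphere_directions",
           "read_bval_bvec", "write_bval_bvec"]

_UNIT_TOL = 1e-8


@dataclass(frozen=True)
class AcquisitionScheme:
    """b-values and unit gradient directions, one entry per volume.

    ``bvals`` has one entry per volume (including b = 0 volumes); ``bvecs``
    is (n_volumes, 3) with zero rows exactly where b = 0 and unit rows
    elsewhere.  b-values are in s/mm².
    """

    bvals: np.ndarray
    bvecs: np.ndarray

    def __post_init__(self):
        bvals = np.asarray(self.bvals, dtype=float).ravel()
        bvecs = np.asarray(self.bvecs, dtype=float)
        if bvecs.shape != (bvals.size, 3):
            raise ValueError(
                f"bvecs shape {bvecs.shape} does not match {bvals.size} volumes"
            )
        if np.any(bvals < 0):
            raise ValueError("b-values must be non-negative")
        norms = np.linalg.norm(bvecs, axis=1)
        weighted = bvals > 0
        if np.any(np.abs(norms[weighted] - 1.0) > _UNIT_TOL):
            raise ValueError("weighted-volume directions must have unit norm")
        if np.any(norms[weighted] == 0):
            raise ValueError("nonzero b-value with zero direction vector")
        object.__setattr__(self, "bvals", bvals)
        object.__setattr__(self, "bvecs", bvecs)

    @property
    def n_volumes(self) -> int:
        return self.bvals.size

    @property
    def n_b0(self) -> int:
        return int(np.sum(self.bvals == 0))

    @property
    def shells(self) -> np.ndarray:
        """Sorted unique nonzero b-values."""
        return np.unique(self.bvals[self.bvals > 0])

    def subset(self, mask: np.ndarray) -> "AcquisitionScheme":
        mask = np.asarray(mask, dtype=bool)
        return AcquisitionScheme(self.bvals[mask], self.bvecs[mask])


def sphere_directions(n: int, seed: int = 0, n_iter: int = 200) -> np.ndarray:
    """`n` roughly uniformly spread unit vectors (electrostatic repulsion).

    Deterministic given ``seed``; antipodal symmetry is respected by
    repelling both a point and its antipode, as gradient tables require.
    """
    rng = np.random.default_rng(seed)
    v = rng.standard_normal((n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    step = 0.1
    for _ in range(n_iter):
        force = np.zeros_like(v)
        for sign in (1.0, -1.0):
            diff = v[:, None, :] - sign * v[None, :, :]
            d2 = np.maximum(np.sum(diff**2, axis=-1), 1e-4)
            if sign > 0:
                np.fill_diagonal(d2, np.inf)
            force += np.sum(diff / d2[..., None] ** 1.5, axis=1)
        norm = np.linalg.norm(force, axis=1, keepdims=True)
        force /= np.maximum(norm, 1.0)
        v += step * force
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        step *= 0.97
    return v


def default_scheme(seed: int = 0) -> AcquisitionScheme:
    """The study protocol: 10 b = 0 volumes plus shells at b = 700, 1000 and
    2855 s/mm² along 6, 30 and 60 non-collinear directions (106 volumes)."""
    parts_b, parts_v = [np.zeros(10)], [np.zeros((10, 3))]
    for i, (b, nd) in enumerate([(700.0, 6), (1000.0, 30), (2855.0, 60)]):
        parts_b.append(np.full(nd, b))
        parts_v.append(sphere_directions(nd, seed=seed + i))
    return AcquisitionScheme(np.concatenate(parts_b), np.vstack(parts_v))


def read_bval_bvec(bval_path, bvec_path, *, renorm_warn_tol: float = 1e-3
                   ) -> AcquisitionScheme:
    """Read FSL-dialect files: bvals as one whitespace row, bvecs as 3 rows.

    Directions are renormalized to unit length; deviations beyond
    ``renorm_warn_tol`` trigger a warning.  A zero vector paired with a
    nonzero b-value is rejected.
    """
    import warnings

    bvals = np.loadtxt(bval_path, ndmin=2).ravel()
    bvecs = np.loadtxt(bvec_path, ndmin=2)
    if bvecs.shape[0] != 3:
        raise ValueError(
            f"bvec file must have exactly 3 rows (got {bvecs.shape[0]})"
        )
    bvecs = bvecs.T
    if bvecs.shape[0] != bvals.size:
        raise ValueError(
            f"bvec column count {bvecs.shape[0]} != bval count {bvals.size}"
        )
    norms = np.linalg.norm(bvecs, axis=1)
    weighted = bvals > 0
    if np.any(norms[weighted] == 0):
        bad = int(np.flatnonzero(weighted & (norms == 0))[0])
        raise ValueError(f"volume {bad}: nonzero b-value with zero direction")
    if np.any(np.abs(norms[weighted] - 1.0) > renorm_warn_tol):
        warnings.warn("renormalizing gradient directions deviating from unit "
                      "norm by more than %g" % renorm_warn_tol, stacklevel=2)
    out = bvecs.copy()
    out[weighted] = bvecs[weighted] / norms[weighted, None]
    out[~weighted] = 0.0
    return AcquisitionScheme(bvals, out)


def write_bval_bvec(scheme: AcquisitionScheme, bval_path, bvec_path) -> None:
    Path(bval_path).write_text(
        " ".join(f"{b:g}" for b in scheme.bvals) + "\n")
    rows = [" ".join(f"{x:.10f}" for x in scheme.bvecs[:, ax])
            for ax in range(3)]
    Path(bvec_path).write_text("\n".join(rows) + "\n")
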