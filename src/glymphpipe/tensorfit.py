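"""Log-linear least-squares diffusion tensor estimation on the low-b shell."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .forward import DWIVolume
from .scheme import AcquisitionScheme

__all__ = ["TensorField", "fit_tensor_lls", "fa_from_eigenvalues"]

log = logging.getLogger(__name__)


def fa_from_eigenvalues(evals: np.ndarray) -> np.ndarray:
    """Fractional anisotropy sqrt(3/2)·‖λ − λ̄‖/‖λ‖ (0 where ‖λ‖ = 0)."""
    evals = np.asarray(evals, float)
    dev = evals - evals.mean(axis=-1, keepdims=True)
    num = np.linalg.norm(dev, axis=-1)
    den = np.linalg.norm(evals, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5) * num / den
    return np.clip(np.nan_to_num(fa), 0.0, 1.0)


@dataclass
class TensorField:
    """Per-voxel diffusion tensors with eigen-decomposition and FA.

    Eigenvalues are sorted descending (λ1 ≥ λ2 ≥ λ3); ``evecs[..., :, k]``
    is the unit eigenvector of λ_{k+1}.
    """

    tensors: np.ndarray      # (X, Y, Z, 3, 3), mm²/s
    evals: np.ndarray        # (X, Y, Z, 3), descending
    evecs: np.ndarray        # (X, Y, Z, 3, 3), columns matching evals
    fa_map: np.ndarray
    mask: np.ndarray         # voxels actually fitted
    n_clipped: int           # voxels with negative eigenvalues clipped to 0

    @property
    def color_fa(self) -> np.ndarray:
        """RGB = FA·|v1|: red = x (left–right), green = y, blue = z."""
        return self.fa_map[..., None] * np.abs(self.evecs[..., :, 0])


def _design_matrix(bvals: np.ndarray, bvecs: np.ndarray) -> np.ndarray:
    g = bvecs
    cols = [np.ones_like(bvals),
            -bvals * g[:, 0] ** 2, -bvals * g[:, 1] ** 2, -bvals * g[:, 2] ** 2,
            -2 * bvals * g[:, 0] * g[:, 1],
            -2 * bvals * g[:, 0] * g[:, 2],
            -2 * bvals * g[:, 1] * g[:, 2]]
    return np.column_stack(cols)


def fit_tensor_lls(dwi, scheme: AcquisitionScheme | None = None, *,
                   max_b: float = 1000.0, include_max_b: bool = False,
                   mask: np.ndarray | None = None) -> TensorField:
    """Fit per-voxel tensors by linear regression on log-signal.

    Only volumes with b < ``max_b`` (or ≤ when ``include_max_b``) plus all
    b = 0 volumes are used; the default reproduces a strict low-b-shell fit
    that keeps 6 directions on the 700/1000/2855 protocol, and the inclusive
    switch keeps 36.  Voxels with any non-positive signal on the retained
    volumes are excluded from the fit.  Negative eigenvalues are clipped to
    zero and the affected voxel count is logged.
    """
    if isinstance(dwi, DWIVolume):
        signal = dwi.signal
        scheme = scheme or dwi.scheme
    else:
        signal = np.asarray(dwi, float)
        if scheme is None:
            raise ValueError("scheme required when dwi is a bare array")

    keep = (scheme.bvals == 0) | (
        scheme.bvals <= max_b if include_max_b else scheme.bvals < max_b)
    sub = scheme.subset(keep)
    n_dirs = np.unique(np.round(sub.bvecs[sub.bvals > 0], 6), axis=0).shape[0]
    if n_dirs < 6 or sub.n_b0 < 1:
        raise ValueError(
            f"shell filter b {'<=' if include_max_b else '<'} {max_b:g} leaves "
            f"{n_dirs} distinct directions and {sub.n_b0} b=0 volumes; need "
            "at least 6 directions and one b=0 volume")

    sig = signal[..., keep]
    shape = sig.shape[:-1]
    fit_mask = np.all(sig > 0, axis=-1)
    if mask is not None:
        fit_mask &= np.asarray(mask, bool)

    design = _design_matrix(sub.bvals, sub.bvecs)
    y = np.log(sig[fit_mask])                         # (V, M)
    coef, *_ = np.linalg.lstsq(design, y.T, rcond=None)
    d6 = coef[1:].T                                   # (V, 6)

    tensors = np.zeros(shape + (3, 3))
    t = np.empty((d6.shape[0], 3, 3))
    t[:, 0, 0], t[:, 1, 1], t[:, 2, 2] = d6[:, 0], d6[:, 1], d6[:, 2]
    t[:, 0, 1] = t[:, 1, 0] = d6[:, 3]
    t[:, 0, 2] = t[:, 2, 0] = d6[:, 4]
    t[:, 1, 2] = t[:, 2, 1] = d6[:, 5]
    tensors[fit_mask] = t

    w, v = np.linalg.eigh(t)                          # ascending
    w = w[:, ::-1]
    v = v[:, :, ::-1]
    n_clipped = int(np.sum(np.any(w < 0, axis=-1)))
    if n_clipped:
        log.info("clipped negative eigenvalues in %d voxels", n_clipped)
    w = np.clip(w, 0.0, None)

    evals = np.zeros(shape + (3,))
    evecs = np.zeros(shape + (3, 3))
    evals[fit_mask] = w
    evecs[fit_mask] = v
    fa = np.zeros(shape)
    fa[fit_mask] = fa_from_eigenvalues(w)

    return TensorField(tensors=tensors, evals=evals, evecs=evecs, fa_map=fa,
                       mask=fit_mask, n_clipped=n_clipped)
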