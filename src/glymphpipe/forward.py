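"""Forward simulation of multi-shell diffusion signals from phantom truth.

Tissue voxels follow the three-compartment neurite model

    S/S0 = (1 − iso)·[icvf·S_intra + (1 − icvf)·S_extra] + iso·exp(−b·d_iso)

with Watson-dispersed sticks for the intra-neurite compartment, a
tortuosity-scaled axially-symmetric tensor (d_perp = d_par·(1 − icvf)) for
the extra-neurite compartment, and free water for CSF.  Compartment
diffusivities are fixed at the conventional d_par = 1.7e-3 mm²/s and
d_iso = 3.0e-3 mm²/s.

Periventricular (ALPS) voxels instead use a Gaussian tensor signal whose
x-axis diffusivity is multiplied by the phantom's perivascular gain — the
quantity the ALPS index is built to read out lives at the tensor level, not
inside the neurite model.

Noise is Rician: two independent Gaussian channels of scale ``noise_sigma``,
magnitude taken.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from .phantom import Label, PhantomTruth
from .scheme import AcquisitionScheme
from .watson import kappa_from_odi, watson_stick_signal, watson_tau

__all__ = ["D_PAR", "D_ISO", "DWIVolume", "noddi_signal", "synthesize_dwi",
           "synthesize_subject_maps"]

D_PAR = 1.7e-3   # intrinsic parallel diffusivity, mm²/s
D_ISO = 3.0e-3   # free-water diffusivity, mm²/s

# nominal FA of each tissue class for map-level simulation
_FA_TRUTH = {
    Label.BACKGROUND: 0.0, Label.CSF: 0.02, Label.GM: 0.15,
    Label.WM_TRACT_1: 0.80, Label.WM_TRACT_2: 0.80, Label.WM_CROSSING: 0.55,
    Label.PV_PROJECTION: 0.60, Label.PV_ASSOCIATION: 0.60,
}


@dataclass
class DWIVolume:
    """4-D diffusion-weighted signal plus its acquisition scheme."""

    signal: np.ndarray          # (X, Y, Z, n_volumes)
    scheme: AcquisitionScheme
    s0: float
    noise_sigma: float

    def __post_init__(self):
        if self.signal.shape[-1] != self.scheme.n_volumes:
            raise ValueError(
                f"signal has {self.signal.shape[-1]} volumes, scheme has "
                f"{self.scheme.n_volumes}")


def noddi_signal(bvals, bvecs, icvf, odi, iso, mu,
                 d_par: float = D_PAR, d_iso: float = D_ISO) -> np.ndarray:
    """Noiseless normalized (S/S0) three-compartment signal.

    ``icvf, odi, iso`` are (V,) arrays, ``mu`` is (V, 3) unit mean axes (or
    (V, 2, 3) for two-fiber voxels, zero second row meaning absent; the
    anisotropic part is averaged over the fibers present).  Returns (V, M).
    """
    bvals = np.asarray(bvals, float)
    bvecs = np.asarray(bvecs, float)
    icvf = np.atleast_1d(np.asarray(icvf, float))
    odi = np.atleast_1d(np.asarray(odi, float))
    iso = np.atleast_1d(np.asarray(iso, float))
    mu = np.asarray(mu, float)
    if mu.ndim == 2:
        mu = mu[:, None, :]
    for name, arr in (("icvf", icvf), ("odi", odi), ("iso", iso)):
        if np.any(arr < 0) or np.any(arr > 1):
            raise ValueError(f"{name} must lie in [0, 1]")

    kappa = np.asarray(kappa_from_odi(odi))
    tau = np.atleast_1d(watson_tau(kappa))
    d_perp = d_par * (1.0 - icvf)
    de_par = d_perp + (d_par - d_perp) * tau
    de_perp = d_perp + (d_par - d_perp) * (1.0 - tau) / 2.0

    aniso = np.zeros((icvf.size, bvals.size))
    n_fib = np.zeros(icvf.size)
    for f in range(mu.shape[1]):
        mu_f = mu[:, f, :]
        present = np.linalg.norm(mu_f, axis=1) > 0
        if not np.any(present):
            continue
        cos_psi = mu_f @ bvecs.T                                   # (V, M)
        a_intra = watson_stick_signal(
            kappa[:, None], bvals[None, :] * d_par, cos_psi)
        a_extra = np.exp(-bvals[None, :] * (
            de_perp[:, None] + (de_par - de_perp)[:, None] * cos_psi**2))
        contrib = icvf[:, None] * a_intra + (1 - icvf)[:, None] * a_extra
        aniso[present] += contrib[present]
        n_fib += present
    n_fib = np.maximum(n_fib, 1)
    aniso /= n_fib[:, None]

    s_iso = np.exp(-bvals[None, :] * d_iso)
    return (1 - iso)[:, None] * aniso + iso[:, None] * s_iso


def _tensor_signal(bvals, bvecs, tensors) -> np.ndarray:
    """exp(−b gᵀDg) for per-voxel tensors (V, 3, 3) → (V, M)."""
    quad = np.einsum("mi,vij,mj->vm", bvecs, tensors, bvecs)
    return np.exp(-bvals[None, :] * quad)


def synthesize_dwi(truth: PhantomTruth, scheme: AcquisitionScheme,
                   s0: float = 1000.0, noise_sigma: float = 0.0,
                   seed: int = 0) -> DWIVolume:
    """Forward-simulate the phantom's 4-D DWI signal under ``scheme``.

    Voxels are grouped by their (piecewise-constant) parameter rows so the
    sphere quadrature runs once per distinct tissue configuration.
    Deterministic given ``seed``.
    """
    if s0 <= 0:
        raise ValueError("s0 must be positive")
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be >= 0")

    shape = truth.grid_shape
    bvals, bvecs = scheme.bvals, scheme.bvecs
    signal = np.zeros(shape + (scheme.n_volumes,))

    flat_labels = truth.label_map.ravel()
    tissue = flat_labels != Label.BACKGROUND
    rows = np.column_stack([
        truth.icvf_map.ravel(), truth.odi_map.ravel(), truth.iso_map.ravel(),
        truth.orientation_field.reshape(-1, 6),
        flat_labels.astype(float),
    ])[tissue]
    uniq, inverse = np.unique(rows, axis=0, return_inverse=True)

    flat_sig = np.zeros((tissue.sum(), scheme.n_volumes))
    pv_labels = (int(Label.PV_PROJECTION), int(Label.PV_ASSOCIATION))
    for g in range(uniq.shape[0]):
        icvf, odi, iso = uniq[g, :3]
        mu = uniq[g, 3:9].reshape(2, 3)
        lab = int(uniq[g, 9])
        if lab in pv_labels:
            d_perp = D_PAR * (1.0 - icvf)
            d_mat = d_perp * np.eye(3) + (D_PAR - d_perp) * np.outer(mu[0], mu[0])
            d_mat[0, 0] *= truth.perivascular_gain
            aniso = _tensor_signal(bvals, bvecs, d_mat[None])[0]
            s_norm = (1 - iso) * aniso + iso * np.exp(-bvals * D_ISO)
        else:
            s_norm = noddi_signal(bvals, bvecs, [icvf], [odi], [iso],
                                  mu[None])[0]
        flat_sig[inverse == g] = s_norm

    signal.reshape(-1, scheme.n_volumes)[tissue] = s0 * flat_sig

    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        re = signal + rng.normal(0, noise_sigma, signal.shape)
        im = rng.normal(0, noise_sigma, signal.shape)
        signal = np.hypot(re, im)

    return DWIVolume(signal=signal, scheme=scheme, s0=float(s0),
                     noise_sigma=float(noise_sigma))


def synthesize_subject_maps(truth: PhantomTruth, *, fa_noise: float = 0.02,
                            metric_noise: float = 0.02,
                            smooth_sigma_vox: float = 1.0,
                            seed: int = 0) -> dict:
    """Map-level simulation of one registered subject.

    Emulates the per-subject scalar maps a fitted-and-registered real study
    works with (FA, ICVF, ODI, ISO, GM probability) without simulating and
    refitting the full 4-D signal — the mode used for group-level skeleton
    studies where only map-space structure matters.  Smoothing gives tracts
    a ridge profile (maximal on the centerline) and noise is additive
    Gaussian in map space, clipped to [0, 1].
    """
    rng = np.random.default_rng(seed)
    fa = np.zeros(truth.grid_shape)
    for lab, v in _FA_TRUTH.items():
        fa[truth.label_map == lab] = v
    out = {}
    for name, base, sig in (
        ("fa", fa, fa_noise),
        ("icvf", truth.icvf_map, metric_noise),
        ("odi", truth.odi_map, metric_noise),
        ("iso", truth.iso_map, metric_noise),
        ("gm_prob", truth.gm_probability(), metric_noise),
    ):
        m = gaussian_filter(base, smooth_sigma_vox) if smooth_sigma_vox else base
        m = m + rng.normal(0, sig, m.shape) if sig > 0 else m.copy()
        out[name] = np.clip(m, 0.0, 1.0)
    return out
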