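"""Group-level inference: TFCE permutation testing, covariate-adjusted ROI
comparisons with Bonferroni correction, and partial correlations.

Voxelwise inference follows the nonparametric max-statistic recipe: the
group-contrast t-map is enhanced by threshold-free cluster enhancement
(TFCE), covariates are handled with the Freedman–Lane scheme (fit the
reduced model, permute its residuals, refit the full model), and the
family-wise-error p-value of each voxel is the fraction of permutations
whose maximum enhanced statistic reaches the observed value.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats as sps

__all__ = ["TfceParams", "DesignSpec", "tfce", "permutation_inference",
           "roi_summary", "adjusted_group_comparison", "partial_correlation"]


@dataclass(frozen=True)
class TfceParams:
    """TFCE settings: enhanced(v) = Σ_h e(h,v)^E · h^H · dh.

    ``dh = None`` uses max(stat)/n_steps per map, the conventional adaptive
    step.  Connectivity 26 (full 3×3×3 neighborhood) or 6 (faces).
    """

    e: float = 0.5
    h: float = 2.0
    dh: float | None = None
    n_steps: int = 100
    connectivity: int = 26

    def __post_init__(self):
        if self.e <= 0 or self.h <= 0 or (self.dh is not None and self.dh <= 0):
            raise ValueError("E, H and dh must be positive")
        if self.connectivity not in (6, 26):
            raise ValueError("connectivity must be 6 or 26")

    @property
    def structure(self) -> np.ndarray:
        return (np.ones((3, 3, 3), bool) if self.connectivity == 26
                else ndimage.generate_binary_structure(3, 1))


def _tfce_one_sided(stat: np.ndarray, params: TfceParams) -> np.ndarray:
    """Enhance the non-negative part of ``stat``."""
    peak = float(stat.max(initial=0.0))
    if peak <= 0:
        return np.zeros_like(stat)
    dh = params.dh if params.dh is not None else peak / params.n_steps
    out = np.zeros_like(stat)
    structure = params.structure
    # thresholds k·dh ≤ stat(v); the tiny slack keeps a voxel sitting exactly
    # on a threshold inside it despite float rounding of k·dh
    n_thr = int(np.floor(peak / dh + 1e-9))
    for k in range(1, n_thr + 1):
        h = k * dh
        supra = stat >= h - 1e-12
        if not supra.any():
            break
        labels, n = ndimage.label(supra, structure=structure)
        if n:
            sizes = np.bincount(labels.ravel())
            contrib = sizes ** params.e * h ** params.h * dh
            contrib[0] = 0.0
            out += contrib[labels]
    return out


def tfce(stat_map: np.ndarray, params: TfceParams | None = None) -> np.ndarray:
    """Threshold-free cluster enhancement of a 3-D statistic map.

    Negative values are enhanced separately on the negated map and returned
    with their sign, so the output is an odd function of the input.
    """
    params = params or TfceParams()
    stat = np.asarray(stat_map, float)
    if not np.isfinite(stat).all():
        raise ValueError("stat_map contains non-finite values")
    return (_tfce_one_sided(np.maximum(stat, 0.0), params)
            - _tfce_one_sided(np.maximum(-stat, 0.0), params))


@dataclass
class DesignSpec:
    """Two-group design with optional covariates.

    ``group`` is a 0/1 indicator per subject; ``contrast`` +1 tests
    group 1 > group 0, −1 the reverse.  Covariates (n, k) must be complete.
    """

    group: np.ndarray
    covariates: np.ndarray | None = None
    contrast: int = 1

    def __post_init__(self):
        self.group = np.asarray(self.group, float).ravel()
        u = np.unique(self.group)
        if not np.all(np.isin(u, [0.0, 1.0])) or u.size != 2:
            raise ValueError("group must contain both levels, coded 0/1")
        if self.covariates is not None:
            self.covariates = np.atleast_2d(np.asarray(self.covariates, float))
            if self.covariates.shape[0] != self.group.size:
                self.covariates = self.covariates.T
            if self.covariates.shape[0] != self.group.size:
                raise ValueError("covariate rows must match subjects")
            if not np.isfinite(self.covariates).all():
                raise ValueError("covariates must be complete (finite)")
        if self.contrast not in (1, -1):
            raise ValueError("contrast must be +1 or -1")

    @property
    def n(self) -> int:
        return self.group.size

    def reduced_matrix(self) -> np.ndarray:
        cols = [np.ones(self.n)]
        if self.covariates is not None:
            cols.append(self.covariates)
        return np.column_stack(cols)

    def full_matrix(self) -> np.ndarray:
        return np.column_stack([self.reduced_matrix(), self.group])


def _t_map(x: np.ndarray, y: np.ndarray, contrast_col: int,
           pinv_x: np.ndarray, xtx_inv_cc: float) -> np.ndarray:
    """t-statistics of one design column for many outcomes (columns of y)."""
    beta = pinv_x @ y
    resid = y - x @ beta
    dof = x.shape[0] - x.shape[1]
    sigma2 = np.sum(resid**2, axis=0) / dof
    with np.errstate(invalid="ignore", divide="ignore"):
        t = beta[contrast_col] / np.sqrt(sigma2 * xtx_inv_cc)
    return np.nan_to_num(t)


def permutation_inference(values: np.ndarray, design: DesignSpec, *,
                          grid_shape, voxel_index: np.ndarray,
                          tfce_params: TfceParams | None = None,
                          n_perm: int = 5000, seed: int = 0) -> dict:
    """Voxelwise FWER inference on skeleton data by permutation + TFCE.

    ``values`` is (n_subjects, V) over the skeleton voxels listed in
    ``voxel_index`` ((V, 3) indices into ``grid_shape``), so connectivity is
    evaluated in the native 3-D grid.  Covariates are removed with the
    Freedman–Lane scheme; the null distribution is the per-permutation
    maximum of the one-sided (per ``design.contrast``) enhanced t-map.  If
    the exact number of residual permutations is below ``n_perm``, they are
    enumerated exhaustively.  Deterministic given ``seed``.

    Returns dict with ``t`` (V,), ``enhanced`` (V,), ``p_fwe`` (V,),
    ``max_null`` (n_perm,), and ``n_perm``.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    tfce_params = tfce_params or TfceParams()
    y = np.asarray(values, float)
    if y.shape[0] != design.n:
        raise ValueError("values rows must match design subjects")
    voxel_index = np.asarray(voxel_index, int)

    x_red = design.reduced_matrix()
    x_full = design.full_matrix()
    # confounded design: the group column must not lie in the covariate span
    g_resid = design.group - x_red @ np.linalg.lstsq(
        x_red, design.group, rcond=None)[0]
    if np.linalg.norm(g_resid) < 1e-10 * max(1.0, np.linalg.norm(design.group)):
        raise ValueError("group indicator lies in the covariate span; "
                         "the design is confounded")

    pinv_full = np.linalg.pinv(x_full)
    c = x_full.shape[1] - 1
    xtx_inv_cc = np.linalg.inv(x_full.T @ x_full)[c, c]

    hat_red = x_red @ np.linalg.pinv(x_red)
    y_hat = hat_red @ y
    resid = y - y_hat

    def enhanced_map(t_signed: np.ndarray) -> np.ndarray:
        grid = np.zeros(grid_shape)
        grid[tuple(voxel_index.T)] = np.maximum(
            design.contrast * t_signed, 0.0)
        enh = _tfce_one_sided(grid, tfce_params)
        return enh[tuple(voxel_index.T)]

    t_obs = _t_map(x_full, y, c, pinv_full, xtx_inv_cc)
    enh_obs = enhanced_map(t_obs)

    n = design.n
    exact = math.factorial(n) <= n_perm
    if exact:
        perms = np.array(list(itertools.permutations(range(n))))
    else:
        rng = np.random.default_rng(seed)
        perms = np.array([rng.permutation(n) for _ in range(n_perm)])

    max_null = np.empty(len(perms))
    for i, p in enumerate(perms):
        y_star = y_hat + resid[p]
        t_star = _t_map(x_full, y_star, c, pinv_full, xtx_inv_cc)
        max_null[i] = enhanced_map(t_star).max(initial=0.0)

    n_eff = len(perms)
    exceed = (max_null[None, :] >= enh_obs[:, None]).sum(axis=1)
    p_fwe = (1.0 + exceed) / (n_eff + 1.0)
    return {"t": t_obs, "enhanced": enh_obs, "p_fwe": p_fwe,
            "max_null": max_null, "n_perm": n_eff, "exact": exact}


def roi_summary(projected_values: np.ndarray, region_labels: np.ndarray,
                subject_ids=None) -> pd.DataFrame:
    """Per-subject, per-region mean of skeleton-projected values.

    ``projected_values`` is (S, V); ``region_labels`` (V,) with 0 meaning
    unlabeled (excluded, counted).  NaNs (unfillable voxels) are ignored in
    the means; a region with no skeleton voxels is emitted as NaN.
    """
    vals = np.atleast_2d(np.asarray(projected_values, float))
    labels = np.asarray(region_labels).ravel()
    if labels.size != vals.shape[1]:
        raise ValueError("region_labels must align with projected columns")
    if subject_ids is None:
        subject_ids = list(range(vals.shape[0]))
    n_unlabeled = int(np.sum(labels == 0))
    rows = []
    regions = [r for r in np.unique(labels) if r != 0]
    for s, sid in enumerate(subject_ids):
        for r in regions:
            m = labels == r
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                mean = float(np.nanmean(vals[s, m])) if m.any() else np.nan
            rows.append(dict(subject=sid, region=int(r), mean=mean,
                             n_voxels=int(m.sum())))
    out = pd.DataFrame(rows)
    out.attrs["n_unlabeled_voxels"] = n_unlabeled
    return out


def adjusted_group_comparison(table: pd.DataFrame, outcome: str, group: str,
                              covariates=(), family_size: int = 1) -> dict:
    """ANOVA of ``outcome`` across ``group`` levels adjusted for covariates.

    Linear-model F-test of the group factor on top of the covariates
    (ANCOVA); ``family_size`` is the caller-supplied Bonferroni multiplier.
    A constant outcome yields an undefined F, reported as NaN.
    """
    if family_size < 1:
        raise ValueError("family_size must be >= 1")
    df = table.dropna(subset=[outcome, group, *covariates])
    y = df[outcome].to_numpy(float)
    n = y.size
    g = pd.Categorical(df[group])
    dummies = pd.get_dummies(g, drop_first=True).to_numpy(float)
    x_red = np.column_stack([np.ones(n)] +
                            [df[c].to_numpy(float) for c in covariates])
    x_full = np.column_stack([x_red, dummies])

    def rss(x):
        beta, *_ = np.linalg.lstsq(x, y, rcond=None)
        r = y - x @ beta
        return float(r @ r), np.linalg.matrix_rank(x)

    rss_red, rank_red = rss(x_red)
    rss_full, rank_full = rss(x_full)
    q = rank_full - rank_red
    dof = n - rank_full
    if dof <= 0 or q <= 0 or np.var(y) == 0 or rss_full <= 0:
        return dict(f=np.nan, p=np.nan, p_bonferroni=np.nan, dof=(q, dof),
                    note="undefined F (constant outcome or saturated design)")
    f = ((rss_red - rss_full) / q) / (rss_full / dof)
    p = float(sps.f.sf(f, q, dof))
    return dict(f=float(f), p=p, p_bonferroni=min(1.0, p * family_size),
                dof=(q, dof), note="")


def partial_correlation(x, y, covariates=None) -> tuple:
    """Pearson correlation of x and y after linear covariate adjustment.

    Residualizes both variables on [1, covariates] and correlates the
    residuals; p comes from the t transform with n − k − 2 degrees of
    freedom (k covariates).  With no covariates this is the plain Pearson
    correlation.  Zero-variance residuals are reported as (nan, nan).
    """
    x = np.asarray(x, float).ravel()
    y = np.asarray(y, float).ravel()
    n = x.size
    if covariates is None or (np.size(covariates) == 0):
        z = np.ones((n, 1))
        k = 0
    else:
        cov = np.atleast_2d(np.asarray(covariates, float))
        if cov.shape[0] != n:
            cov = cov.T
        z = np.column_stack([np.ones(n), cov])
        k = cov.shape[1]
    if n <= k + 2:
        raise ValueError(f"need n > k + 2 (n={n}, k={k})")
    rx = x - z @ np.linalg.lstsq(z, x, rcond=None)[0]
    ry = y - z @ np.linalg.lstsq(z, y, rcond=None)[0]
    if np.allclose(rx, 0) or np.allclose(ry, 0):
        warnings.warn("zero-variance residuals; partial correlation undefined")
        return np.nan, np.nan
    r = float(np.dot(rx, ry) / np.sqrt(np.dot(rx, rx) * np.dot(ry, ry)))
    r = max(-1.0, min(1.0, r))
    dof = n - k - 2
    if abs(r) >= 1.0:
        return r, 0.0
    t = r * np.sqrt(dof / (1.0 - r**2))
    p = float(2.0 * sps.t.sf(abs(t), dof))
    return r, p
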