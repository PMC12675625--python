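"""TFCE, permutation inference, ROI/ANCOVA and partial correlations."""

import numpy as np
import pandas as pd
import pytest

from glymphpipe.stats import (DesignSpec, TfceParams,
                              adjusted_group_comparison, partial_correlation,
                              permutation_inference, roi_summary, tfce)


# ------------------------------------------------------------------ TFCE

def test_tfce_zero_map_is_zero():
    assert np.array_equal(tfce(np.zeros((6, 6, 6))), np.zeros((6, 6, 6)))


def test_tfce_single_cluster_closed_form():
    """One constant-height cluster: every voxel gets n^E · Σ (k·dh)^H · dh."""
    stat = np.zeros((8, 8, 8))
    stat[2:4, 2:4, 2] = 3.0                       # n = 4 voxels at h0 = 3
    params = TfceParams(e=0.5, h=2.0, dh=0.1)
    ks = np.arange(1, 31)                         # k·dh ≤ 3.0 inclusive
    expected = 4 ** 0.5 * np.sum((0.1 * ks) ** 2 * 0.1)
    out = tfce(stat, params)
    assert np.allclose(out[2:4, 2:4, 2], expected, atol=1e-10)
    assert np.all(out[stat == 0] == 0)


def test_tfce_monotone_in_voxel_height(rng):
    stat = rng.random((6, 6, 6))
    params = TfceParams(dh=0.05)
    base = tfce(stat, params)
    bumped = stat.copy()
    bumped[3, 3, 3] += 0.5
    assert np.all(tfce(bumped, params) >= base - 1e-12)


def test_tfce_is_odd_in_sign():
    stat = np.zeros((6, 6, 6))
    stat[1:3, 1, 1] = 2.0
    stat[4, 4, 4] = -1.5
    params = TfceParams(dh=0.1)
    out = tfce(stat, params)
    assert np.array_equal(tfce(-stat, params), -out)
    assert out[4, 4, 4] < 0 < out[1, 1, 1]


def test_tfce_rejects_nonfinite():
    bad = np.zeros((4, 4, 4))
    bad[0, 0, 0] = np.nan
    with pytest.raises(ValueError, match="non-finite"):
        tfce(bad)


def brute_force_tfce(stat, params):
    """Independent discrete-sum oracle with its own BFS labelling."""
    from collections import deque

    shape = stat.shape
    offs = [(i, j, k) for i in (-1, 0, 1) for j in (-1, 0, 1)
            for k in (-1, 0, 1) if (i, j, k) != (0, 0, 0)]
    if params.connectivity == 6:
        offs = [o for o in offs if sum(map(abs, o)) == 1]
    peak = stat.max(initial=0.0)
    dh = params.dh if params.dh is not None else peak / params.n_steps
    out = np.zeros(shape)
    if peak <= 0:
        return out
    for kk in range(1, int(np.floor(peak / dh + 1e-9)) + 1):
        h = kk * dh
        supra = stat >= h - 1e-12
        seen = np.zeros(shape, bool)
        for start in np.argwhere(supra):
            start = tuple(start)
            if seen[start]:
                continue
            comp = [start]
            seen[start] = True
            q = deque([start])
            while q:
                cur = q.popleft()
                for o in offs:
                    nb = tuple(np.add(cur, o))
                    if all(0 <= nb[d] < shape[d] for d in range(3)) \
                            and supra[nb] and not seen[nb]:
                        seen[nb] = True
                        comp.append(nb)
                        q.append(nb)
            contrib = len(comp) ** params.e * h ** params.h * dh
            for vox in comp:
                out[vox] += contrib
    return out


@pytest.mark.parametrize("connectivity", [6, 26])
def test_tfce_matches_brute_force_small_maps(connectivity, rng):
    params = TfceParams(connectivity=connectivity, n_steps=40)
    for _ in range(5):
        stat = np.maximum(rng.normal(0.2, 1.0, (7, 7, 7)), 0.0)
        assert np.abs(tfce(stat, params)
                      - brute_force_tfce(stat, params)).max() <= 1e-6


# --------------------------------------------------- permutation inference

VOX = np.array([(x, y, 3) for x in range(1, 6) for y in range(1, 6)])


def test_identical_groups_give_null_result():
    rng = np.random.default_rng(0)
    half = rng.standard_normal((8, len(VOX)))
    y = np.vstack([half, half])                  # both groups identical data
    design = DesignSpec(group=np.repeat([0, 1], 8))
    res = permutation_inference(y, design, grid_shape=(7, 7, 7),
                                voxel_index=VOX, n_perm=100, seed=0)
    assert np.allclose(res["t"], 0.0, atol=1e-10)
    assert np.all(res["p_fwe"] == 1.0)


def test_p_values_bounded_and_reproducible():
    rng = np.random.default_rng(1)
    y = rng.standard_normal((16, len(VOX)))
    design = DesignSpec(group=np.repeat([0, 1], 8),
                        covariates=rng.standard_normal((16, 2)))
    a = permutation_inference(y, design, grid_shape=(7, 7, 7),
                              voxel_index=VOX, n_perm=150, seed=3)
    b = permutation_inference(y, design, grid_shape=(7, 7, 7),
                              voxel_index=VOX, n_perm=150, seed=3)
    assert np.array_equal(a["p_fwe"], b["p_fwe"])
    assert a["p_fwe"].min() >= 1.0 / 151.0
    assert a["p_fwe"].max() <= 1.0


def test_planted_effect_detected():
    rng = np.random.default_rng(2)
    y = rng.standard_normal((20, len(VOX)))
    y[10:, :6] += 3.0                              # strong shift, group 1
    design = DesignSpec(group=np.repeat([0, 1], 10), contrast=1)
    res = permutation_inference(y, design, grid_shape=(7, 7, 7),
                                voxel_index=VOX, n_perm=200, seed=0)
    assert res["p_fwe"][:6].min() < 0.05


def test_confounded_design_rejected():
    g = np.repeat([0.0, 1.0], 6)
    design = DesignSpec(group=g, covariates=g.reshape(-1, 1))
    with pytest.raises(ValueError, match="confounded"):
        permutation_inference(np.random.default_rng(0).random((12, len(VOX))),
                              design, grid_shape=(7, 7, 7), voxel_index=VOX,
                              n_perm=100, seed=0)


def test_small_n_enumerates_exactly():
    rng = np.random.default_rng(3)
    y = rng.standard_normal((5, len(VOX)))
    design = DesignSpec(group=np.array([0, 0, 1, 1, 1]))
    res = permutation_inference(y, design, grid_shape=(7, 7, 7),
                                voxel_index=VOX, n_perm=200, seed=0)
    assert res["exact"] and res["n_perm"] == 120    # 5! enumerations


# ------------------------------------------------------------ ROI summary

def test_roi_summary_oracle():
    labels = np.array([1, 1, 2, 2, 2, 0])
    vals = np.array([[1.0, 3.0, 2.0, 4.0, 6.0, 99.0]])
    out = roi_summary(vals, labels)
    assert out[out.region == 1]["mean"].item() == pytest.approx(2.0)
    assert out[out.region == 2]["mean"].item() == pytest.approx(4.0)
    assert out.attrs["n_unlabeled_voxels"] == 1


def test_roi_summary_constant_and_single_region():
    labels = np.ones(10, int)
    vals = np.full((3, 10), 0.7)
    out = roi_summary(vals, labels)
    assert np.allclose(out["mean"], 0.7)
    assert len(out) == 3


# --------------------------------------------------------- group ANCOVA

def _cohort_frame(rng, shift=0.0, n=30):
    g = np.repeat(["a", "b"], n)
    age = rng.normal(60, 8, 2 * n)
    y = rng.normal(0, 1, 2 * n) + 0.05 * age
    y[n:] += shift
    return pd.DataFrame({"y": y, "group": g, "age": age,
                         "sex": rng.integers(0, 2, 2 * n)})


def test_identical_groups_f_near_zero(rng):
    df = _cohort_frame(rng, shift=0.0)
    for col in ("y", "age", "sex"):               # literally identical groups
        df[col] = np.tile(df[col][:30], 2)
    res = adjusted_group_comparison(df, "y", "group", ["age", "sex"])
    assert res["f"] < 1e-10 and res["p"] > 0.999


def test_planted_shift_is_significant():
    hits = 0
    for seed in range(20):
        rng = np.random.default_rng(seed)
        df = _cohort_frame(rng, shift=3.0)
        res = adjusted_group_comparison(df, "y", "group", ["age", "sex"])
        hits += res["p"] < 0.001
    assert hits >= 19                              # >= 95% of seeds


def test_bonferroni_identity_and_scaling(rng):
    df = _cohort_frame(rng, shift=1.0)
    r1 = adjusted_group_comparison(df, "y", "group", ["age"], family_size=1)
    r5 = adjusted_group_comparison(df, "y", "group", ["age"], family_size=5)
    assert r1["p_bonferroni"] == r1["p"]
    assert r5["p_bonferroni"] == pytest.approx(min(1.0, 5 * r5["p"]))


def test_ancova_matches_statsmodels(rng):
    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm

    df = _cohort_frame(rng, shift=0.8)
    res = adjusted_group_comparison(df, "y", "group", ["age", "sex"])
    fit = smf.ols("y ~ age + sex + C(group)", data=df).fit()
    tab = anova_lm(smf.ols("y ~ age + sex", data=df).fit(), fit)
    assert res["f"] == pytest.approx(tab["F"][1], rel=1e-8)
    assert res["p"] == pytest.approx(tab["Pr(>F)"][1], rel=1e-8)


def test_constant_outcome_reported_undefined(rng):
    df = _cohort_frame(rng)
    df["y"] = 1.0
    res = adjusted_group_comparison(df, "y", "group", ["age"])
    assert np.isnan(res["f"]) and "undefined" in res["note"]


# ---------------------------------------------------- partial correlation

def test_no_covariates_equals_plain_pearson(rng):
    from scipy.stats import pearsonr

    x, y = rng.random(40), rng.random(40)
    r, p = partial_correlation(x, y)
    rr, pp = pearsonr(x, y)
    assert r == pytest.approx(rr, abs=1e-12)
    assert p == pytest.approx(pp, abs=1e-10)


def test_self_correlation_is_one(rng):
    x = rng.random(30)
    cov = rng.random((30, 2))
    r, _ = partial_correlation(x, x, cov)
    assert r == pytest.approx(1.0, abs=1e-12)


def test_partial_matches_residual_regression_oracle(rng):
    z = rng.standard_normal(50)
    x = 2.0 * z + rng.standard_normal(50)
    y = -1.5 * z + rng.standard_normal(50)
    r, _ = partial_correlation(x, y, z.reshape(-1, 1))
    # two-step residualization oracle
    zz = np.column_stack([np.ones(50), z])
    rx = x - zz @ np.linalg.lstsq(zz, x, rcond=None)[0]
    ry = y - zz @ np.linalg.lstsq(zz, y, rcond=None)[0]
    expected = np.corrcoef(rx, ry)[0, 1]
    assert r == pytest.approx(expected, abs=1e-10)


def test_partial_correlation_symmetric_and_matches_pingouin(rng):
    import pingouin as pg

    df = pd.DataFrame({"x": rng.random(40), "y": rng.random(40),
                       "z1": rng.random(40), "z2": rng.random(40)})
    r_xy, p_xy = partial_correlation(df.x, df.y, df[["z1", "z2"]].to_numpy())
    r_yx, _ = partial_correlation(df.y, df.x, df[["z1", "z2"]].to_numpy())
    assert r_xy == pytest.approx(r_yx, abs=1e-14)
    ref = pg.partial_corr(df, x="x", y="y", covar=["z1", "z2"])
    assert r_xy == pytest.approx(ref["r"].item(), abs=1e-10)
    assert p_xy == pytest.approx(ref["p_val"].item(), abs=1e-10)


def test_zero_variance_residuals_reported(rng):
    z = rng.random(20)
    with pytest.warns(UserWarning, match="zero-variance"):
        r, p = partial_correlation(3.0 * z, rng.random(20), z.reshape(-1, 1))
    assert np.isnan(r)
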