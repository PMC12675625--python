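"""Gower / PAM / silhouette / CH / ARI / bootstrap against brute force."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from glymphpipe.cluster import (GowerSpec, adjusted_rand_index,
                                bootstrap_stability, calinski_harabasz,
                                flag_unassigned, gower_distance, pam,
                                select_k, silhouette)


def _blob_distance(sizes, within=0.05, between=0.9, seed=0):
    """Distance matrix of well-separated planted blobs."""
    rng = np.random.default_rng(seed)
    labels = np.repeat(np.arange(len(sizes)), sizes)
    n = labels.size
    d = np.empty((n, n))
    for i in range(n):
        for j in range(n):
            base = within if labels[i] == labels[j] else between
            d[i, j] = base + 0.01 * rng.random()
    d = 0.5 * (d + d.T)
    np.fill_diagonal(d, 0.0)
    return d, labels


# ---------------------------------------------------------------- Gower

def _spec():
    return GowerSpec(variables={"a": "continuous", "b": "binary",
                                "c": "categorical"})


def test_gower_identical_rows_zero():
    t = pd.DataFrame({"a": [1.0, 1.0], "b": [0, 0], "c": ["x", "x"]})
    d = gower_distance(t, _spec())
    assert np.allclose(d, 0.0)


def test_gower_single_binary_difference_is_one_over_m():
    t = pd.DataFrame({"a": [1.0, 1.0], "b": [0, 1], "c": ["x", "x"]})
    d = gower_distance(t, _spec())
    assert d[0, 1] == pytest.approx(1.0 / 3.0)


def test_gower_all_different_binary_rows_is_one():
    spec = GowerSpec(variables={"b1": "binary", "b2": "binary"})
    t = pd.DataFrame({"b1": [0, 1], "b2": [1, 0]})
    assert gower_distance(t, spec)[0, 1] == 1.0


def test_gower_pairwise_deletion_and_weights():
    spec = GowerSpec(variables={"a": "continuous", "b": "binary"},
                     weights={"a": 2.0, "b": 1.0})
    t = pd.DataFrame({"a": [0.0, 10.0, np.nan], "b": [0, 1, 1]})
    d = gower_distance(t, spec)
    # rows 0,1: (2*1 + 1*1) / 3; rows 1,2: only b observed -> 0
    assert d[0, 1] == pytest.approx(1.0)
    assert d[1, 2] == 0.0
    assert d[0, 2] == 1.0             # only b observed, and it differs


def test_gower_no_joint_observation_errors():
    spec = GowerSpec(variables={"a": "continuous", "b": "continuous"})
    t = pd.DataFrame({"a": [1.0, np.nan], "b": [np.nan, 2.0]})
    with pytest.raises(ValueError, match="no observed variable"):
        gower_distance(t, spec)


def test_gower_validation():
    with pytest.raises(ValueError, match="unknown type"):
        GowerSpec(variables={"a": "ordinal"})
    with pytest.raises(ValueError, match="weight"):
        GowerSpec(variables={"a": "binary"}, weights={"a": 0.0})
    with pytest.raises(ValueError, match="not in table"):
        gower_distance(pd.DataFrame({"x": [1]}), _spec())


@settings(derandomize=True, max_examples=25)
@given(st.integers(min_value=0, max_value=10_000))
def test_gower_is_bounded_symmetric_dissimilarity(seed):
    rng = np.random.default_rng(seed)
    n = 8
    t = pd.DataFrame({
        "a": rng.normal(size=n),
        "b": rng.integers(0, 2, n),
        "c": rng.choice(list("xyz"), n),
    })
    d = gower_distance(t, _spec())
    assert np.allclose(d, d.T)
    assert np.all(np.diag(d) == 0.0)
    assert d.min() >= 0.0 and d.max() <= 1.0


# ------------------------------------------------------------------ PAM

def test_pam_k_equals_n_zero_objective():
    d, _ = _blob_distance([3, 3])
    medoids, labels = pam(d, 6)
    assert sorted(medoids) == list(range(6))
    assert np.all(d[np.arange(6), medoids[labels]] == 0.0)


def test_pam_matches_exhaustive_search_small_instances():
    for seed in range(10):
        rng = np.random.default_rng(seed)
        n = 8
        d = rng.random((n, n))
        d = 0.5 * (d + d.T)
        np.fill_diagonal(d, 0.0)
        medoids, labels = pam(d, 2)
        obj = d[np.arange(n), medoids[labels]].sum()
        best = min(d[:, list(pair)].min(axis=1).sum()
                   for pair in itertools.combinations(range(n), 2))
        assert obj == pytest.approx(best, abs=1e-12)


def test_pam_recovers_planted_blobs():
    d, truth = _blob_distance([5, 7], seed=3)
    _, labels = pam(d, 2)
    assert adjusted_rand_index(labels, truth) == 1.0


def test_pam_deterministic_and_validated():
    d, _ = _blob_distance([4, 4])
    a = pam(d, 2)
    b = pam(d, 2)
    assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])
    with pytest.raises(ValueError):
        pam(d, 1)
    with pytest.raises(ValueError):
        pam(d, 9)


# ------------------------------------------------------------ silhouette

def test_silhouette_brute_force_small_instances():
    for seed in range(5):
        rng = np.random.default_rng(seed)
        n = 10
        d = rng.random((n, n))
        d = 0.5 * (d + d.T)
        np.fill_diagonal(d, 0.0)
        labels = rng.integers(0, 3, n)
        if np.unique(labels).size < 2:
            continue
        widths, mean = silhouette(d, labels)
        for i in range(n):
            own = [j for j in range(n) if labels[j] == labels[i] and j != i]
            if not own:
                assert widths[i] == 0.0
                continue
            a = np.mean([d[i, j] for j in own])
            b = min(np.mean([d[i, j] for j in range(n) if labels[j] == c])
                    for c in np.unique(labels) if c != labels[i])
            assert widths[i] == pytest.approx((b - a) / max(a, b), abs=1e-12)
        assert mean == pytest.approx(widths.mean())


def test_silhouette_agrees_with_sklearn():
    from sklearn.metrics import silhouette_samples

    d, truth = _blob_distance([5, 6, 4], seed=1)
    widths, _ = silhouette(d, truth)
    ref = silhouette_samples(d, truth, metric="precomputed")
    assert np.allclose(widths, ref, atol=1e-12)


def test_silhouette_edge_cases():
    d, truth = _blob_distance([6, 6], seed=2)
    widths, mean = silhouette(d, truth)
    assert mean > 0.9                            # tight far blobs
    # equidistant point: b == a -> s = 0
    d2 = np.array([[0, 1.0, 2.0, 2.0], [1, 0, 2, 2],
                   [2, 2, 0, 1], [2, 2, 1, 0]])
    labels = np.array([0, 0, 1, 1])
    d2[0, 2] = d2[2, 0] = 1.0
    d2[0, 3] = d2[3, 0] = 1.0                    # point 0: a = 1, b = 1
    w, _ = silhouette(d2, labels)
    assert w[0] == 0.0
    with pytest.raises(ValueError):
        silhouette(d2, np.zeros(4, int))


# ---------------------------------------------------- Calinski-Harabasz

def test_ch_prefers_true_k_and_scale_property():
    d, truth = _blob_distance([6, 6], seed=4)
    _, l2 = pam(d, 2)
    _, l3 = pam(d, 3)
    ch2, ch3 = calinski_harabasz(d, l2), calinski_harabasz(d, l3)
    assert ch2 > ch3
    assert calinski_harabasz(2.0 * d, l2) == pytest.approx(ch2, rel=1e-12)
    assert calinski_harabasz(2.0 * d, l3) == pytest.approx(ch3, rel=1e-12)
    with pytest.raises(ValueError):
        calinski_harabasz(d, np.zeros(12, int))


# -------------------------------------------------------------- select_k

def test_select_k_finds_planted_two_blobs():
    d, _ = _blob_distance([6, 8], seed=5)
    sol = select_k(d, range(2, 7))
    assert sol.k == 2
    assert set(sol.by_k) == {2, 3, 4, 5, 6}


def test_select_k_single_candidate_and_flat_ties():
    d = np.ones((3, 3)) - np.eye(3)
    sol = select_k(d, [2])
    assert sol.k == 2
    flat = np.ones((6, 6)) - np.eye(6)
    assert select_k(flat, range(2, 5)).k == 2     # tie -> smallest k


# -------------------------------------------------------- flag_unassigned

def test_flag_unassigned_paths():
    d, truth = _blob_distance([5, 5], seed=6)
    sol = select_k(d, [2])
    labels, un = flag_unassigned(sol, d)
    assert un == [] and np.array_equal(labels, sol.labels)
    labels, un = flag_unassigned(sol, d, width_threshold=1.0)
    assert len(un) == 10 and np.all(labels == -1)


def test_flag_unassigned_boundary_point():
    """A point assigned to one cluster but mean-closer to the other has a
    negative silhouette width and is the only one flagged."""
    from glymphpipe.cluster import ClusterSolution, silhouette

    d, truth = _blob_distance([3, 4], within=0.05, between=0.9, seed=7)
    # point 6 sits in cluster 1 but is mean-closer to cluster 0
    d[6, :3] = d[:3, 6] = 0.45
    d[6, 3:6] = d[3:6, 6] = [0.30, 0.85, 0.85]
    np.fill_diagonal(d, 0)
    labels = np.array([0, 0, 0, 1, 1, 1, 1])
    widths, mean = silhouette(d, labels)
    sol = ClusterSolution(k=2, medoids=np.array([0, 3]), labels=labels,
                          silhouette_widths=widths, mean_silhouette=mean,
                          calinski_harabasz=0.0)
    flagged, un = flag_unassigned(sol, d)
    assert un == [6]
    assert flagged[6] == -1 and np.all(flagged[:6] == labels[:6])


# ------------------------------------------------------------------- ARI

def test_ari_identities():
    assert adjusted_rand_index([0, 0, 1, 1], [1, 1, 0, 0]) == 1.0
    assert adjusted_rand_index([0, 0, 0, 0], [0, 1, 2, 0]) == 0.0


def test_ari_matches_sklearn_brute_force(rng):
    from sklearn.metrics import adjusted_rand_score

    for _ in range(20):
        a = rng.integers(0, 3, 10)
        b = rng.integers(0, 4, 10)
        assert adjusted_rand_index(a, b) == pytest.approx(
            adjusted_rand_score(a, b), abs=1e-12)


def test_ari_rejects_empty_or_mismatched():
    with pytest.raises(ValueError):
        adjusted_rand_index([], [])
    with pytest.raises(ValueError):
        adjusted_rand_index([0, 1], [0, 1, 2])


# ------------------------------------------------------------- bootstrap

def _blob_table(n_per=8, sep=6.0, seed=0):
    rng = np.random.default_rng(seed)
    x = np.concatenate([rng.normal(0, 1, n_per), rng.normal(sep, 1, n_per)])
    y = np.concatenate([rng.normal(0, 1, n_per), rng.normal(sep, 1, n_per)])
    return pd.DataFrame({"x": x, "y": y})


def test_bootstrap_perfect_structure_all_ones():
    spec = GowerSpec(variables={"x": "continuous", "y": "continuous"})
    out = bootstrap_stability(_blob_table(sep=20.0), spec, 2, n_boot=30,
                              seed=1)
    assert np.all(out["ari"] == 1.0) and out["mean"] == 1.0


def test_bootstrap_overlap_reduces_stability():
    spec = GowerSpec(variables={"x": "continuous", "y": "continuous"})
    tight = bootstrap_stability(_blob_table(sep=20.0, seed=2), spec, 2,
                                n_boot=40, seed=5)
    loose = bootstrap_stability(_blob_table(sep=1.0, seed=2), spec, 2,
                                n_boot=40, seed=5)
    assert loose["mean"] < tight["mean"]


def test_bootstrap_deterministic():
    spec = GowerSpec(variables={"x": "continuous", "y": "continuous"})
    t = _blob_table(seed=3)
    a = bootstrap_stability(t, spec, 2, n_boot=20, seed=9)
    b = bootstrap_stability(t, spec, 2, n_boot=20, seed=9)
    assert np.array_equal(a["ari"], b["ari"])
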