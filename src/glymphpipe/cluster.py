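"""Mixed-data phenotype clustering: Gower distance, PAM (k-medoids),
internal validation (silhouette, Calinski–Harabasz), and external
validation by bootstrap adjusted-Rand stability.

Everything is deterministic: PAM's BUILD and SWAP phases break ties toward
the lowest index, k-selection breaks ties toward the smaller k, and the
bootstrap is driven by an explicit seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["GowerSpec", "ClusterSolution", "gower_distance", "pam",
           "silhouette", "calinski_harabasz", "select_k", "flag_unassigned",
           "adjusted_rand_index", "bootstrap_stability"]

_CONTINUOUS = "continuous"
_TYPES = (_CONTINUOUS, "binary", "categorical")


@dataclass
class GowerSpec:
    """Variable registry for the Gower dissimilarity.

    ``variables`` maps column name -> type (continuous / binary /
    categorical); ``weights`` (default 1) and, for continuous variables,
    ``ranges`` (default: observed sample range).  Missing values are
    handled by pairwise deletion: a variable contributes to a pair only
    where both values are observed.
    """

    variables: dict
    weights: dict = field(default_factory=dict)
    ranges: dict = field(default_factory=dict)

    def __post_init__(self):
        for name, t in self.variables.items():
            if t not in _TYPES:
                raise ValueError(f"variable {name!r}: unknown type {t!r}")
        w = [self.weights.get(n, 1.0) for n in self.variables]
        if any(x < 0 for x in w):
            raise ValueError("weights must be >= 0")
        if not any(x > 0 for x in w):
            raise ValueError("at least one weight must be positive")
        for n, r in self.ranges.items():
            if r <= 0:
                raise ValueError(f"range for {n!r} must be > 0")


def gower_distance(table: pd.DataFrame, spec: GowerSpec) -> np.ndarray:
    """Symmetric Gower dissimilarity matrix in [0, 1].

    d(i,j) = Σ_v w_v δ_v s_v / Σ_v w_v δ_v with s_v = |x_i − x_j| / range_v
    for continuous variables and the disagreement indicator otherwise;
    δ_v = 0 where either value is missing.  A pair of rows with no jointly
    observed variable is an error.
    """
    missing_cols = [c for c in spec.variables if c not in table.columns]
    if missing_cols:
        raise ValueError(f"columns not in table: {missing_cols}")
    n = len(table)
    num = np.zeros((n, n))
    den = np.zeros((n, n))
    for name, vtype in spec.variables.items():
        w = spec.weights.get(name, 1.0)
        if w == 0:
            continue
        col = table[name]
        if vtype == _CONTINUOUS:
            x = col.to_numpy(float)
            obs = np.isfinite(x)
            rng = spec.ranges.get(name)
            if rng is None:
                vals = x[obs]
                rng = float(vals.max() - vals.min()) if vals.size else 0.0
            if rng == 0:
                s = np.zeros((n, n))
            else:
                s = np.abs(x[:, None] - x[None, :]) / rng
        else:
            x = col.to_numpy(object)
            obs = ~pd.isna(col).to_numpy()
            if vtype == "binary" and len(set(x[obs])) > 2:
                raise ValueError(f"binary variable {name!r} has >2 levels")
            s = (x[:, None] != x[None, :]).astype(float)
        delta = (obs[:, None] & obs[None, :]).astype(float)
        num += w * delta * np.nan_to_num(s)
        den += w * delta
    if np.any(den == 0):
        i, j = np.argwhere(den == 0)[0]
        raise ValueError(f"rows {i} and {j} share no observed variable")
    d = num / den
    np.fill_diagonal(d, 0.0)
    return np.clip(0.5 * (d + d.T), 0.0, 1.0)


def _objective(dist: np.ndarray, medoids) -> float:
    return float(dist[:, list(medoids)].min(axis=1).sum())


def pam(dist: np.ndarray, k: int, *, exhaustive_limit: int = 2000):
    """Partitioning around medoids.

    Small instances (at most ``exhaustive_limit`` medoid subsets) are solved
    exactly by enumeration, ties broken toward the lexicographically
    smallest medoid set; larger ones use greedy BUILD followed by
    best-improvement SWAP, all ties toward the lowest index.  Either way the
    result is deterministic.  Returns (medoid indices sorted, labels) with
    labels holding each point's position in the medoid list.  The objective
    (total distance of points to their medoid) never increases across SWAP
    iterations.
    """
    import math

    dist = np.asarray(dist, float)
    n = dist.shape[0]
    if dist.shape != (n, n):
        raise ValueError("dist must be square")
    if not 2 <= k <= n:
        raise ValueError(f"k must lie in [2, n] (k={k}, n={n})")

    if math.comb(n, k) <= exhaustive_limit:
        import itertools

        best_obj, best_set = np.inf, None
        for combo in itertools.combinations(range(n), k):
            obj = _objective(dist, combo)
            if obj < best_obj - 1e-12:
                best_obj, best_set = obj, combo
        medoids = sorted(best_set)
        labels = np.argmin(dist[:, medoids], axis=1)
        labels[medoids] = np.arange(k)
        return np.array(medoids), labels

    # BUILD: start from the most central point, then add the point giving
    # the largest objective decrease (np.argmin returns the lowest index on
    # ties).
    medoids = [int(np.argmin(dist.sum(axis=1)))]
    while len(medoids) < k:
        current = dist[:, medoids].min(axis=1)
        gains = np.sum(np.maximum(current[None, :] - dist, 0.0), axis=1)
        gains[medoids] = -np.inf
        medoids.append(int(np.argmax(gains)))

    # SWAP: accept the single best strictly-improving swap per iteration.
    obj = _objective(dist, medoids)
    improved = True
    while improved:
        improved = False
        best = (0.0, None)
        for mi, m in enumerate(sorted(medoids)):
            for h in range(n):
                if h in medoids:
                    continue
                cand = [x for x in medoids if x != m] + [h]
                delta = _objective(dist, cand) - obj
                if delta < best[0] - 1e-12:
                    best = (delta, (m, h))
        if best[1] is not None:
            m, h = best[1]
            medoids = [x for x in medoids if x != m] + [h]
            obj += best[0]
            improved = True

    medoids = sorted(medoids)
    labels = np.argmin(dist[:, medoids], axis=1)
    labels[medoids] = np.arange(k)       # a medoid belongs to its own cluster
    return np.array(medoids), labels


def silhouette(dist: np.ndarray, labels: np.ndarray):
    """Per-point silhouette widths and their mean.

    s(i) = (b − a) / max(a, b) with a the mean within-cluster distance
    (excluding self) and b the smallest mean distance to another cluster.
    Points in singleton clusters get s = 0 by convention.
    """
    dist = np.asarray(dist, float)
    labels = np.asarray(labels)
    clusters = np.unique(labels)
    if clusters.size < 2:
        raise ValueError("silhouette needs at least 2 clusters")
    n = labels.size
    s = np.zeros(n)
    for i in range(n):
        own = labels == labels[i]
        if own.sum() == 1:
            s[i] = 0.0
            continue
        a = dist[i, own].sum() / (own.sum() - 1)
        b = min(dist[i, labels == c].mean() for c in clusters
                if c != labels[i])
        denom = max(a, b)
        s[i] = 0.0 if denom == 0 else (b - a) / denom
    return s, float(s.mean())


def calinski_harabasz(dist: np.ndarray, labels: np.ndarray) -> float:
    """Distance-based Calinski–Harabasz score.

    Gower space has no coordinates, so dispersions are built from squared
    distances to medoids: W = Σ_i d(i, m_{c(i)})² with m_c each cluster's
    medoid (min total within-cluster distance), B = Σ_c n_c·d(m_c, m)² with
    m the global medoid, and CH = (B/(k−1)) / (W/(n−k)).
    """
    dist = np.asarray(dist, float)
    labels = np.asarray(labels)
    clusters = np.unique(labels)
    k, n = clusters.size, labels.size
    if k < 2:
        raise ValueError("Calinski-Harabasz needs at least 2 clusters")
    if k >= n:
        raise ValueError("Calinski-Harabasz needs k < n")
    global_medoid = int(np.argmin(dist.sum(axis=1)))
    w = 0.0
    b = 0.0
    for c in clusters:
        idx = np.flatnonzero(labels == c)
        medoid = idx[int(np.argmin(dist[np.ix_(idx, idx)].sum(axis=1)))]
        w += float(np.sum(dist[idx, medoid] ** 2))
        b += idx.size * float(dist[medoid, global_medoid] ** 2)
    if w == 0:
        return np.inf if b > 0 else 0.0
    return (b / (k - 1)) / (w / (n - k))


@dataclass
class ClusterSolution:
    k: int
    medoids: np.ndarray
    labels: np.ndarray
    silhouette_widths: np.ndarray
    mean_silhouette: float
    calinski_harabasz: float
    unassigned: list = field(default_factory=list)
    by_k: dict = field(default_factory=dict)   # k -> (mean_sil, ch)


def select_k(dist: np.ndarray, k_range) -> ClusterSolution:
    """Run PAM over ``k_range`` and keep the max-mean-silhouette solution
    (ties toward smaller k); the Calinski–Harabasz score is reported
    alongside for each candidate."""
    k_range = sorted(set(int(k) for k in k_range))
    n = np.asarray(dist).shape[0]
    if not k_range or k_range[0] < 2 or k_range[-1] > n - 1:
        raise ValueError(f"k_range must lie within [2, n-1] (n={n})")
    best = None
    by_k = {}
    for k in k_range:
        medoids, labels = pam(dist, k)
        widths, mean_sil = silhouette(dist, labels)
        ch = calinski_harabasz(dist, labels)
        by_k[k] = (mean_sil, ch)
        if best is None or mean_sil > best.mean_silhouette + 1e-12:
            best = ClusterSolution(k=k, medoids=medoids, labels=labels,
                                   silhouette_widths=widths,
                                   mean_silhouette=mean_sil,
                                   calinski_harabasz=ch)
    best.by_k = by_k
    return best


def flag_unassigned(solution: ClusterSolution, dist: np.ndarray,
                    width_threshold: float = 0.0):
    """Move subjects with silhouette width ≤ ``width_threshold`` to the
    unassigned list (label −1).

    This is an explicit package convention for leaving poorly-fitting
    subjects "in neither group"; it is the simplest internal criterion
    with that effect, not a claim about how any particular study did it.
    """
    widths, _ = silhouette(dist, solution.labels)
    labels = solution.labels.copy()
    unassigned = np.flatnonzero(widths <= width_threshold)
    labels[unassigned] = -1
    return labels, list(map(int, unassigned))


def adjusted_rand_index(labels_a, labels_b) -> float:
    """Chance-corrected Rand agreement from the contingency table."""
    a = np.asarray(labels_a).ravel()
    b = np.asarray(labels_b).ravel()
    if a.size == 0 or a.size != b.size:
        raise ValueError("labelings must be non-empty and equal length")
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    cont = np.zeros((ai.max() + 1, bi.max() + 1))
    np.add.at(cont, (ai, bi), 1)

    def comb2(x):
        return x * (x - 1) / 2.0

    sum_ij = comb2(cont).sum()
    sum_a = comb2(cont.sum(axis=1)).sum()
    sum_b = comb2(cont.sum(axis=0)).sum()
    total = comb2(a.size)
    expected = sum_a * sum_b / total if total else 0.0
    max_index = 0.5 * (sum_a + sum_b)
    if max_index == expected:
        return 1.0 if sum_ij == expected else 0.0
    return float((sum_ij - expected) / (max_index - expected))


def bootstrap_stability(table: pd.DataFrame, spec: GowerSpec, k: int,
                        n_boot: int = 1000, seed: int = 0,
                        max_redraws: int = 1000) -> dict:
    """Bootstrap cluster-stability analysis.

    Clusters the full table once, then for each of ``n_boot`` resamples
    (rows sampled with replacement; resamples with fewer than k unique rows
    are redrawn and counted) recomputes Gower + PAM(k) on the resample and
    scores the adjusted Rand index against the full-data labels on the
    unique subjects present (duplicates contribute once).  Deterministic
    given ``seed``.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    n = len(table)
    full_dist = gower_distance(table, spec)
    _, full_labels = pam(full_dist, k)

    rng = np.random.default_rng(seed)
    aris = np.empty(n_boot)
    n_redrawn = 0
    for b in range(n_boot):
        for _ in range(max_redraws):
            idx = rng.integers(0, n, size=n)
            if np.unique(idx).size >= k:
                break
            n_redrawn += 1
        else:
            raise RuntimeError("could not draw a resample with >= k unique "
                               "subjects")
        sub = table.iloc[idx].reset_index(drop=True)
        d = gower_distance(sub, spec)
        _, lab = pam(d, k)
        uniq, first = np.unique(idx, return_index=True)
        aris[b] = adjusted_rand_index(lab[first], full_labels[uniq])
    return {"ari": aris, "mean": float(aris.mean()),
            "quantiles": {q: float(np.quantile(aris, q))
                          for q in (0.025, 0.25, 0.5, 0.75, 0.975)},
            "n_redrawn": n_redrawn, "full_labels": full_labels}
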