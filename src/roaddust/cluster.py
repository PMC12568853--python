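"""k-medoids clustering of site concentration profiles.

Sites are grouped by PAM-style k-medoids on Euclidean distances between
z-score-standardized metal profiles (standardization stops Fe/Ni magnitudes
from dominating the metric). The number of clusters is chosen by majority
vote over a panel of internal validity indices (silhouette, Dunn,
Calinski–Harabasz, Davies–Bouldin, gap statistic), cluster quality is
scored by connectivity / Dunn / mean silhouette, and reproducibility by the
mean bootstrap Jaccard overlap per cluster.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.metrics import (
    calinski_harabasz_score,
    davies_bouldin_score,
    silhouette_score,
)

__all__ = [
    "ClusterSolution",
    "KSelection",
    "standardize",
    "kmedoids",
    "validity",
    "select_k",
    "stability",
    "stability_label",
]

DEFAULT_SEED = 20250829


def _as_frame(profiles) -> pd.DataFrame:
    if isinstance(profiles, pd.DataFrame):
        return profiles
    arr = np.asarray(profiles, dtype=float)
    return pd.DataFrame(arr, index=[str(i) for i in range(arr.shape[0])])


def standardize(profiles) -> pd.DataFrame:
    """z-score per feature (ddof=1); constant features are left centred at 0."""
    df = _as_frame(profiles).astype(float)
    sd = df.std(axis=0, ddof=1).replace(0.0, 1.0)
    return (df - df.mean(axis=0)) / sd


@dataclass
class ClusterSolution:
    k: int
    medoid_sites: list[str]
    assignment: pd.Series          # site id -> cluster index (0..k-1)
    total_cost: float              # sum of distances to assigned medoids
    validity: dict[str, float] = field(default_factory=dict)
    stability: pd.Series | None = None

    @property
    def labels(self) -> np.ndarray:
        return self.assignment.to_numpy()


@dataclass
class KSelection:
    candidate_ks: tuple[int, ...]
    votes: dict[int, int]
    chosen_k: int
    best_by_index: dict[str, int] = field(default_factory=dict)


def _assign(D: np.ndarray, medoids: np.ndarray) -> tuple[np.ndarray, float]:
    sub = D[:, medoids]
    labels = sub.argmin(axis=1)
    return labels, float(sub.min(axis=1).sum())


def _swap_to_local_optimum(D: np.ndarray, medoids: np.ndarray) -> tuple[np.ndarray, float]:
    n = D.shape[0]
    medoids = np.array(sorted(medoids))
    _, cost = _assign(D, medoids)
    improved = True
    while improved:
        improved = False
        best_cost, best_swap = cost, None
        in_med = np.zeros(n, dtype=bool)
        in_med[medoids] = True
        for mi in range(len(medoids)):
            for h in range(n):
                if in_med[h]:
                    continue
                trial = medoids.copy()
                trial[mi] = h
                _, c = _assign(D, trial)
                if c < best_cost - 1e-12:
                    best_cost, best_swap = c, (mi, h)
        if best_swap is not None:
            medoids[best_swap[0]] = best_swap[1]
            medoids.sort()
            cost = best_cost
            improved = True
    return medoids, cost


def kmedoids(profiles, k: int, seed: int = DEFAULT_SEED, n_restarts: int = 10) -> ClusterSolution:
    """PAM-style k-medoids (random initialisation + swap phase, best of restarts).

    Minimises the summed dissimilarity of every site to its cluster medoid;
    deterministic for a fixed seed. ``k = n`` is the degenerate one-site-per-
    cluster solution with zero cost.
    """
    df = _as_frame(profiles)
    n = df.shape[0]
    if not 2 <= k <= n:
        raise ValueError(f"k must be in [2, {n}], got {k}")
    D = squareform(pdist(df.to_numpy(dtype=float)))
    rng = np.random.default_rng(seed)
    best: tuple[float, np.ndarray] | None = None
    for _ in range(n_restarts):
        init = rng.choice(n, size=k, replace=False)
        medoids, cost = _swap_to_local_optimum(D, init)
        if best is None or cost < best[0] - 1e-12:
            best = (cost, medoids)
    cost, medoids = best[0], best[1]
    labels, cost = _assign(D, medoids)
    sites = [str(s) for s in df.index]
    return ClusterSolution(
        k=k,
        medoid_sites=[sites[m] for m in medoids],
        assignment=pd.Series(labels, index=df.index, name="cluster"),
        total_cost=cost,
    )


# -- internal validity ---------------------------------------------------------

def _connectivity(D: np.ndarray, labels: np.ndarray, n_neighbors: int = 10) -> float:
    """Neighbor-count connectivity (lower is better): for every point, sum
    1/j over its j-th nearest neighbours that sit in a different cluster."""
    n = D.shape[0]
    L = min(n_neighbors, n - 1)
    total = 0.0
    order = np.argsort(D, axis=1, kind="stable")
    for i in range(n):
        neighbours = [j for j in order[i] if j != i][:L]
        for rank, j in enumerate(neighbours, start=1):
            if labels[j] != labels[i]:
                total += 1.0 / rank
    return total


def _dunn(D: np.ndarray, labels: np.ndarray) -> float:
    """Minimum between-cluster distance over maximum cluster diameter."""
    clusters = np.unique(labels)
    max_diam = 0.0
    for c in clusters:
        idx = np.flatnonzero(labels == c)
        if len(idx) > 1:
            max_diam = max(max_diam, D[np.ix_(idx, idx)].max())
    min_inter = np.inf
    for a in range(len(clusters)):
        ia = np.flatnonzero(labels == clusters[a])
        for b in range(a + 1, len(clusters)):
            ib = np.flatnonzero(labels == clusters[b])
            min_inter = min(min_inter, D[np.ix_(ia, ib)].min())
    if max_diam == 0.0:
        return np.inf
    return float(min_inter / max_diam)


def validity(solution: ClusterSolution, profiles, n_neighbors: int = 10) -> dict[str, float]:
    """Connectivity (lower better), Dunn and mean silhouette (higher better)."""
    df = _as_frame(profiles)
    X = df.to_numpy(dtype=float)
    D = squareform(pdist(X))
    labels = solution.labels
    scores = {
        "connectivity": _connectivity(D, labels, n_neighbors),
        "dunn": _dunn(D, labels),
    }
    if 2 <= len(np.unique(labels)) <= len(labels) - 1:
        scores["silhouette"] = float(silhouette_score(X, labels))
    else:
        scores["silhouette"] = float("nan")
    solution.validity = scores
    return scores


# -- choosing k ----------------------------------------------------------------

def _log_wk(D2: np.ndarray, labels: np.ndarray) -> float:
    """log of the pooled within-cluster dispersion (gap-statistic W_k)."""
    w = 0.0
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        if len(idx) > 1:
            w += D2[np.ix_(idx, idx)].sum() / (2.0 * len(idx))
    return float(np.log(max(w, 1e-300)))


def _gap_curve(df: pd.DataFrame, ks: list[int], seed: int, B: int = 10,
               n_restarts: int = 10) -> tuple[np.ndarray, np.ndarray]:
    X = df.to_numpy(dtype=float)
    D2 = squareform(pdist(X)) ** 2
    rng = np.random.default_rng(seed)
    lo, hi = X.min(axis=0), X.max(axis=0)
    ref_logw = np.empty((B, len(ks)))
    for b in range(B):
        Xref = rng.uniform(lo, hi, size=X.shape)
        D2ref = squareform(pdist(Xref)) ** 2
        for j, k in enumerate(ks):
            sol = kmedoids(Xref, k, seed=int(rng.integers(2**31)), n_restarts=n_restarts)
            ref_logw[b, j] = _log_wk(D2ref, sol.labels)
    gaps = np.empty(len(ks))
    for j, k in enumerate(ks):
        sol = kmedoids(df, k, seed=seed, n_restarts=n_restarts)
        gaps[j] = ref_logw[:, j].mean() - _log_wk(D2, sol.labels)
    s = ref_logw.std(axis=0, ddof=1) * np.sqrt(1.0 + 1.0 / B)
    return gaps, s


def select_k(profiles, candidate_ks, seed: int = DEFAULT_SEED,
             n_restarts: int = 10) -> KSelection:
    """Majority vote over a five-index panel for the number of clusters.

    Silhouette, Dunn and Calinski–Harabasz vote for their maximising k,
    Davies–Bouldin for its minimising k, and the gap statistic follows the
    one-standard-error rule (first k whose gap exceeds the next gap minus
    its standard error). Ties in the vote go to the smaller k.
    """
    ks = sorted(int(k) for k in candidate_ks)
    if len(ks) < 2:
        raise ValueError("need at least two candidate values of k")
    df = _as_frame(profiles)
    X = df.to_numpy(dtype=float)
    D = squareform(pdist(X))
    sil, dunn, ch, db = {}, {}, {}, {}
    for k in ks:
        sol = kmedoids(df, k, seed=seed, n_restarts=n_restarts)
        labels = sol.labels
        if len(np.unique(labels)) < 2 or len(np.unique(labels)) > len(labels) - 1:
            continue
        sil[k] = silhouette_score(X, labels)
        dunn[k] = _dunn(D, labels)
        ch[k] = calinski_harabasz_score(X, labels)
        db[k] = davies_bouldin_score(X, labels)
    gaps, s = _gap_curve(df, ks, seed=seed, n_restarts=n_restarts)
    gap_k = ks[-1]
    for j in range(len(ks) - 1):
        if gaps[j] >= gaps[j + 1] - s[j + 1]:
            gap_k = ks[j]
            break
    best_by_index = {
        "silhouette": min(sil, key=lambda k: (-sil[k], k)),
        "dunn": min(dunn, key=lambda k: (-dunn[k], k)),
        "calinski_harabasz": min(ch, key=lambda k: (-ch[k], k)),
        "davies_bouldin": min(db, key=lambda k: (db[k], k)),
        "gap": gap_k,
    }
    votes = Counter(best_by_index.values())
    top = max(votes.values())
    chosen = min(k for k, v in votes.items() if v == top)
    return KSelection(tuple(ks), dict(votes), chosen, best_by_index)


# -- bootstrap stability -------------------------------------------------------

def stability_label(jaccard: float) -> str:
    """Verbal label for a mean Jaccard value (>0.85 highly stable, 0.6–0.85 stable)."""
    if jaccard > 0.85:
        return "highly stable"
    if jaccard >= 0.6:
        return "stable"
    return "unstable"


def stability(profiles, k: int, B: int = 100, seed: int = DEFAULT_SEED,
              n_restarts: int = 10) -> pd.Series:
    """Mean bootstrap Jaccard overlap per cluster.

    For each of ``B`` nonparametric bootstrap resamples, the resampled sites
    are re-clustered and every original cluster is matched to the resample
    cluster with which it shares the largest Jaccard overlap (computed on the
    distinct sites present in the resample). Returns the per-cluster mean.
    """
    if B < 20:
        warnings.warn("fewer than 20 bootstrap resamples give an unstable Jaccard estimate")
    df = _as_frame(profiles)
    n = df.shape[0]
    base = kmedoids(df, k, seed=seed, n_restarts=n_restarts)
    original = [set(np.flatnonzero(base.labels == c)) for c in range(k)]
    rng = np.random.default_rng(seed)
    sums = np.zeros(k)
    counts = np.zeros(k)
    for _ in range(B):
        idx = rng.integers(0, n, size=n)
        boot = kmedoids(df.iloc[idx], k, seed=int(rng.integers(2**31)),
                        n_restarts=n_restarts)
        boot_sets = []
        for c in range(k):
            members = np.unique(idx[boot.labels == c])
            boot_sets.append(set(members.tolist()))
        present = set(idx.tolist())
        for c, orig in enumerate(original):
            orig_present = orig & present
            if not orig_present:
                continue
            j = max(
                len(orig_present & bs) / len(orig_present | bs)
                for bs in boot_sets if bs
            )
            sums[c] += j
            counts[c] += 1
    mean_j = np.divide(sums, counts, out=np.zeros(k), where=counts > 0)
    return pd.Series(mean_j, index=pd.RangeIndex(k, name="cluster"), name="mean_jaccard")
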