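"""Assemblage delineation: Ward clustering, silhouette-based k, ANOSIM.

The agglomeration is implemented directly through the Lance-Williams
recursion so both common Ward variants are available: ``ward.D`` applies
the update to the raw dissimilarities, ``ward.D2`` to their squares
(heights reported on the original scale).  Cluster number is chosen by
maximizing the average silhouette width on the original dissimilarities,
and between-group separation is tested with the rank-based ANOSIM
permutation test (midranks for ties).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster
from scipy.spatial.distance import squareform
from scipy.stats import rankdata
from sklearn.metrics import silhouette_score

__all__ = [
    "ClusteringResult",
    "ward_cluster",
    "choose_k",
    "cut_clusters",
    "AnosimResult",
    "anosim",
    "pairwise_anosim",
    "to_newick",
]


def _check_square(dissim: pd.DataFrame) -> np.ndarray:
    d = dissim.to_numpy(dtype=float)
    if d.shape[0] != d.shape[1]:
        raise ValueError("dissimilarity matrix must be square")
    if not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("dissimilarity matrix must be symmetric")
    if (d < -1e-12).any():
        raise ValueError("dissimilarity matrix has negative entries")
    if not np.allclose(np.diag(d), 0.0, atol=1e-10):
        raise ValueError("dissimilarity matrix must have a zero diagonal")
    return d


def _lance_williams_ward(d: np.ndarray) -> np.ndarray:
    """Ward agglomeration by the Lance-Williams recursion.

    Operates on whatever scale ``d`` is given on (raw for ward.D,
    squared for ward.D2) and returns a scipy-style linkage matrix with
    heights on that same scale.
    """
    n = d.shape[0]
    work = d.copy().astype(float)
    np.fill_diagonal(work, np.inf)
    sizes = {i: 1 for i in range(n)}
    ids = {i: i for i in range(n)}  # row -> current cluster id
    active = list(range(n))
    Z = np.empty((n - 1, 4))
    for step in range(n - 1):
        sub = work[np.ix_(active, active)]
        flat = np.argmin(sub)
        ai, aj = np.unravel_index(flat, sub.shape)
        i, j = active[ai], active[aj]
        if i > j:
            i, j = j, i
        h = work[i, j]
        ni, nj = sizes[i], sizes[j]
        Z[step] = (min(ids[i], ids[j]), max(ids[i], ids[j]), h, ni + nj)
        # fold j into i, update distances to every other active cluster
        for k in active:
            if k in (i, j):
                continue
            nk = sizes[k]
            tot = ni + nj + nk
            work[i, k] = work[k, i] = (
                (ni + nk) * work[i, k] + (nj + nk) * work[j, k] - nk * h
            ) / tot
        active.remove(j)
        sizes[i] = ni + nj
        ids[i] = n + step
    return Z


@dataclass
class ClusteringResult:
    """Ward merge tree plus the chosen partition."""

    linkage: np.ndarray  # scipy-format (n-1, 4)
    stations: list
    method: str
    k: int | None = None
    labels: pd.Series | None = None
    silhouette_by_k: dict[int, float] = field(default_factory=dict)

    def cut(self, k: int) -> pd.Series:
        lab = fcluster(self.linkage, t=k, criterion="maxclust")
        return pd.Series(lab, index=self.stations, name="cluster")


def ward_cluster(dissim: pd.DataFrame, method: str = "ward.D2") -> ClusteringResult:
    """Agglomerate stations under Ward's criterion.

    ``ward.D2`` (default) runs the recursion on squared dissimilarities
    and reports heights back on the original scale; ``ward.D`` runs it on
    the raw values.
    """
    d = _check_square(dissim)
    if d.shape[0] < 3:
        raise ValueError("need at least 3 stations to cluster")
    if method == "ward.D2":
        Z = _lance_williams_ward(d**2)
        Z[:, 2] = np.sqrt(np.maximum(Z[:, 2], 0.0))
    elif method == "ward.D":
        Z = _lance_williams_ward(d)
    else:
        raise ValueError(f"unknown ward variant {method!r}")
    return ClusteringResult(linkage=Z, stations=list(dissim.index), method=method)


def choose_k(
    clustering: ClusteringResult,
    dissim: pd.DataFrame,
    k_range=None,
) -> ClusteringResult:
    """Pick k by average silhouette width on the original dissimilarities.

    Ties go to the smallest k.  If no candidate beats a zero silhouette
    (structureless input) the smallest k is returned with a warning.
    """
    d = _check_square(dissim)
    n = d.shape[0]
    if k_range is None:
        k_range = range(2, min(n - 1, 10) + 1)
    k_range = [int(k) for k in k_range]
    if not k_range:
        raise ValueError("empty k_range")
    if min(k_range) < 2 or max(k_range) > n - 1:
        raise ValueError(f"k_range must lie within [2, {n - 1}]")

    scores: dict[int, float] = {}
    for k in sorted(k_range):
        labels = clustering.cut(k)
        if labels.nunique() < 2:
            scores[k] = -np.inf
            continue
        scores[k] = float(silhouette_score(d, labels.to_numpy(), metric="precomputed"))

    best_k = max(sorted(scores), key=lambda k: scores[k])  # ties -> smallest
    if scores[best_k] <= 1e-9:
        warnings.warn(
            "no clustering achieves a positive silhouette; "
            f"returning smallest k={min(scores)}",
            stacklevel=2,
        )
        best_k = min(scores)
    clustering.k = best_k
    clustering.labels = clustering.cut(best_k)
    clustering.silhouette_by_k = scores
    return clustering


def cut_clusters(dissim: pd.DataFrame, k: int, method: str = "ward.D2") -> pd.Series:
    """Convenience: Ward tree cut into exactly k clusters."""
    return ward_cluster(dissim, method=method).cut(k)


@dataclass
class AnosimResult:
    R: float
    p: float
    n_perm: int
    seed: int | None
    groups: tuple


def _anosim_r(ranks: np.ndarray, within: np.ndarray) -> float:
    m = len(ranks)
    rw = ranks[within].mean()
    rb = ranks[~within].mean()
    return float((rb - rw) / (m / 2))


def anosim(
    dissim: pd.DataFrame,
    labels,
    n_perm: int | str = 999,
    seed: int | None = None,
) -> AnosimResult:
    """One-way analysis of similarities on ranked dissimilarities.

    R = (mean between-group rank - mean within-group rank) / (M/2) with
    M = n(n-1)/2; the p value is (1 + #{permuted R >= observed}) /
    (n_perm + 1) under random relabelling of stations.  With
    ``n_perm="exact"`` all n! relabellings are enumerated (small n only)
    and p = #{R >= observed} / n!.
    """
    d = _check_square(dissim)
    labels = pd.Series(labels, index=dissim.index) if not isinstance(
        labels, pd.Series
    ) else labels.reindex(dissim.index)
    if labels.isna().any():
        raise ValueError("labels missing for some stations")
    counts = labels.value_counts()
    if len(counts) < 2:
        raise ValueError("need at least 2 groups")
    if (counts < 2).any():
        raise ValueError(
            f"groups of size 1 not allowed: {list(counts[counts < 2].index)}"
        )

    ranks = rankdata(squareform(d, checks=False))  # midranks
    lab = labels.to_numpy()
    n = len(lab)
    iu = np.triu_indices(n, k=1)
    within = lab[iu[0]] == lab[iu[1]]
    r_obs = _anosim_r(ranks, within)

    if n_perm == "exact":
        from itertools import permutations as _perms
        from math import factorial

        if n > 8:
            raise ValueError("exact enumeration limited to n <= 8")
        count_ge = 0
        for order in _perms(range(n)):
            perm = lab[list(order)]
            w = perm[iu[0]] == perm[iu[1]]
            if _anosim_r(ranks, w) >= r_obs - 1e-12:
                count_ge += 1
        p = count_ge / factorial(n)
        return AnosimResult(
            R=r_obs, p=p, n_perm=factorial(n), seed=seed,
            groups=tuple(sorted(counts.index)),
        )

    rng = np.random.default_rng(seed)
    count_ge = 0
    for _ in range(n_perm):
        perm = rng.permutation(lab)
        w = perm[iu[0]] == perm[iu[1]]
        if _anosim_r(ranks, w) >= r_obs - 1e-12:
            count_ge += 1
    p = (1 + count_ge) / (n_perm + 1)
    return AnosimResult(
        R=r_obs, p=p, n_perm=n_perm, seed=seed, groups=tuple(sorted(counts.index))
    )


def pairwise_anosim(
    dissim: pd.DataFrame,
    labels,
    n_perm: int = 999,
    seed: int | None = None,
    bonferroni: bool = False,
) -> pd.DataFrame:
    """One-way ANOSIM for every pair of groups on their submatrix."""
    labels = pd.Series(labels, index=dissim.index) if not isinstance(
        labels, pd.Series
    ) else labels.reindex(dissim.index)
    counts = labels.value_counts()
    singletons = sorted(counts[counts < 2].index)
    if singletons:
        warnings.warn(
            f"skipping singleton groups in pairwise tests: {singletons}",
            stacklevel=2,
        )
    groups = sorted(counts[counts >= 2].index)
    rows = []
    n_tests = len(groups) * (len(groups) - 1) // 2
    for gi in range(len(groups)):
        for gj in range(gi + 1, len(groups)):
            keep = labels.isin([groups[gi], groups[gj]])
            sub = dissim.loc[keep, keep]
            res = anosim(sub, labels[keep], n_perm=n_perm, seed=seed)
            p = min(1.0, res.p * n_tests) if bonferroni else res.p
            rows.append((groups[gi], groups[gj], res.R, p, n_perm))
    return pd.DataFrame(rows, columns=["group_a", "group_b", "R", "p", "n_perm"])


def to_newick(clustering: ClusteringResult) -> str:
    """Nested-parenthesis text form of the merge tree with branch lengths."""
    Z = clustering.linkage
    names = [str(s) for s in clustering.stations]
    n = len(names)
    height = {i: 0.0 for i in range(n)}
    node: dict[int, str] = {i: names[i] for i in range(n)}
    for step, (a, b, h, _) in enumerate(Z):
        a, b = int(a), int(b)
        la = h - height[a]
        lb = h - height[b]
        nid = n + step
        node[nid] = f"({node[a]}:{la:.6g},{node[b]}:{lb:.6g})"
        height[nid] = h
    return node[n + len(Z) - 1] + ";"
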