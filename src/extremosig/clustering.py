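"""Clustering backends and evaluation: Hungarian-matched accuracy,
genus completeness/contamination quality, and cross-domain consensus pairs.

The clustering accuracy ACC maps cluster labels to true labels through an
optimal assignment: injectively (rectangular Hungarian matching) when there
are at most as many clusters as classes, and by majority class per cluster
when there are more clusters than classes (the standard many-to-one
extension).  Density-based "noise" labels (-1) never match any class.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import KMeans
from sklearn.mixture import GaussianMixture

from .folds import SampleMeta

__all__ = [
    "ClusterAssignment",
    "ClusterQualityReport",
    "hungarian_acc",
    "cluster_quality",
    "evaluate_parametric",
    "consensus_pairs",
    "CLUSTER_BACKENDS",
    "register_backend",
]


@dataclass
class ClusterAssignment:
    """Per-sample integer cluster labels from one clustering run.

    -1 marks density-backend noise.  ``compact()`` renumbers non-noise
    clusters contiguously from 0.
    """

    algorithm: str
    labels: np.ndarray
    n_clusters_requested: int | None = None

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)

    @property
    def n_clusters(self) -> int:
        return len(set(self.labels[self.labels >= 0]))

    def compact(self) -> "ClusterAssignment":
        uniq = np.unique(self.labels[self.labels >= 0])
        remap = {int(c): i for i, c in enumerate(uniq)}
        new = np.array([remap.get(int(c), -1) for c in self.labels])
        return ClusterAssignment(self.algorithm, new, self.n_clusters_requested)


def hungarian_acc(pred: ClusterAssignment | Sequence[int],
                  truth: Sequence,
                  mode: str = "auto") -> float:
    """Unsupervised clustering accuracy in [0, 1].

    ACC = (1/n) * sum_i 1[l_i == f(c_i)] where f optimally maps cluster
    labels to true labels.  ``mode``: "injective" forces one-to-one matching
    (rectangular assignment), "majority" maps each cluster to its most
    common true class, "auto" (default) uses injective when #clusters <=
    #classes and majority otherwise.
    """
    labels = pred.labels if isinstance(pred, ClusterAssignment) else np.asarray(pred)
    y = np.asarray(truth)
    if len(labels) == 0 or len(labels) != len(y):
        raise ValueError("pred and truth must be equal-length and non-empty")
    keep = labels >= 0
    clusters = np.unique(labels[keep])
    classes = np.unique(y)
    n = len(y)
    if len(clusters) == 0:
        return 0.0
    # contingency: rows clusters, cols classes
    cont = np.zeros((len(clusters), len(classes)), dtype=np.int64)
    cl_idx = {c: i for i, c in enumerate(clusters)}
    cls_idx = {c: i for i, c in enumerate(classes)}
    for c, t in zip(labels[keep], y[keep]):
        cont[cl_idx[c], cls_idx[t]] += 1
    if mode == "auto":
        mode = "injective" if len(clusters) <= len(classes) else "majority"
    if mode == "injective":
        r, c = linear_sum_assignment(cont, maximize=True)
        matched = cont[r, c].sum()
    elif mode == "majority":
        matched = cont.max(axis=1).sum()
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return float(matched) / n


@dataclass
class ClusterQualityReport:
    """Per-cluster genus completeness/contamination and the quality count.

    completeness = occurrences of the cluster's most common genus in the
    cluster / total sequences of that genus in the dataset; contamination =
    fraction of the cluster outside its most common genus.  A cluster
    qualifies when completeness >= 0.5 and contamination <= 0.5.  Counts of
    recovered genera are restricted to genera represented by more than two
    sequences.
    """

    per_cluster: pd.DataFrame
    n_qualifying: int
    n_considered_genera: int
    n_recovered_genera: int


def cluster_quality(assign: ClusterAssignment, genus: Sequence[str],
                    min_genus_size: int = 3,
                    completeness_min: float = 0.5,
                    contamination_max: float = 0.5) -> ClusterQualityReport:
    labels = assign.labels
    g = np.asarray(genus)
    if len(labels) != len(g):
        raise ValueError("assignment and genus vector must align")
    genus_total = pd.Series(g).value_counts()
    considered = set(genus_total[genus_total >= min_genus_size].index)
    rows = []
    recovered = set()
    for c in np.unique(labels[labels >= 0]):
        members = g[labels == c]
        counts = pd.Series(members).value_counts()
        top_genus = counts.index[0]
        top_n = int(counts.iloc[0])
        completeness = top_n / int(genus_total[top_genus])
        contamination = 1.0 - top_n / len(members)
        qualifying = (completeness >= completeness_min
                      and contamination <= contamination_max)
        if qualifying and top_genus in considered:
            recovered.add(top_genus)
        rows.append([int(c), top_genus, completeness, contamination,
                     len(members), qualifying])
    df = pd.DataFrame(rows, columns=["cluster", "majority_genus",
                                     "completeness", "contamination",
                                     "size", "qualifying"])
    return ClusterQualityReport(
        per_cluster=df,
        n_qualifying=int(df["qualifying"].sum()) if len(df) else 0,
        n_considered_genera=len(considered),
        n_recovered_genera=len(recovered),
    )


# ---------------------------------------------------------------------------
# backends


def _kmeans(X: np.ndarray, n_clusters: int, seed: int) -> np.ndarray:
    return KMeans(n_clusters=n_clusters, random_state=seed, n_init=10).fit_predict(X)


def _gmm(X: np.ndarray, n_clusters: int, seed: int) -> np.ndarray:
    return GaussianMixture(n_components=n_clusters, random_state=seed,
                           covariance_type="diag").fit(X).predict(X)


def _kmedoids(X: np.ndarray, n_clusters: int, seed: int,
              max_iter: int = 100) -> np.ndarray:
    """PAM-style k-medoids on Euclidean distances with seeded greedy init."""
    from scipy.spatial.distance import squareform, pdist

    D = squareform(pdist(X))
    n = len(X)
    rng = np.random.default_rng(seed)
    medoids = [int(rng.integers(n))]
    while len(medoids) < n_clusters:
        d_min = D[:, medoids].min(axis=1)
        medoids.append(int(np.argmax(d_min)))  # farthest-point init
    medoids = np.array(medoids)
    for _ in range(max_iter):
        assign = np.argmin(D[:, medoids], axis=1)
        new_medoids = medoids.copy()
        for c in range(n_clusters):
            members = np.flatnonzero(assign == c)
            if len(members) == 0:
                continue
            within = D[np.ix_(members, members)].sum(axis=1)
            new_medoids[c] = members[np.argmin(within)]
        if np.array_equal(new_medoids, medoids):
            break
        medoids = new_medoids
    return np.argmin(D[:, medoids], axis=1)


CLUSTER_BACKENDS: dict[str, Callable] = {
    "kmeans": _kmeans,
    "gmm": _gmm,
    "kmedoids": _kmedoids,
}


def register_backend(name: str, fn: Callable) -> None:
    """Register a clustering backend: fn(X, n_clusters, seed) -> labels."""
    CLUSTER_BACKENDS[name] = fn


def evaluate_parametric(
    signatures: np.ndarray | pd.DataFrame,
    backend: str,
    n_clusters: int,
    truths: Mapping[str, Sequence],
    seed: int = 0,
    mode: str = "auto",
) -> tuple[ClusterAssignment, dict[str, float]]:
    """Run a parametric clustering backend and score ACC against each truth."""
    if backend not in CLUSTER_BACKENDS:
        raise ValueError(f"unknown backend {backend!r}; "
                         f"registered: {sorted(CLUSTER_BACKENDS)}")
    X = np.asarray(signatures, dtype=float)
    labels = CLUSTER_BACKENDS[backend](X, n_clusters, seed)
    assign = ClusterAssignment(algorithm=backend, labels=labels,
                               n_clusters_requested=n_clusters).compact()
    accs = {name: hungarian_acc(assign, truth, mode=mode)
            for name, truth in truths.items()}
    return assign, accs


def consensus_pairs(
    assignments: Sequence[ClusterAssignment],
    meta: Sequence[SampleMeta],
    min_votes: int | None = None,
) -> list[tuple[int, int, int]]:
    """Cross-domain sample pairs co-clustered by a majority of assignments.

    Returns (i, j, votes) for pairs with domain(i) != domain(j) co-clustered
    (same non-noise label) in at least ``min_votes`` assignments (default:
    strict majority).
    """
    if len(assignments) < 2:
        raise ValueError("need at least two assignments for a consensus")
    m = len(assignments)
    if min_votes is None:
        min_votes = m // 2 + 1
    n = len(meta)
    votes = np.zeros((n, n), dtype=np.int32)
    for a in assignments:
        lab = a.labels
        for c in np.unique(lab[lab >= 0]):
            idx = np.flatnonzero(lab == c)
            votes[np.ix_(idx, idx)] += 1
    domains = np.array([s.domain for s in meta])
    out = []
    for i, j in combinations(range(n), 2):
        if domains[i] != domains[j] and votes[i, j] >= min_votes:
            out.append((i, j, int(votes[i, j])))
    return out
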