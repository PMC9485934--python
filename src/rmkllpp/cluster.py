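"""Subtype discovery on the embedding: k-means with silhouette-based model
selection, and survival-driven merging of clusters whose outcomes are
statistically indistinguishable.

The merging rule formalizes the common practice of collapsing clusters with
overlapping survival curves: all pairwise log-rank tests are computed among
the initial clusters, pairs with p > alpha are connected, and the connected
components of that graph become the merged subtypes, renumbered by
ascending 3-year mortality (label 1 = best prognosis). Merging is optional
and recorded in the result so it is fully auditable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .survival import DAYS_PER_YEAR, logrank_test, mortality_at

__all__ = [
    "SubtypeResult",
    "SilhouetteKMeans",
    "kmeans_cluster",
    "select_k_by_silhouette",
    "merge_subtypes_by_survival",
]

logger = logging.getLogger(__name__)


@dataclass
class SubtypeResult:
    """Subtype labels before and after survival-based merging.

    Labels are contiguous integers starting at 1. ``merge_map`` sends each
    initial label to its merged label; when no merging was performed it is
    the identity.
    """

    initial_labels: np.ndarray
    k_selected: int
    silhouette_by_k: dict = field(default_factory=dict)
    merged_labels: np.ndarray | None = None
    merge_map: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.merged_labels is None:
            self.merged_labels = self.initial_labels.copy()
            self.merge_map = {int(l): int(l) for l in np.unique(self.initial_labels)}

    @property
    def n_merged(self) -> int:
        return len(np.unique(self.merged_labels))


class SilhouetteKMeans(ClusterMixin, BaseEstimator):
    """k-means with the cluster number chosen by mean silhouette.

    Runs k-means (k-means++ seeding, best of ``n_init`` restarts) for every
    k in ``k_range`` and keeps the k maximizing the mean silhouette
    coefficient in the clustering space (Euclidean); ties break toward
    smaller k. Each k uses its own deterministic RNG stream derived from
    ``random_state``.

    Attributes
    ----------
    labels_ : ndarray
        1-based cluster labels at the selected k.
    k_ : int
    silhouette_by_k_ : dict mapping k -> mean silhouette
    """

    def __init__(self, k_range=(2, 10), n_init: int = 50, random_state: int = 0):
        self.k_range = k_range
        self.n_init = n_init
        self.random_state = random_state

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        n = X.shape[0]
        k_lo, k_hi = int(self.k_range[0]), int(self.k_range[1])
        if not 2 <= k_lo <= k_hi <= n - 1:
            raise ValueError(f"k_range must lie within [2, {n - 1}]")
        if np.allclose(X, X[0]):
            raise ValueError("degenerate coordinates: all samples identical")
        scores: dict[int, float] = {}
        labels_by_k: dict[int, np.ndarray] = {}
        for k in range(k_lo, k_hi + 1):
            labels = kmeans_cluster(X, k, self.n_init, self.random_state + k)
            labels_by_k[k] = labels
            scores[k] = float(silhouette_score(X, labels, metric="euclidean"))
        # argmax with ties toward smaller k (dict preserves ascending k order)
        best_k = max(scores, key=lambda k: (scores[k], -k))
        self.k_ = best_k
        self.labels_ = labels_by_k[best_k]
        self.silhouette_by_k_ = scores
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


def kmeans_cluster(coords: np.ndarray, k: int, n_init: int = 50, seed: int = 0) -> np.ndarray:
    """Best-of-n_init k-means labels (1-based), deterministic given seed."""
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    if not 2 <= k <= n:
        raise ValueError(f"k must be in [2, {n}]")
    km = KMeans(n_clusters=k, n_init=n_init, init="k-means++", random_state=seed)
    return km.fit_predict(coords) + 1


def select_k_by_silhouette(
    coords: np.ndarray, k_range=(2, 10), n_init: int = 50, seed: int = 0
) -> SubtypeResult:
    """Cluster at every k in k_range and keep the silhouette argmax."""
    est = SilhouetteKMeans(k_range=k_range, n_init=n_init, random_state=seed).fit(coords)
    return SubtypeResult(
        initial_labels=est.labels_, k_selected=est.k_, silhouette_by_k=est.silhouette_by_k_
    )


def _component_mortality(surv: pd.DataFrame, member_mask: np.ndarray, horizon: float) -> float:
    return mortality_at(
        surv.loc[member_mask, "time"].to_numpy(),
        surv.loc[member_mask, "event"].to_numpy(),
        horizon,
    )


def merge_subtypes_by_survival(
    initial_labels: np.ndarray,
    surv: pd.DataFrame,
    alpha: float = 0.05,
    horizon_years: float = 3.0,
) -> SubtypeResult:
    """Merge clusters whose survival curves are statistically alike.

    Pairwise log-rank tests among the initial clusters define a graph with
    an edge for every pair with p > alpha; merged subtypes are the
    connected components, renumbered 1..G by ascending Kaplan–Meier
    mortality at ``horizon_years``. Clusters with fewer than 2 samples are
    attached to the component with the nearest horizon mortality (with a
    logged warning).
    """
    initial_labels = np.asarray(initial_labels)
    if len(initial_labels) != len(surv):
        raise ValueError("labels and survival table have different lengths")
    if surv[["time", "event"]].isna().any().any():
        raise ValueError("every sample needs survival data")
    uniq = np.unique(initial_labels)
    idx = {lab: i for i, lab in enumerate(uniq)}
    small = [lab for lab in uniq if (initial_labels == lab).sum() < 2]
    testable = [lab for lab in uniq if lab not in small]
    horizon = horizon_years * DAYS_PER_YEAR

    times = surv["time"].to_numpy()
    events = surv["event"].to_numpy()
    edges_i, edges_j = [], []
    for a, b in combinations(testable, 2):
        mask = np.isin(initial_labels, [a, b])
        _, p = logrank_test(times[mask], events[mask], initial_labels[mask])
        if p > alpha:
            edges_i.append(idx[a])
            edges_j.append(idx[b])
    g = len(uniq)
    adj = csr_matrix(
        (np.ones(len(edges_i)), (edges_i, edges_j)), shape=(g, g)
    )
    n_comp, comp = connected_components(adj, directed=False)

    # attach tiny clusters to the nearest-mortality component
    comp = comp.copy()
    if small:
        logger.warning("clusters below size 2 merged by nearest survival: %s", small)
        comp_mort = {}
        for c in np.unique(comp[[idx[lab] for lab in testable]]) if testable else []:
            members = np.isin(initial_labels, [lab for lab in testable if comp[idx[lab]] == c])
            comp_mort[c] = _component_mortality(surv, members, horizon)
        for lab in small:
            if not comp_mort:
                break
            m = _component_mortality(surv, initial_labels == lab, horizon)
            nearest = min(comp_mort, key=lambda c: abs(comp_mort[c] - m))
            comp[idx[lab]] = nearest

    # renumber components by ascending horizon mortality
    comp_ids = np.unique(comp)
    mort = {}
    for c in comp_ids:
        members = np.isin(initial_labels, [lab for lab in uniq if comp[idx[lab]] == c])
        mort[c] = _component_mortality(surv, members, horizon)
    order = sorted(comp_ids, key=lambda c: mort[c])
    renum = {c: i + 1 for i, c in enumerate(order)}
    merge_map = {int(lab): renum[comp[idx[lab]]] for lab in uniq}
    merged = np.array([merge_map[int(l)] for l in initial_labels])
    return SubtypeResult(
        initial_labels=initial_labels,
        k_selected=len(uniq),
        merged_labels=merged,
        merge_map=merge_map,
    )
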