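"""k-means clustering of expression dynamics and category labelling.

Genes deregulated by perturbation A are clustered on their z-scored
expression profiles across the four conditions (replicate columns by
default).  Each cluster centroid is then read as a dynamic: the contrast
deltas ``d1 = mean(A) - mean(control)`` and ``d2 = mean(AB) - mean(A)``
determine whether the cluster behaves like a putative oncogene set
(up in A, pulled down when B is added), a putative tumor-suppressor set
(the mirror image), a not-reversed set (moved by A, unchanged by adding
B), or something else.  The category map — not cluster identity, which
depends on k and the seed — is the meaningful output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score

from revertome.reversal import CATEGORIES

DEFAULT_K = 12
DEFAULT_EPSILON = 0.25  # z-units


@dataclass
class ClusterModel:
    """Fitted k-means model over gene profiles."""

    k: int
    assignments: pd.Series  # gene -> cluster id (0-based)
    centroids: np.ndarray  # k x d
    inertia: float
    seed: int
    n_init: int
    converged: bool
    columns: list[str] = field(default_factory=list)

    def recomputed_inertia(self, profiles: pd.DataFrame) -> float:
        x = profiles.to_numpy(dtype=float)
        lab = self.assignments.reindex(profiles.index).to_numpy()
        return float(((x - self.centroids[lab]) ** 2).sum())


@dataclass
class ClusterCategoryMap:
    """Cluster -> dynamic category, with centroid contrast directions."""

    categories: dict[int, str]
    directions: dict[int, dict[str, float]]
    epsilon: float

    def gene_categories(self, assignments: pd.Series) -> pd.Series:
        return assignments.map(self.categories).rename("category")

    def shares(self, assignments: pd.Series) -> dict[str, float]:
        """Fraction of clustered genes per category."""
        cats = self.gene_categories(assignments)
        n = len(cats)
        return {c: float((cats == c).sum()) / n if n else 0.0 for c in CATEGORIES}


def kmeans(
    profiles: pd.DataFrame,
    k: int = DEFAULT_K,
    seed: int = 0,
    n_init: int = 10,
    max_iter: int = 300,
    tol: float = 1e-4,
) -> ClusterModel:
    """Lloyd k-means with k-means++ seeding, best of ``n_init`` restarts.

    Deterministic given the seed.  Raises if ``k`` exceeds the number of
    distinct profile rows (the objective would be degenerate).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if n_init < 1:
        raise ValueError("n_init must be >= 1")
    x = profiles.to_numpy(dtype=float)
    n_distinct = np.unique(x, axis=0).shape[0]
    if k > n_distinct:
        raise ValueError(
            f"k={k} exceeds the number of distinct profiles ({n_distinct})"
        )
    km = KMeans(
        n_clusters=k,
        init="k-means++",
        n_init=n_init,
        max_iter=max_iter,
        tol=tol,
        random_state=seed,
        algorithm="lloyd",
    ).fit(x)
    return ClusterModel(
        k=k,
        assignments=pd.Series(km.labels_, index=profiles.index, name="cluster"),
        centroids=km.cluster_centers_,
        inertia=float(km.inertia_),
        seed=seed,
        n_init=n_init,
        converged=bool(km.n_iter_ < max_iter),
        columns=list(profiles.columns),
    )


def label_clusters(
    model: ClusterModel,
    conditions: list[str] | pd.Series,
    epsilon: float = DEFAULT_EPSILON,
) -> ClusterCategoryMap:
    """Map each cluster to a dynamic category from its centroid.

    ``conditions`` gives the condition of each centroid column (length d,
    values among control/A/B/AB).  With condition means ``c_control, c_A,
    c_B, c_AB`` and ``d1 = c_A - c_control``, ``d2 = c_AB - c_A``:

    * ``putative_oncogene``   iff d1 >  eps and d2 < -eps
    * ``putative_suppressor`` iff d1 < -eps and d2 >  eps
    * ``not_reversed``        iff |d1| > eps and |d2| <= eps
    * ``other`` otherwise.
    """
    if epsilon < 0:
        raise ValueError("epsilon must be >= 0")
    conditions = list(conditions)
    if len(conditions) != model.centroids.shape[1]:
        raise ValueError(
            f"conditions has length {len(conditions)} but centroids have "
            f"{model.centroids.shape[1]} columns"
        )
    required = {"control", "A", "AB"}
    missing = required - set(conditions)
    if missing:
        raise ValueError(f"design missing conditions: {sorted(missing)}")

    cond_arr = np.asarray(conditions)
    categories: dict[int, str] = {}
    directions: dict[int, dict[str, float]] = {}
    for ci in range(model.k):
        centroid = model.centroids[ci]
        means = {c: float(centroid[cond_arr == c].mean()) for c in set(conditions)}
        d1 = means["A"] - means["control"]
        d2 = means["AB"] - means["A"]
        d_b = means.get("B", means["control"]) - means["control"]
        if d1 > epsilon and d2 < -epsilon:
            cat = "putative_oncogene"
        elif d1 < -epsilon and d2 > epsilon:
            cat = "putative_suppressor"
        elif abs(d1) > epsilon and abs(d2) <= epsilon:
            cat = "not_reversed"
        else:
            cat = "other"
        categories[ci] = cat
        directions[ci] = {
            "A_minus_control": d1,
            "AB_minus_A": d2,
            "B_minus_control": d_b,
        }
    return ClusterCategoryMap(categories=categories, directions=directions, epsilon=epsilon)


def cluster_agreement(assignments, truth_labels) -> float:
    """Adjusted Rand index between two labelings of the same genes."""
    a = np.asarray(assignments)
    b = np.asarray(truth_labels)
    if a.shape != b.shape:
        raise ValueError(f"label vectors differ in length: {a.shape} vs {b.shape}")
    return float(adjusted_rand_score(a, b))
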