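"""Correlation-based feature selection.

The robust features are clustered with average-linkage hierarchical
clustering on the distance ``1 - |r|`` (Pearson correlation across all
lesions), the tree is cut at a fixed number of clusters (default 8, a
config parameter — no automatic cut is attempted), and one representative
per cluster is kept: the highest-ranked member of a user preference list,
or the lexicographically first member.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .errors import InsufficientDataError
from .heterogeneity import feature_columns

__all__ = ["FeatureClustering", "cluster_features", "select_representatives"]


@dataclass
class FeatureClustering:
    """Partition of the kept features into correlation clusters.

    ``assignment`` maps feature -> cluster id (0-based, contiguous);
    constant (zero-variance) features get their own singleton clusters and
    are listed in ``constant_features``.  ``linkage`` is the scipy linkage
    matrix over the non-constant features (None if fewer than 2).
    """

    n_clusters: int
    assignment: dict[str, int]
    linkage: np.ndarray | None = None
    constant_features: list[str] = field(default_factory=list)

    def clusters(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for f, c in self.assignment.items():
            out.setdefault(c, []).append(f)
        return {c: sorted(members) for c, members in sorted(out.items())}


def cluster_features(table: pd.DataFrame, k: int = 8, linkage_method: str = "average",
                     correlation: str = "pearson") -> FeatureClustering:
    """Cut the ``1 - |r|`` average-linkage dendrogram at exactly ``k`` clusters.

    Constant features have undefined correlation; each is flagged and put
    in its own singleton cluster on top of the ``k`` correlation clusters.
    """
    feats = feature_columns(table)
    if len(table) < 3:
        raise InsufficientDataError("clustering needs >= 3 lesions")
    X = table[feats].to_numpy(dtype=np.float64)
    variances = X.var(axis=0)
    constant = [f for f, v in zip(feats, variances) if v == 0]
    active = [f for f in feats if f not in constant]
    if len(active) < k:
        raise InsufficientDataError(
            f"{len(active)} non-constant features < k={k} clusters"
        )
    corr = table[active].corr(method=correlation).to_numpy()
    dist = 1.0 - np.abs(corr)
    np.fill_diagonal(dist, 0.0)
    dist = np.clip(0.5 * (dist + dist.T), 0.0, None)
    Z = hierarchy.linkage(squareform(dist, checks=False), method=linkage_method)
    flat = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    # relabel cluster ids deterministically by first (sorted) member
    order: dict[int, int] = {}
    assignment: dict[str, int] = {}
    for f in sorted(active):
        c = int(flat[active.index(f)])
        if c not in order:
            order[c] = len(order)
        assignment[f] = order[c]
    next_id = len(order)
    for f in sorted(constant):
        assignment[f] = next_id
        next_id += 1
    return FeatureClustering(
        n_clusters=next_id, assignment=assignment, linkage=Z,
        constant_features=sorted(constant),
    )


def select_representatives(clustering: FeatureClustering,
                           preference=()) -> list[str]:
    """One representative feature per cluster.

    Within each cluster the highest-ranked member of ``preference`` wins
    (earlier in the list = more interpretable, e.g. tumor volume before a
    gray level non-uniformity index); clusters with no preferred member
    fall back to lexicographic order.
    """
    pref_rank = {name: i for i, name in enumerate(preference)}
    reps = []
    for _, members in clustering.clusters().items():
        preferred = [m for m in members if m in pref_rank]
        if preferred:
            reps.append(min(preferred, key=lambda m: pref_rank[m]))
        else:
            reps.append(min(members))
    return reps
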