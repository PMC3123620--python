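"""Hierarchical clustering of samples as an unsupervised classifier.

Samples are compared by Euclidean distance over a signature's features,
merged bottom-up with average linkage (UPGMA: the distance between two
clusters is the unweighted mean of all cross-cluster pairwise distances),
and a dendrogram cut into k clusters is scored against the tissue-class
annotation by majority vote — each cluster is labeled with its most
frequent class and minority members count as misplaced.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import squareform

__all__ = [
    "Dendrogram",
    "ClusterAssignment",
    "distance_matrix",
    "average_linkage",
    "cut_tree",
    "score_assignment",
]


@dataclass
class Dendrogram:
    """A UPGMA merge history over labeled leaves (scipy linkage encoding)."""

    linkage: np.ndarray  # (n-1, 4) scipy format; heights non-decreasing
    labels: list[str]

    def to_newick(self) -> str:
        """Serialize as a newick string with merge heights as branch lengths."""
        tree = sch.to_tree(self.linkage)

        def walk(node) -> str:
            if node.is_leaf():
                return self.labels[node.id]
            left, right = node.get_left(), node.get_right()
            lb = node.dist - (0 if left.is_leaf() else left.dist)
            rb = node.dist - (0 if right.is_leaf() else right.dist)
            return f"({walk(left)}:{lb:g},{walk(right)}:{rb:g})"

        return walk(tree) + ";"


@dataclass
class ClusterAssignment:
    """Sample -> cluster index (1..k), with majority-class scoring slots."""

    assignment: pd.Series  # index sample_id, values 1..k
    majority_class: dict[int, str] | None = None
    misplaced: list[str] | None = None
    ties: list[int] | None = None

    @property
    def k(self) -> int:
        return int(self.assignment.nunique())


def distance_matrix(m: pd.DataFrame, features) -> pd.DataFrame:
    """Pairwise Euclidean distances between samples over signature features.

    With missing wells, each pair's distance uses the mutually non-missing
    features and is rescaled by sqrt(n_total / n_used) to stay comparable.
    """
    features = list(features)
    absent = [f for f in features if f not in m.index]
    if absent:
        raise KeyError(f"signature features absent from matrix: {absent}")
    x = m.loc[features].to_numpy(dtype=float).T  # samples x features
    n_samp, n_tot = x.shape
    d = np.zeros((n_samp, n_samp))
    for i in range(n_samp):
        for j in range(i + 1, n_samp):
            both = ~np.isnan(x[i]) & ~np.isnan(x[j])
            used = both.sum()
            if used == 0:
                raise ValueError(
                    f"samples {m.columns[i]!r} and {m.columns[j]!r} share no "
                    "non-missing signature features"
                )
            diff = x[i, both] - x[j, both]
            d[i, j] = d[j, i] = np.sqrt(np.sum(diff**2) * (n_tot / used))
    return pd.DataFrame(d, index=m.columns.copy(), columns=m.columns.copy())


def average_linkage(d: pd.DataFrame) -> Dendrogram:
    """UPGMA clustering of a symmetric, non-negative distance matrix."""
    vals = d.to_numpy(dtype=float)
    if vals.shape[0] < 2:
        raise ValueError("clustering needs at least 2 samples")
    if not np.allclose(vals, vals.T) or np.any(np.diag(vals) != 0):
        raise ValueError("distance matrix must be symmetric with zero diagonal")
    if np.any(vals < 0):
        raise ValueError("distances must be non-negative")
    z = sch.linkage(squareform(vals, checks=False), method="average")
    return Dendrogram(z, list(d.index))


def cut_tree(t: Dendrogram, k: int) -> ClusterAssignment:
    """Cut into exactly k clusters by undoing the last k-1 merges."""
    n = len(t.labels)
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    flat = sch.cut_tree(t.linkage, n_clusters=k).ravel()
    # relabel clusters 1..k in order of first appearance, for stable output
    remap: dict[int, int] = {}
    out = np.empty(n, dtype=int)
    for i, c in enumerate(flat):
        if c not in remap:
            remap[c] = len(remap) + 1
        out[i] = remap[c]
    return ClusterAssignment(pd.Series(out, index=pd.Index(t.labels, name="sample_id")))


def score_assignment(
    c: ClusterAssignment, a: pd.DataFrame
) -> tuple[int, float, ClusterAssignment]:
    """Majority-vote scoring of a cluster assignment against tissue classes.

    Per cluster, the majority ``tissue_class`` is the label; members of the
    minority class are misplaced.  A tied cluster (equal class counts) is
    conservatively scored against the cohort-wide majority class and
    recorded in ``ties``.  Returns ``(misplaced count, error rate,
    annotated assignment)``.
    """
    missing = [s for s in c.assignment.index if s not in a.index]
    if missing:
        raise KeyError(f"samples lack annotation: {missing}")
    classes = a.loc[c.assignment.index, "tissue_class"]
    global_majority = classes.mode().iloc[0]
    majority: dict[int, str] = {}
    misplaced: list[str] = []
    ties: list[int] = []
    for cl in sorted(c.assignment.unique()):
        members = c.assignment.index[c.assignment == cl]
        counts = classes.loc[members].value_counts()
        if len(counts) > 1 and counts.iloc[0] == counts.iloc[1]:
            ties.append(int(cl))
            label = global_majority
        else:
            label = counts.index[0]
        majority[int(cl)] = label
        misplaced.extend(s for s in members if classes.loc[s] != label)
    n = len(c.assignment)
    scored = ClusterAssignment(c.assignment, majority, misplaced, ties)
    return len(misplaced), len(misplaced) / n, scored
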