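"""PCA of signature expression and unsupervised subgroup discovery.

:func:`pca` projects samples onto principal components of their
feature-standardized signature expression, for confirming a two-class
separation visually or numerically.

:func:`subgroup_sweep` searches for substructure among one class of samples
(typically the malignant ones) by gradually tightening a per-feature
p-value threshold — a one-way F-test across the levels of a grouping
variable such as Gleason score — and at each threshold projecting the
retained features with PCA and partitioning the sample scores into as many
k-means groups as there are levels.  The sweep reports the most permissive
threshold whose grouping best matches the known levels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as st
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

__all__ = ["PCAResult", "SubgroupSweepResult", "pca", "feature_group_pvalues", "subgroup_sweep"]


@dataclass
class PCAResult:
    scores: pd.DataFrame  # samples x components
    loadings: pd.DataFrame  # features x components
    variance_explained: np.ndarray  # fraction per component, non-increasing
    dropped_features: list[str] = field(default_factory=list)


@dataclass
class SubgroupSweepResult:
    threshold: float
    feature_ids: list[str]
    assignment: pd.Series  # sample -> subgroup index
    misplaced: list[str]
    trace: pd.DataFrame  # per threshold: n_features, misplaced count


def pca(m: pd.DataFrame, features, n_components: int | None = None) -> PCAResult:
    """PCA of samples over (centered, unit-variance) signature features.

    Zero-variance features are dropped with a warning.  Loading signs are
    fixed so each component's largest-magnitude loading is positive.
    """
    features = list(features)
    x = m.loc[features].to_numpy(dtype=float).T  # samples x features
    if np.isnan(x).any():
        raise ValueError("PCA input contains missing values; impute or subset first")
    sd = x.std(axis=0, ddof=1)
    keep = sd > 0
    dropped = [f for f, k in zip(features, keep) if not k]
    if dropped:
        warnings.warn(f"dropping zero-variance features: {dropped}", stacklevel=2)
        features = [f for f, k in zip(features, keep) if k]
        x = x[:, keep]
        sd = sd[keep]
    z = (x - x.mean(axis=0)) / sd
    n_comp = min(n_components or min(z.shape), *z.shape)
    model = PCA(n_components=n_comp, svd_solver="full")
    scores = model.fit_transform(z)
    loadings = model.components_.T  # features x components
    # sign convention: largest |loading| per component is positive
    for j in range(loadings.shape[1]):
        i = np.argmax(np.abs(loadings[:, j]))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    comp_names = [f"PC{j + 1}" for j in range(n_comp)]
    return PCAResult(
        scores=pd.DataFrame(scores, index=m.columns.copy(), columns=comp_names),
        loadings=pd.DataFrame(loadings, index=features, columns=comp_names),
        variance_explained=model.explained_variance_ratio_,
        dropped_features=dropped,
    )


def feature_group_pvalues(m: pd.DataFrame, groups: pd.Series) -> pd.Series:
    """One-way F-test p per feature across the levels of ``groups``.

    Features with fewer than two levels represented among their non-missing
    wells, or with no within-group variance, get ``NaN``.
    """
    levels = groups.dropna().unique()
    if len(levels) < 2:
        raise ValueError("grouping variable must have at least 2 levels")
    p = pd.Series(np.nan, index=m.index.copy(), name="p_group")
    cols = groups.dropna().index
    sub = m[cols]
    for fid, row in sub.iterrows():
        arrays = [
            row[groups[cols] == lv].dropna().to_numpy()
            for lv in levels
        ]
        arrays = [x for x in arrays if x.size >= 2]
        if len(arrays) < 2:
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            stat, pv = st.f_oneway(*arrays)
        if np.isfinite(pv):
            p.loc[fid] = pv
    return p


def subgroup_sweep(
    m: pd.DataFrame,
    a: pd.DataFrame,
    grouping_variable: str = "gleason_score",
    thresholds=None,
    n_components: int = 2,
    n_restarts: int = 50,
    seed: int = 0,
) -> SubgroupSweepResult:
    """Descending p-threshold sweep for subgroup structure.

    Operates on the samples whose ``grouping_variable`` is non-missing
    (pass a malignant-only annotation for tumor subgrouping).  For each
    threshold: keep features with F-test p below it, project with PCA,
    k-means the top ``n_components`` scores into g = #levels groups, and
    count misplaced samples (cluster majority level differs from the
    sample's own).  Thresholds retaining fewer than 2 complete features are
    skipped.  Returns the largest threshold attaining the minimal misplaced
    count, with the full sweep trace.
    """
    groups = a[grouping_variable].dropna()
    if groups.nunique() < 2:
        raise ValueError(f"{grouping_variable!r} must have at least 2 levels")
    samples = [s for s in m.columns if s in groups.index]
    sub = m[samples]
    groups = groups.loc[samples]
    g = groups.nunique()

    if thresholds is None:
        thresholds = np.geomspace(0.05, 1e-4, 40)
    thresholds = sorted(set(float(t) for t in thresholds), reverse=True)

    pvals = feature_group_pvalues(sub, groups)
    rows = []
    best: tuple[int, float, list[str], pd.Series, list[str]] | None = None
    for thr in thresholds:
        feats = [f for f in sub.index if pvals.get(f, np.nan) < thr]
        # PCA needs complete rows; restrict to features with no missing wells
        feats = [f for f in feats if not sub.loc[f].isna().any()]
        if len(feats) < 2:
            warnings.warn(f"threshold {thr:g} leaves <2 usable features; skipped", stacklevel=2)
            continue
        res = pca(sub, feats, n_components=min(n_components, len(feats), len(samples)))
        scores = res.scores.iloc[:, : n_components]
        km = KMeans(n_clusters=g, n_init=n_restarts, random_state=seed % (2**31))
        labels = km.fit_predict(scores.to_numpy())
        assignment = pd.Series(labels + 1, index=scores.index)
        misplaced = _score_subgroups(assignment, groups)
        rows.append((thr, len(feats), len(misplaced)))
        if best is None or len(misplaced) < best[0]:
            best = (len(misplaced), thr, feats, assignment, misplaced)
    if best is None:
        raise ValueError("no threshold in the sweep retained >= 2 usable features")
    trace = pd.DataFrame(rows, columns=["threshold", "n_features", "misplaced"]).set_index(
        "threshold"
    )
    _, thr, feats, assignment, misplaced = best
    return SubgroupSweepResult(thr, feats, assignment, misplaced, trace)


def _score_subgroups(assignment: pd.Series, groups: pd.Series) -> list[str]:
    """Samples whose cluster's majority level differs from their own level."""
    misplaced: list[str] = []
    for cl in sorted(assignment.unique()):
        members = assignment.index[assignment == cl]
        counts = groups.loc[members].value_counts()
        label = counts.index[0]
        misplaced.extend(s for s in members if groups.loc[s] != label)
    return misplaced
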