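"""Coarse feature selection: redundancy clustering and six feature rankers.

The coarse stage prunes a large reproducible-feature pool to at most
``top_k`` candidates per ranking method: features are grouped into redundant
clusters by hierarchical (complete-linkage) clustering of their pairwise
association, each ranker keeps only the top-scoring member of every cluster,
and the pruned list is truncated to the top ten.

Rankers: ReliefF (k = 5 neighbors, standardized features), chi-square on
quartile-binned features, mRMR (mutual-information difference, greedy),
pooled-variance |t|, standardized Wilcoxon rank-sum |z|, and univariate
threshold accuracy. Ties are broken by lexicographic feature name for
determinism.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .io_core import FeatureTable
from .reproducibility import ccc

__all__ = [
    "RANKERS",
    "ClusterAssignment",
    "RankedList",
    "correlation_clusters",
    "rank_features",
    "coarse_select",
]

RANKERS = ("relief", "chi2", "mrmr", "ttest", "wilcoxon", "univacc")


@dataclass
class ClusterAssignment:
    assignment: dict[str, int]
    threshold: float

    def clusters(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for name, cid in self.assignment.items():
            out.setdefault(cid, []).append(name)
        return out


@dataclass
class RankedList:
    """One ranker's ordered candidate features (descending score)."""

    method: str
    features: list[str]
    scores: list[float]


# ---------------------------------------------------------------------------
# Redundancy clustering
# ---------------------------------------------------------------------------

def _association_matrix(values: np.ndarray, measure: str) -> np.ndarray:
    p = values.shape[1]
    if measure == "pearson":
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.corrcoef(values, rowvar=False)
        r = np.abs(np.nan_to_num(r, nan=0.0))
    elif measure == "ccc":
        r = np.eye(p)
        for i in range(p):
            for j in range(i + 1, p):
                xi, xj = values[:, i], values[:, j]
                if xi.var() == 0 or xj.var() == 0:
                    v = 0.0
                else:
                    v = abs(ccc(xi, xj))
                r[i, j] = r[j, i] = v
    else:
        raise ValueError(f"unknown association measure {measure!r}")
    np.fill_diagonal(r, 1.0)
    return np.clip(r, 0.0, 1.0)


def correlation_clusters(
    table: FeatureTable,
    threshold: float = 0.8,
    measure: str = "pearson",
) -> ClusterAssignment:
    """Group features into redundant clusters by their mutual association.

    Complete-linkage agglomerative clustering on distance 1 - |r| cut at
    1 - threshold, so every within-cluster pair has |r| strictly above the
    threshold. ``measure`` is "pearson" (default) or "ccc". A constant
    feature is given zero association with every other feature (it forms a
    singleton) with a warning.
    """
    if table.n_patients < 2:
        raise ValueError("need at least two patients")
    constant = [
        name
        for j, name in enumerate(table.feature_names)
        if table.values[:, j].var() == 0
    ]
    if constant:
        warnings.warn(
            f"constant features assigned singleton clusters: {constant}", stacklevel=2
        )
    if table.n_features == 1:
        return ClusterAssignment({table.feature_names[0]: 1}, threshold)
    r = _association_matrix(table.values, measure)
    dist = 1.0 - r
    np.fill_diagonal(dist, 0.0)
    condensed = squareform(np.maximum(dist, 0.0), checks=False)
    tree = linkage(condensed, method="complete")
    cut = (1.0 - threshold) - 1e-12
    labels = fcluster(tree, t=max(cut, -1.0), criterion="distance")
    return ClusterAssignment(
        {name: int(cid) for name, cid in zip(table.feature_names, labels)}, threshold
    )


# ---------------------------------------------------------------------------
# Rankers
# ---------------------------------------------------------------------------

def _quartile_bins(x: np.ndarray) -> np.ndarray:
    edges = np.unique(np.quantile(x, [0.25, 0.5, 0.75]))
    return np.digitize(x, edges)


def _mutual_information(a: np.ndarray, b: np.ndarray) -> float:
    """Discrete mutual information (nats) from the joint contingency table."""
    ua, ia = np.unique(a, return_inverse=True)
    ub, ib = np.unique(b, return_inverse=True)
    joint = np.zeros((ua.size, ub.size))
    np.add.at(joint, (ia, ib), 1.0)
    joint /= joint.sum()
    pa = joint.sum(axis=1, keepdims=True)
    pb = joint.sum(axis=0, keepdims=True)
    nz = joint > 0
    return float((joint[nz] * np.log(joint[nz] / (pa @ pb)[nz])).sum())


def _relief_scores(values: np.ndarray, labels: np.ndarray, k: int = 5) -> np.ndarray:
    """Relief-F weights with k nearest hits/misses, all samples used."""
    x = values.copy()
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    x = (x - x.mean(axis=0)) / sd
    rng_span = x.max(axis=0) - x.min(axis=0)
    rng_span[rng_span == 0] = 1.0
    n, p = x.shape
    d2 = ((x[:, None, :] - x[None, :, :]) ** 2).sum(axis=2)
    np.fill_diagonal(d2, np.inf)
    weights = np.zeros(p)
    for i in range(n):
        same = np.nonzero(labels == labels[i])[0]
        same = same[same != i]
        other = np.nonzero(labels != labels[i])[0]
        kh = min(k, same.size)
        km = min(k, other.size)
        if kh == 0 or km == 0:
            continue
        hits = same[np.argsort(d2[i, same])[:kh]]
        misses = other[np.argsort(d2[i, other])[:km]]
        weights += (
            np.abs(x[i] - x[misses]).mean(axis=0) - np.abs(x[i] - x[hits]).mean(axis=0)
        ) / rng_span
    return weights / n


def _univariate_accuracy(x: np.ndarray, y: np.ndarray) -> float:
    """Best resubstitution accuracy of a single-threshold classifier,
    both orientations swept over all cut points."""
    order = np.argsort(x, kind="stable")
    xs, ys = x[order], y[order]
    n = len(y)
    # thresholds between consecutive distinct values, plus the extremes
    cuts = np.concatenate(([xs[0] - 1.0], (xs[:-1] + xs[1:]) / 2.0, [xs[-1] + 1.0]))
    preds = x[:, None] > cuts[None, :]
    acc_pos = (preds == (y[:, None] == 1)).mean(axis=0)
    best = max(float(acc_pos.max()), float((1.0 - acc_pos).max()))
    return best


def rank_features(table: FeatureTable, labels: np.ndarray | None = None, method: str = "ttest") -> RankedList:
    """Score and order all features of a table by one ranking method.

    Scores are descending; ties are broken lexicographically by feature
    name. For mRMR the order is the greedy selection order and the score is
    the (descending) selection rank, since the greedy criterion itself is
    not monotone.
    """
    labels = np.asarray(table.labels if labels is None else labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")
    if method not in RANKERS:
        raise ValueError(f"unknown ranking method {method!r}; expected one of {RANKERS}")
    values = table.values
    names = table.feature_names
    pos = values[labels == 1]
    neg = values[labels == 0]

    if method == "relief":
        scores = _relief_scores(values, labels)
    elif method == "ttest":
        with np.errstate(invalid="ignore", divide="ignore"):
            t, _ = stats.ttest_ind(pos, neg, axis=0, equal_var=True)
        scores = np.abs(np.nan_to_num(t, nan=0.0))
    elif method == "wilcoxon":
        scores = np.empty(len(names))
        for j in range(len(names)):
            z, _ = stats.ranksums(pos[:, j], neg[:, j])
            scores[j] = abs(z)
    elif method == "chi2":
        scores = np.empty(len(names))
        for j in range(len(names)):
            binned = _quartile_bins(values[:, j])
            contingency = np.zeros((np.max(binned) + 1, 2))
            np.add.at(contingency, (binned, labels), 1.0)
            contingency = contingency[contingency.sum(axis=1) > 0]
            if contingency.shape[0] < 2:
                scores[j] = 0.0
            else:
                scores[j] = stats.chi2_contingency(contingency, correction=False).statistic
    elif method == "univacc":
        scores = np.array([_univariate_accuracy(values[:, j], labels) for j in range(len(names))])
    elif method == "mrmr":
        return _mrmr_ranking(table, labels)

    order = sorted(range(len(names)), key=lambda j: (-scores[j], names[j]))
    return RankedList(
        method=method,
        features=[names[j] for j in order],
        scores=[float(scores[j]) for j in order],
    )


def _mrmr_ranking(table: FeatureTable, labels: np.ndarray) -> RankedList:
    """Greedy mutual-information-difference (MID) ordering on quartile bins."""
    names = table.feature_names
    p = len(names)
    binned = [_quartile_bins(table.values[:, j]) for j in range(p)]
    relevance = np.array([_mutual_information(binned[j], labels) for j in range(p)])
    pairwise = np.full((p, p), np.nan)
    selected: list[int] = []
    remaining = sorted(range(p), key=lambda j: (-relevance[j], names[j]))
    first = remaining.pop(0)
    selected.append(first)
    while remaining:
        best_j, best_score = None, -np.inf
        for j in remaining:
            red = 0.0
            for s in selected:
                if np.isnan(pairwise[j, s]):
                    pairwise[j, s] = pairwise[s, j] = _mutual_information(binned[j], binned[s])
                red += pairwise[j, s]
            score = relevance[j] - red / len(selected)
            if score > best_score + 1e-15 or (
                abs(score - best_score) <= 1e-15 and best_j is not None and names[j] < names[best_j]
            ):
                best_j, best_score = j, score
        selected.append(best_j)
        remaining.remove(best_j)
    return RankedList(
        method="mrmr",
        features=[names[j] for j in selected],
        scores=[float(p - i) for i in range(p)],
    )


# ---------------------------------------------------------------------------
# Coarse selection
# ---------------------------------------------------------------------------

def coarse_select(
    table: FeatureTable,
    labels: np.ndarray | None = None,
    threshold: float = 0.8,
    top_k: int = 10,
    measure: str = "pearson",
) -> dict[str, RankedList]:
    """Redundancy-pruned top-k candidate list for each of the six rankers.

    For every ranker, all features are scored, only the best-scoring member
    of each redundancy cluster survives, and the surviving features are
    re-ranked and truncated to ``top_k``.
    """
    labels = np.asarray(table.labels if labels is None else labels, dtype=int)
    if table.n_features < 1:
        raise ValueError("need at least one feature")
    clusters = correlation_clusters(table, threshold=threshold, measure=measure)
    out: dict[str, RankedList] = {}
    for method in RANKERS:
        ranked = rank_features(table, labels, method)
        rank_of = {f: i for i, f in enumerate(ranked.features)}
        survivors: list[str] = []
        for members in clusters.clusters().values():
            survivors.append(min(members, key=lambda f: rank_of[f]))
        survivors.sort(key=lambda f: rank_of[f])
        kept = survivors[:top_k]
        score_of = dict(zip(ranked.features, ranked.scores))
        out[method] = RankedList(
            method=method,
            features=kept,
            scores=[score_of[f] for f in kept],
        )
    return out
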