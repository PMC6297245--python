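"""SVM model building: forward search, cross-validated AUC, bootstrap tests.

The classifier is a soft-margin SVM at box-constraint C = 100 (linear kernel
by default; RBF available) on z-scored features, scored by signed decision
margin with the mutant class positive. The fine selection is a single-pass
forward search over a ranked candidate list that keeps a feature only when
it strictly improves the 3-fold cross-validated AUC under a fold assignment
fixed once per run. AUC uses the Mann-Whitney formulation (ties 0.5); its
confidence interval and model comparisons use patient-level bootstrap
resampling of the out-of-fold scores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .io_core import FeatureTable
from .selection import RankedList

__all__ = [
    "SVMSpec",
    "CVScores",
    "AUCSummary",
    "ModelReport",
    "train_svm",
    "cv_scores",
    "auc",
    "bootstrap_auc_ci",
    "compare_models",
    "forward_search",
    "select_features",
    "nested_cv_auc",
    "build_optimal_model",
    "support_vector_fraction",
    "transfer_evaluate",
]

IMPROVEMENT_TOL = 1e-10


@dataclass
class SVMSpec:
    """A fitted SVM with its training standardization, for reuse/transfer."""

    features: list[str]
    kernel: str
    C: float
    scaler_mean: np.ndarray
    scaler_scale: np.ndarray
    n_support: int
    svc: SVC = field(repr=False)

    def decision_scores(self, table: FeatureTable) -> np.ndarray:
        """Signed margins of the frozen model on a feature table."""
        missing = [f for f in self.features if f not in table.feature_names]
        if missing:
            raise KeyError(f"selected feature(s) missing from table: {missing}")
        x = table.subset(self.features).values
        z = (x - self.scaler_mean) / self.scaler_scale
        return self.svc.decision_function(z)


@dataclass
class CVScores:
    """Out-of-fold decision score per patient, with the fold assignment."""

    patient_ids: list[str]
    scores: np.ndarray
    fold_assignment: np.ndarray
    seed: int


@dataclass
class AUCSummary:
    auc: float
    ci_low: float
    ci_high: float
    n_bootstrap: int
    seed: int


@dataclass
class ModelReport:
    setting: str
    spec: SVMSpec
    cv: CVScores
    auc_summary: AUCSummary
    sv_fraction_pct: float
    ranker: str


def _standardize_fit(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mean = x.mean(axis=0)
    scale = x.std(axis=0)
    scale[scale == 0] = 1.0
    return mean, scale


def train_svm(
    table: FeatureTable,
    labels: np.ndarray | None = None,
    features: list[str] | None = None,
    C: float = 100.0,
    kernel: str = "linear",
) -> SVMSpec:
    """Fit the soft-margin SVM on z-scored features of the whole table.

    Decision scores are signed margins with mutant (label 1) positive.
    """
    labels = np.asarray(table.labels if labels is None else labels, dtype=int)
    features = list(features) if features is not None else list(table.feature_names)
    classes = np.unique(labels)
    if classes.size < 2:
        raise ValueError("both classes must be present for training")
    if min(np.bincount(labels)) < 2:
        raise ValueError("need at least 2 patients per class")
    x = table.subset(features).values
    mean, scale = _standardize_fit(x)
    svc = SVC(kernel=kernel, C=C)
    svc.fit((x - mean) / scale, labels)
    return SVMSpec(
        features=features,
        kernel=kernel,
        C=float(C),
        scaler_mean=mean,
        scaler_scale=scale,
        n_support=int(svc.n_support_.sum()),
        svc=svc,
    )


def make_folds(labels: np.ndarray, folds: int, seed: int) -> np.ndarray:
    """Stratified fold assignment (array of fold ids), fixed by seed."""
    labels = np.asarray(labels, dtype=int)
    counts = np.bincount(labels, minlength=2)
    if counts.min() < folds:
        raise ValueError(f"each class needs at least {folds} members for {folds}-fold CV")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=int(seed) % (2**31))
    assignment = np.empty(len(labels), dtype=int)
    for k, (_, test_idx) in enumerate(skf.split(np.zeros((len(labels), 1)), labels)):
        assignment[test_idx] = k
    return assignment


def _oof_scores(
    x: np.ndarray, labels: np.ndarray, fold_assignment: np.ndarray, C: float, kernel: str
) -> np.ndarray:
    scores = np.empty(len(labels), dtype=np.float64)
    for k in np.unique(fold_assignment):
        train = fold_assignment != k
        test = ~train
        mean, scale = _standardize_fit(x[train])
        svc = SVC(kernel=kernel, C=C)
        svc.fit((x[train] - mean) / scale, labels[train])
        scores[test] = svc.decision_function((x[test] - mean) / scale)
    return scores


def cv_scores(
    table: FeatureTable,
    labels: np.ndarray | None = None,
    features: list[str] | None = None,
    folds: int = 3,
    seed: int = 0,
    C: float = 100.0,
    kernel: str = "linear",
    fold_assignment: np.ndarray | None = None,
) -> CVScores:
    """Pooled out-of-fold decision scores under stratified k-fold CV.

    Standardization is refit inside each training fold; every patient is
    scored exactly once; the fold assignment is fixed by the seed (or passed
    in explicitly so several models share folds).
    """
    labels = np.asarray(table.labels if labels is None else labels, dtype=int)
    features = list(features) if features is not None else list(table.feature_names)
    if fold_assignment is None:
        fold_assignment = make_folds(labels, folds, seed)
    x = table.subset(features).values
    scores = _oof_scores(x, labels, fold_assignment, C, kernel)
    return CVScores(
        patient_ids=list(table.patient_ids),
        scores=scores,
        fold_assignment=np.asarray(fold_assignment),
        seed=int(seed),
    )


def auc(scores: np.ndarray | CVScores, labels: np.ndarray) -> float:
    """Mann-Whitney AUC of scores against binary labels; ties count 0.5."""
    if isinstance(scores, CVScores):
        scores = scores.scores
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels, dtype=int)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = rankdata(scores)
    u = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def _resample_indices(rng: np.random.Generator, labels: np.ndarray, max_tries: int) -> np.ndarray:
    n = len(labels)
    for _ in range(max_tries):
        idx = rng.integers(0, n, size=n)
        if labels[idx].min() != labels[idx].max():
            return idx
    raise RuntimeError("bootstrap redraw limit reached without a two-class resample")


def bootstrap_auc_ci(
    scores: np.ndarray | CVScores,
    labels: np.ndarray,
    B: int = 1000,
    seed: int = 0,
) -> AUCSummary:
    """Percentile 95% CI of the AUC by patient-level bootstrap resampling.

    Resamples that lose a class are redrawn (budget 10*B redraws in total).
    """
    if isinstance(scores, CVScores):
        scores = scores.scores
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels, dtype=int)
    if B < 100:
        warnings.warn(f"B = {B} bootstrap replicates is low; CI will be noisy", stacklevel=2)
    point = auc(scores, labels)
    rng = np.random.default_rng(int(seed) % (2**31))
    replicates = np.empty(B)
    budget = 10 * B
    for b in range(B):
        idx = _resample_indices(rng, labels, max_tries=budget)
        replicates[b] = auc(scores[idx], labels[idx])
    low, high = np.percentile(replicates, [2.5, 97.5])
    return AUCSummary(
        auc=point, ci_low=float(low), ci_high=float(high), n_bootstrap=B, seed=int(seed)
    )


def compare_models(
    scores_a: np.ndarray | CVScores,
    scores_b: np.ndarray | CVScores,
    labels: np.ndarray,
    B: int = 1000,
    seed: int = 0,
) -> float:
    """Two-sided bootstrap p-value for AUC_A vs AUC_B on the same patients.

    Paired patient-level bootstrap of dAUC = AUC_A - AUC_B;
    p = 2 min(frac(d* <= 0), frac(d* >= 0)), clipped to (1/B, 1].
    """
    ids_a = scores_a.patient_ids if isinstance(scores_a, CVScores) else None
    ids_b = scores_b.patient_ids if isinstance(scores_b, CVScores) else None
    if ids_a is not None and ids_b is not None and ids_a != ids_b:
        raise ValueError("score sets must cover the same patients")
    a = scores_a.scores if isinstance(scores_a, CVScores) else np.asarray(scores_a, dtype=float)
    b = scores_b.scores if isinstance(scores_b, CVScores) else np.asarray(scores_b, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if a.shape != b.shape or a.shape != labels.shape:
        raise ValueError("score sets and labels must have equal length")
    rng = np.random.default_rng(int(seed) % (2**31))
    deltas = np.empty(B)
    for i in range(B):
        idx = _resample_indices(rng, labels, max_tries=10 * B)
        deltas[i] = auc(a[idx], labels[idx]) - auc(b[idx], labels[idx])
    p = 2.0 * min((deltas <= 0).mean(), (deltas >= 0).mean())
    return float(min(max(p, 1.0 / B), 1.0))


def forward_search(
    table: FeatureTable,
    labels: np.ndarray | None = None,
    candidates: RankedList | list[str] | None = None,
    folds: int = 3,
    C: float = 100.0,
    seed: int = 0,
    kernel: str = "linear",
    fold_assignment: np.ndarray | None = None,
) -> tuple[list[str], float]:
    """Greedy single-pass forward selection over a ranked candidate list.

    Starting from the empty set (chance AUC 0.5), each candidate is kept iff
    adding it strictly increases the cross-validated AUC under the shared
    fold assignment. If no candidate is ever kept, the single top-ranked
    candidate is returned with its own CV AUC.
    """
    labels = np.asarray(table.labels if labels is None else labels, dtype=int)
    names = candidates.features if isinstance(candidates, RankedList) else list(candidates or [])
    if not names:
        raise ValueError("candidate list must be non-empty")
    if fold_assignment is None:
        fold_assignment = make_folds(labels, folds, seed)
    selected: list[str] = []
    best_auc = 0.5
    for name in names:
        trial = selected + [name]
        x = table.subset(trial).values
        trial_auc = auc(_oof_scores(x, labels, fold_assignment, C, kernel), labels)
        if trial_auc > best_auc + IMPROVEMENT_TOL:
            selected = trial
            best_auc = trial_auc
    if not selected:
        top = names[0]
        x = table.subset([top]).values
        best_auc = auc(_oof_scores(x, labels, fold_assignment, C, kernel), labels)
        selected = [top]
    return selected, float(best_auc)


def select_features(
    table: FeatureTable,
    labels: np.ndarray,
    lists: dict[str, RankedList],
    fold_assignment: np.ndarray,
    C: float = 100.0,
    kernel: str = "linear",
) -> tuple[list[str], str, float]:
    """Forward-search every candidate list under one shared fold assignment
    and return the winning (features, ranker, CV AUC)."""
    if not lists:
        raise ValueError("need at least one non-empty candidate list")
    results = []
    for order, (method, ranked) in enumerate(lists.items()):
        if not ranked.features:
            continue
        feats, cv_auc = forward_search(
            table, labels, ranked, C=C, kernel=kernel, fold_assignment=fold_assignment,
        )
        results.append((cv_auc, -len(feats), -order, method, feats))
    if not results:
        raise ValueError("all candidate lists were empty")
    results.sort(reverse=True)
    cv_auc, _, _, method, feats = results[0]
    return feats, method, cv_auc


def nested_cv_auc(
    table: FeatureTable,
    labels: np.ndarray | None = None,
    folds: int = 3,
    C: float = 100.0,
    seed: int = 0,
    kernel: str = "linear",
    redundancy_threshold: float = 0.8,
    top_k: int = 10,
) -> float:
    """Unbiased pipeline AUC: the whole coarse + fine selection re-run
    inside each outer training fold, scored on the held-out fold.

    The plain protocol selects features on the full cohort with CV as the
    search objective, so its reported CV AUC is optimistic (the forward
    search maximizes it). This nested mode is the honest alternative: its
    null distribution is centered at chance.
    """
    from .selection import coarse_select  # deferred: selection is a sibling stage

    labels = np.asarray(table.labels if labels is None else labels, dtype=int)
    outer = make_folds(labels, folds, seed)
    scores = np.empty(len(labels), dtype=np.float64)
    for k in np.unique(outer):
        train_idx = np.nonzero(outer != k)[0]
        test_idx = np.nonzero(outer == k)[0]
        train = table.rows(train_idx)
        lists = coarse_select(
            train, train.labels, threshold=redundancy_threshold, top_k=top_k
        )
        inner = make_folds(train.labels, folds, seed + 1)
        feats, _, _ = select_features(train, train.labels, lists, inner, C=C, kernel=kernel)
        spec = train_svm(train, train.labels, feats, C=C, kernel=kernel)
        scores[test_idx] = spec.decision_scores(table.rows(test_idx))
    return auc(scores, labels)


def build_optimal_model(
    table: FeatureTable,
    labels: np.ndarray | None = None,
    lists: dict[str, RankedList] | None = None,
    folds: int = 3,
    C: float = 100.0,
    B: int = 1000,
    seed: int = 0,
    kernel: str = "linear",
    setting: str = "",
) -> ModelReport:
    """Forward-search each ranker's candidate list and keep the best model.

    All searches share one fold assignment so the comparison is paired; ties
    in CV AUC are broken by fewer features, then candidate-list order. The
    winning feature set is refit on all patients for the final SVM (support
    vectors counted there), and the out-of-fold scores get a bootstrap CI.
    """
    labels = np.asarray(table.labels if labels is None else labels, dtype=int)
    fold_assignment = make_folds(labels, folds, seed)
    feats, method, cv_auc = select_features(
        table, labels, lists, fold_assignment=fold_assignment, C=C, kernel=kernel
    )
    cv = cv_scores(
        table, labels, feats, folds=folds, seed=seed, C=C, kernel=kernel,
        fold_assignment=fold_assignment,
    )
    summary = bootstrap_auc_ci(cv, labels, B=B, seed=seed)
    spec = train_svm(table, labels, feats, C=C, kernel=kernel)
    fraction = support_vector_fraction(spec.n_support, len(labels))
    return ModelReport(
        setting=setting,
        spec=spec,
        cv=cv,
        auc_summary=summary,
        sv_fraction_pct=fraction,
        ranker=method,
    )


def support_vector_fraction(sv_count: int, n: int) -> float:
    """Support vectors as a percentage of the cohort, one decimal, half-up."""
    if n <= 0:
        raise ValueError("cohort size must be positive")
    if not 0 <= sv_count <= n:
        raise ValueError("support-vector count must lie in [0, n]")
    pct = Decimal(100 * sv_count) / Decimal(n)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def transfer_evaluate(
    spec: SVMSpec,
    target_tables: dict[str, FeatureTable],
    labels: np.ndarray | None = None,
) -> dict[str, float]:
    """Apply a frozen model (weights + training standardization) to other
    settings' feature tables; returns AUC per setting."""
    out = {}
    for name, target in target_tables.items():
        y = np.asarray(target.labels if labels is None else labels, dtype=int)
        out[name] = auc(spec.decision_scores(target), y)
    return out
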