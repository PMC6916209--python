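"""Downstream clinical evaluations of patient representations.

Supervised tasks on top of fixed feature vectors: in-hospital mortality
prediction and ten independent binary comorbidity tasks, each scored by
AUC plus accuracy and F1 at a fixed decision threshold (default 0.8).
Cross-validation is stratified at the *patient* level — all prefix samples
of a patient share a fold — so a patient never appears in both train and
test.  Comorbidity tasks whose positive prevalence falls below 30% are
rebalanced on the training folds with NearMiss-1 undersampling (implemented
here: the majority samples closest, by mean distance to their k nearest
minority neighbours, are retained until the classes balance); the mortality
task runs on the natural class balance.

Also provides top-k comorbidity scoring with its theoretical upper bound
(mean over patients of min(|true comorbidities|, k)/k), average-rank
comparison across representation methods with midrank ties, and grid
sweeps over window size, latent dimension, training fraction, classifier
and undersampler.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import pairwise_distances, roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

logger = logging.getLogger(__name__)

CLASSIFIERS = ("svm", "rf", "gbdt", "knn", "lr", "nb")
UNDERSAMPLERS = ("none", "nearmiss", "random")
SWEEP_AXES = ("window", "dimension", "train_fraction", "classifier", "undersampler")

#: positive-prevalence threshold below which training folds are rebalanced
UNDERSAMPLE_TRIGGER = 0.30


@dataclass
class EvalConfig:
    """Protocol settings for the supervised evaluations."""

    classifier: str = "svm"
    threshold: float = 0.8
    undersampler: str = "nearmiss"
    undersample_trigger: float = UNDERSAMPLE_TRIGGER
    n_folds: int = 5
    seed: int = 0
    nearmiss_k: int = 3
    #: metrics to compute; dropping accuracy/f1 lets SVM skip Platt scaling
    metrics: tuple = ("auc", "accuracy", "f1")

    def __post_init__(self) -> None:
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must be in (0, 1)")
        if self.classifier not in CLASSIFIERS:
            raise ValueError(f"classifier must be one of {CLASSIFIERS}")
        if self.undersampler not in UNDERSAMPLERS:
            raise ValueError(f"undersampler must be one of {UNDERSAMPLERS}")


@dataclass
class EvalResult:
    """Fold-level and mean metrics for one binary task."""

    task: str
    fold_auc: list = field(default_factory=list)
    fold_accuracy: list = field(default_factory=list)
    fold_f1: list = field(default_factory=list)

    @property
    def auc(self) -> float:
        return float(np.mean(self.fold_auc)) if self.fold_auc else float("nan")

    @property
    def accuracy(self) -> float:
        return float(np.mean(self.fold_accuracy)) if self.fold_accuracy else float("nan")

    @property
    def f1(self) -> float:
        return float(np.mean(self.fold_f1)) if self.fold_f1 else float("nan")


@dataclass
class TopKResult:
    """Mean top-k accuracy over patients plus its theoretical upper bound."""

    k: int
    accuracy: float
    upper_bound: float


# --------------------------------------------------------------------------
# metrics
# --------------------------------------------------------------------------

def auc_score(scores: np.ndarray, labels: np.ndarray) -> float:
    """Rank-based AUC: P(random positive outranks random negative), ties = 1/2."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    pos = labels == 1
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs both classes present")
    ranks = rankdata(scores)  # midranks
    return float((ranks[pos].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def threshold_metrics(scores: np.ndarray, labels: np.ndarray, threshold: float) -> tuple[float, float]:
    """(accuracy, positive-class F1) of predictions `score >= threshold`."""
    labels = np.asarray(labels)
    pred = (np.asarray(scores, dtype=float) >= threshold).astype(int)
    acc = float((pred == labels).mean())
    tp = int(((pred == 1) & (labels == 1)).sum())
    fp = int(((pred == 1) & (labels == 0)).sum())
    fn = int(((pred == 0) & (labels == 1)).sum())
    f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 0.0
    return acc, float(f1)


# --------------------------------------------------------------------------
# undersampling
# --------------------------------------------------------------------------

def nearmiss_indices(X: np.ndarray, y: np.ndarray, k: int = 3) -> np.ndarray:
    """NearMiss-1: keep all minority samples plus the majority samples with
    smallest mean distance to their k nearest minority neighbours, until
    the classes balance.  Returns sorted original indices."""
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("undersampling needs both classes present")
    minority = classes[counts.argmin()]
    min_idx = np.flatnonzero(y == minority)
    maj_idx = np.flatnonzero(y != minority)
    if len(maj_idx) <= len(min_idx):
        return np.arange(len(y))
    D = pairwise_distances(X[maj_idx], X[min_idx])
    kk = min(k, len(min_idx))
    mean_near = np.sort(D, axis=1)[:, :kk].mean(axis=1)
    keep_maj = maj_idx[np.argsort(mean_near, kind="stable")[: len(min_idx)]]
    return np.sort(np.concatenate([min_idx, keep_maj]))


def undersample(X: np.ndarray, y: np.ndarray, config: EvalConfig, rng: np.random.Generator | None = None) -> np.ndarray:
    """Dispatch on the configured undersampler; identity when balanced."""
    y = np.asarray(y)
    if config.undersampler == "none":
        return np.arange(len(y))
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("undersampling needs both classes present")
    if counts.min() == counts.max():
        return np.arange(len(y))
    if config.undersampler == "nearmiss":
        return nearmiss_indices(X, y, k=config.nearmiss_k)
    # random undersampling of the majority class
    rng = rng or np.random.default_rng(config.seed)
    minority = classes[counts.argmin()]
    min_idx = np.flatnonzero(y == minority)
    maj_idx = np.flatnonzero(y != minority)
    keep = rng.choice(maj_idx, size=len(min_idx), replace=False)
    return np.sort(np.concatenate([min_idx, keep]))


# --------------------------------------------------------------------------
# classifiers and cross-validation
# --------------------------------------------------------------------------

def needs_undersampling(labels: np.ndarray, config: EvalConfig) -> bool:
    """Rebalance only when the positive prevalence is below the trigger (30%)."""
    if config.undersampler == "none":
        return False
    labels = np.asarray(labels)
    prevalence = labels.mean()
    return min(prevalence, 1.0 - prevalence) < config.undersample_trigger


def make_classifier(name: str, seed: int, need_proba: bool):
    if name == "svm":
        if need_proba:
            # Platt-scaled SVM so threshold metrics see probabilities
            from sklearn.calibration import CalibratedClassifierCV

            return CalibratedClassifierCV(SVC(random_state=seed), ensemble=False)
        return SVC(random_state=seed)
    if name == "rf":
        return RandomForestClassifier(random_state=seed)
    if name == "gbdt":
        return GradientBoostingClassifier(random_state=seed)
    if name == "knn":
        return KNeighborsClassifier()
    if name == "lr":
        return LogisticRegression(max_iter=1000, random_state=seed)
    if name == "nb":
        return GaussianNB()
    raise ValueError(f"unknown classifier {name!r}")


def _scores(clf, X: np.ndarray) -> np.ndarray:
    """Ranking scores: probabilities when available, else decision margins."""
    if hasattr(clf, "predict_proba"):
        return clf.predict_proba(X)[:, 1]
    return clf.decision_function(X)


def patient_folds(patient_ids: np.ndarray, labels: np.ndarray, n_folds: int, seed: int) -> list[tuple[np.ndarray, np.ndarray]]:
    """Stratified folds at the patient level; all of a patient's samples share a fold."""
    patient_ids = np.asarray(patient_ids)
    labels = np.asarray(labels)
    uniq, first = np.unique(patient_ids, return_index=True)
    p_label = labels[first]
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    folds = []
    for tr_p, te_p in skf.split(uniq.reshape(-1, 1), p_label):
        tr_mask = np.isin(patient_ids, uniq[tr_p])
        folds.append((np.flatnonzero(tr_mask), np.flatnonzero(~tr_mask)))
    return folds


def _cross_val(
    features: np.ndarray,
    labels: np.ndarray,
    patient_ids: np.ndarray,
    config: EvalConfig,
    task: str,
) -> tuple[EvalResult, np.ndarray]:
    """Patient-grouped CV; returns per-fold metrics and out-of-fold scores."""
    labels = np.asarray(labels).astype(int)
    need_proba = bool({"accuracy", "f1"} & set(config.metrics))
    result = EvalResult(task=task)
    oof = np.full(len(labels), np.nan)
    for fold_i, (tr, te) in enumerate(
        patient_folds(patient_ids, labels, config.n_folds, config.seed)
    ):
        if len(np.unique(labels[tr])) < 2 or len(np.unique(labels[te])) < 2:
            logger.warning("task %s: fold %d degenerate, skipped", task, fold_i)
            continue
        tr_use = tr
        if needs_undersampling(labels, config):
            sub = undersample(features[tr], labels[tr], config)
            tr_use = tr[sub]
        clf = make_classifier(config.classifier, config.seed, need_proba)
        clf.fit(features[tr_use], labels[tr_use])
        s = clf.predict_proba(features[te])[:, 1] if need_proba else _scores(clf, features[te])
        oof[te] = s
        if "auc" in config.metrics:
            result.fold_auc.append(auc_score(s, labels[te]))
        if need_proba:
            acc, f1 = threshold_metrics(s, labels[te], config.threshold)
            if "accuracy" in config.metrics:
                result.fold_accuracy.append(acc)
            if "f1" in config.metrics:
                result.fold_f1.append(f1)
    return result, oof


def evaluate_mortality(
    features: np.ndarray,
    died: np.ndarray,
    patient_ids: np.ndarray,
    config: EvalConfig | None = None,
) -> EvalResult:
    """Cross-validated in-hospital mortality prediction on fixed features."""
    config = config or EvalConfig()
    result, _ = _cross_val(features, died, patient_ids, config, task="mortality")
    return result


def evaluate_comorbidity(
    features: np.ndarray,
    comorbidity_labels: pd.DataFrame,
    patient_ids: np.ndarray,
    config: EvalConfig | None = None,
) -> tuple[dict[str, EvalResult], np.ndarray]:
    """One independent binary task per comorbidity column.

    Returns per-task results and the (n_samples, n_tasks) out-of-fold score
    matrix used for top-k prediction.
    """
    config = config or EvalConfig()
    results: dict[str, EvalResult] = {}
    scores = np.full((len(features), comorbidity_labels.shape[1]), np.nan)
    for j, task in enumerate(comorbidity_labels.columns):
        y = comorbidity_labels[task].to_numpy().astype(int)
        if y.min() == y.max():
            logger.warning("comorbidity %s has a single class; task skipped", task)
            continue
        results[task], scores[:, j] = _cross_val(features, y, patient_ids, config, task)
    return results, scores


def average_ranks(auc_by_method: pd.DataFrame) -> pd.Series:
    """Average rank of each method across tasks (rows=tasks, cols=methods).

    Higher AUC is better (rank 1); ties get midranks, e.g. two methods tied
    for 4th/5th both rank 4.5.
    """
    ranks = auc_by_method.apply(
        lambda row: rankdata(-row.to_numpy(), method="average"), axis=1,
        result_type="expand",
    )
    ranks.columns = auc_by_method.columns
    return ranks.mean(axis=0)


def topk_comorbidity(
    scores: np.ndarray, true_sets: list[set[int]], k: int
) -> TopKResult:
    """Top-k comorbidity accuracy and its theoretical upper bound.

    Per patient: take the k highest-scoring comorbidities; accuracy is
    |predicted ∩ true| / k.  The upper bound assumes a perfect classifier:
    min(|true|, k)/k.  Patients with no true comorbidities are excluded.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    scores = np.asarray(scores, dtype=float)
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    accs, bounds = [], []
    n_empty = 0
    for row, truth in zip(scores, true_sets):
        if not truth:
            n_empty += 1
            continue
        top = set(np.argsort(-row, kind="stable")[:k].tolist())
        accs.append(len(top & truth) / k)
        bounds.append(min(len(truth), k) / k)
    if n_empty:
        logger.info("top-%d: excluded %d patients with no comorbidities", k, n_empty)
    if not accs:
        raise ValueError("no patients with a non-empty comorbidity set")
    return TopKResult(k=k, accuracy=float(np.mean(accs)), upper_bound=float(np.mean(bounds)))


# --------------------------------------------------------------------------
# sweeps
# --------------------------------------------------------------------------

def sweep(
    axis: str,
    grid: list,
    evaluate_fn,
    base_config: EvalConfig | None = None,
) -> pd.DataFrame:
    """Re-run an evaluation along one protocol axis with shared folds/seed.

    ``evaluate_fn(axis, value, config) -> EvalResult`` supplies the
    task-specific plumbing (e.g. recomputing window features or retraining
    at a different latent dimension); this wrapper owns the grid, the
    shared configuration and the tidy output table.
    """
    if axis not in SWEEP_AXES:
        raise ValueError(f"invalid sweep axis {axis!r}; choose from {SWEEP_AXES}")
    base_config = base_config or EvalConfig()
    rows = []
    for value in grid:
        cfg = base_config
        if axis == "classifier":
            cfg = replace(base_config, classifier=value)
        elif axis == "undersampler":
            cfg = replace(base_config, undersampler=value)
        res = evaluate_fn(axis, value, cfg)
        rows.append(
            {"axis": axis, "value": value, "auc": res.auc,
             "accuracy": res.accuracy, "f1": res.f1}
        )
    return pd.DataFrame(rows)


def subsample_train_fraction(
    n: int, fraction: float, rng: np.random.Generator
) -> np.ndarray:
    """Random index subset for training-size sweeps (fraction of all samples)."""
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    m = max(2, int(round(fraction * n)))
    return np.sort(rng.choice(n, size=m, replace=False))
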