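"""Statistic-based patient representations: Hand, PCA, k-means, GMM.

These are the order-insensitive comparison methods.  Records inside an
observation window (anchored at the last admission) are aggregated into a
single vector — by elementwise mean, matching the "Hand" feature — and the
aggregate is optionally transformed by an unsupervised model: PCA scores,
the assigned k-means centroid, or the diagonal-covariance vector of the
most responsible Gaussian mixture component.  Demographics are appended
after aggregation, mirroring the Deep Feature layout.

Study-scale hyperparameters: PCA 512 components, k-means 16 clusters, GMM
512 components; scaled-down presets (32/16/32) suit the small synthetic
vocabulary whose dimensionality 512 would exceed.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import timedelta

import numpy as np
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.mixture import GaussianMixture

from .schema import ClinicalRecord, Sample, normalize_age

METHODS = ("hand", "pca", "kmeans", "gmm")

#: hyperparameters at the study's vocabulary scale
FULL_SCALE_HYPERPARAMS = {"pca": 512, "kmeans": 16, "gmm": 512}
#: presets for the small synthetic vocabulary
SMALL_SCALE_HYPERPARAMS = {"pca": 32, "kmeans": 16, "gmm": 32}


@dataclass(frozen=True)
class WindowSpec:
    """Observation window in days before (and including) the last admission."""

    window_days: int = 180

    def __post_init__(self) -> None:
        if self.window_days <= 0:
            raise ValueError("window_days must be positive")


def window_filter(records: list[ClinicalRecord], window: WindowSpec) -> list[ClinicalRecord]:
    """Keep records within `window_days` of the last admission (inclusive).

    The last record is always retained, so the result is never empty.
    """
    if not records:
        return []
    anchor = records[-1].admission_time
    cutoff = anchor - timedelta(days=window.window_days)
    return [r for r in records if r.admission_time >= cutoff]


def window_rows(sample: Sample, window: WindowSpec, records: list[ClinicalRecord]) -> np.ndarray:
    """Tensor rows of a prefix sample that fall inside the window."""
    kept = window_filter(records[: sample.prefix_length], window)
    n_kept = len(kept)
    return sample.tensor[sample.prefix_length - n_kept :]


def hand_features(rows: np.ndarray) -> np.ndarray:
    """Elementwise mean of the record vectors (order invariant)."""
    rows = np.atleast_2d(rows)
    if rows.shape[0] < 1:
        raise ValueError("need at least one record row")
    return rows.mean(axis=0)


def aggregate(rows: np.ndarray, how: str = "mean") -> np.ndarray:
    """Window aggregation: mean (default, = Hand), sum or max."""
    rows = np.atleast_2d(rows)
    if how == "mean":
        return rows.mean(axis=0)
    if how == "sum":
        return rows.sum(axis=0)
    if how == "max":
        return rows.max(axis=0)
    raise ValueError(f"unknown aggregation {how!r}")


@dataclass
class BaselineModel:
    """A fitted window-based representation model."""

    method: str
    estimator: object | None  # None for "hand"
    n_components: int | None

    def transform(self, vectors: np.ndarray) -> np.ndarray:
        vectors = np.atleast_2d(vectors)
        if self.method == "hand":
            return vectors
        if self.estimator is None:
            raise ValueError("model is not fitted")
        if self.method == "pca":
            return self.estimator.transform(vectors)
        if self.method == "kmeans":
            labels = self.estimator.predict(vectors)
            return self.estimator.cluster_centers_[labels]
        if self.method == "gmm":
            # diagonal covariance vector of the most responsible component
            resp = self.estimator.predict_proba(vectors)
            comp = resp.argmax(axis=1)
            return self.estimator.covariances_[comp]
        raise ValueError(f"unknown method {self.method!r}")


def fit_baseline(
    vectors: np.ndarray, method: str, n_components: int | None = None, seed: int = 0
) -> BaselineModel:
    """Fit the requested representation on aggregated window vectors."""
    vectors = np.atleast_2d(vectors)
    n, d = vectors.shape
    if method == "hand":
        return BaselineModel("hand", None, None)
    if method == "pca":
        k = n_components or FULL_SCALE_HYPERPARAMS["pca"]
        if k > min(n, d):
            raise ValueError(f"PCA components {k} exceed feasible bound {min(n, d)}")
        est = PCA(n_components=k, random_state=seed).fit(vectors)
    elif method == "kmeans":
        k = n_components or FULL_SCALE_HYPERPARAMS["kmeans"]
        if k > n:
            raise ValueError(f"k-means clusters {k} exceed sample count {n}")
        est = KMeans(n_clusters=k, random_state=seed, n_init=10).fit(vectors)
    elif method == "gmm":
        k = n_components or FULL_SCALE_HYPERPARAMS["gmm"]
        if k > n:
            raise ValueError(f"GMM components {k} exceed sample count {n}")
        est = GaussianMixture(
            n_components=k, covariance_type="diag", random_state=seed
        ).fit(vectors)
    else:
        raise ValueError(f"unknown method {method!r}; choose from {METHODS}")
    return BaselineModel(method, est, k)


def baseline_features(
    samples: list[Sample],
    records_by_patient: dict[str, list[ClinicalRecord]],
    schema,
    method: str,
    window: WindowSpec = WindowSpec(),
    n_components: int | None = None,
    seed: int = 0,
    aggregation: str = "mean",
) -> np.ndarray:
    """End-to-end: window-aggregate every sample, fit, transform, add demographics."""
    agg = np.stack([
        aggregate(window_rows(s, window, records_by_patient[s.patient_id]), aggregation)
        for s in samples
    ])
    model = fit_baseline(agg, method, n_components=n_components, seed=seed)
    rep = model.transform(agg)
    demo = np.array(
        [[normalize_age(s.age, schema), float(s.gender)] for s in samples]
    )
    return np.hstack([demo, rep])
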