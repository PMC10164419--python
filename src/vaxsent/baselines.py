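"""Baseline classifiers: multinomial Naive Bayes, KNN, and a uniform
harness over scikit-learn decision-tree / random-forest / linear-SVM models.

Naive Bayes applies Bayes' rule P(H|X) = P(X|H)·P(H)/P(X) with Laplace
smoothing, in log space; KNN votes among the k Euclidean-nearest training
points.  All baselines expose the same score/label prediction contract as
the NBSVM model so they can share the evaluation harness.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.special import expit, logsumexp
from sklearn.ensemble import RandomForestClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .nbsvm import DocTermMatrix, _as_binary_labels

__all__ = [
    "BASELINE_KINDS",
    "NaiveBayesModel",
    "SklearnTextModel",
    "knn_predict",
    "predict_nb",
    "train_baseline",
    "train_nb",
]

BASELINE_KINDS = ("decision_tree", "random_forest", "svm")


@dataclass(frozen=True)
class NaiveBayesModel:
    """Multinomial NB with Laplace smoothing over a fixed vocabulary."""

    dtm: DocTermMatrix
    log_prior: np.ndarray        # shape (2,), classes [neg, pos]
    log_word_prob: np.ndarray    # shape (2, V)
    alpha: float

    def predict_scores(self, docs: Iterable[Sequence[str]]) -> np.ndarray:
        return np.array([predict_nb(self, d) for d in docs])

    def predict_labels(self, docs: Iterable[Sequence[str]]) -> np.ndarray:
        return (self.predict_scores(docs) >= 0.5).astype(int)


def train_nb(dtm: DocTermMatrix, labels, alpha: float = 1.0) -> NaiveBayesModel:
    """Fit the multinomial NB model (both classes required)."""
    if alpha <= 0:
        raise ValueError(f"alpha must be > 0, got {alpha}")
    y = _as_binary_labels(labels)
    if len(y) != dtm.n_docs:
        raise ValueError("labels length does not match document count")
    counts = dtm.counts
    V = len(dtm.vocabulary)
    log_prior = np.log(
        np.array([(y == 0).sum(), (y == 1).sum()], dtype=float) / len(y)
    )
    log_word_prob = np.empty((2, V))
    for c in (0, 1):
        class_counts = np.asarray(counts[y == c].sum(axis=0)).ravel()
        smoothed = class_counts + alpha
        log_word_prob[c] = np.log(smoothed / smoothed.sum())
    return NaiveBayesModel(
        dtm=dtm, log_prior=log_prior, log_word_prob=log_word_prob, alpha=alpha
    )


def predict_nb(model: NaiveBayesModel, tokens: Sequence[str]) -> float:
    """Posterior P(positive | tokens), normalized over the two classes.

    Words outside the vocabulary contribute nothing, so a document of only
    unseen words falls back to the class prior.
    """
    row = model.dtm.vectorize(tokens)
    log_joint = model.log_prior + model.log_word_prob @ row
    return float(np.exp(log_joint[1] - logsumexp(log_joint)))


def knn_predict(
    train: Sequence[tuple[Sequence[float], object]],
    query: Sequence[float],
    k: int,
):
    """Majority label among the k Euclidean-nearest training points.

    Distance ties are broken by training order; vote ties go to the class
    with the smaller summed distance among the k neighbors.
    """
    if not train:
        raise ValueError("training set is empty")
    if not 1 <= k <= len(train):
        raise ValueError(f"k must lie in [1, {len(train)}], got {k}")
    q = np.asarray(query, dtype=float)
    dists = []
    for i, (vec, label) in enumerate(train):
        v = np.asarray(vec, dtype=float)
        if v.shape != q.shape:
            raise ValueError("feature dimensions differ")
        dists.append((float(np.sqrt(((v - q) ** 2).sum())), i, label))
    dists.sort(key=lambda t: (t[0], t[1]))
    nearest = dists[:k]
    votes: dict[object, int] = {}
    summed: dict[object, float] = {}
    for d, _, label in nearest:
        votes[label] = votes.get(label, 0) + 1
        summed[label] = summed.get(label, 0.0) + d
    best_votes = max(votes.values())
    tied = [lab for lab, n in votes.items() if n == best_votes]
    if len(tied) == 1:
        return tied[0]
    return min(tied, key=lambda lab: summed[lab])


@dataclass
class SklearnTextModel:
    """Uniform wrapper giving sklearn baselines the shared predict contract."""

    kind: str
    dtm: DocTermMatrix
    estimator: object

    def _matrix(self, docs: Iterable[Sequence[str]]) -> np.ndarray:
        return np.vstack([self.dtm.vectorize(d) for d in docs])

    def predict_scores(self, docs: Iterable[Sequence[str]]) -> np.ndarray:
        X = self._matrix(docs)
        est = self.estimator
        if hasattr(est, "predict_proba"):
            return est.predict_proba(X)[:, 1]
        return expit(est.decision_function(X))

    def predict_labels(self, docs: Iterable[Sequence[str]]) -> np.ndarray:
        return (self.predict_scores(docs) >= 0.5).astype(int)


def train_baseline(
    kind: str,
    dtm: DocTermMatrix,
    labels,
    params: dict | None = None,
) -> SklearnTextModel:
    """Train a decision_tree / random_forest / svm baseline on the DTM.

    ``params`` are passed through to the underlying estimator; a ``seed``
    key maps to its ``random_state`` so random_forest runs are reproducible.
    """
    if kind not in BASELINE_KINDS:
        raise ValueError(
            f"unknown baseline kind {kind!r}; valid kinds: {', '.join(BASELINE_KINDS)}"
        )
    y = _as_binary_labels(labels)
    params = dict(params or {})
    seed = params.pop("seed", 0)
    if kind == "decision_tree":
        est = DecisionTreeClassifier(random_state=seed, **params)
    elif kind == "random_forest":
        est = RandomForestClassifier(random_state=seed, **params)
    else:
        params.setdefault("kernel", "linear")
        est = SVC(random_state=seed, **params)
    est.fit(dtm.counts.toarray(), y)
    return SklearnTextModel(kind=kind, dtm=dtm, estimator=est)
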