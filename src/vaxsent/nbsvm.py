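"""NBSVM: a linear margin classifier on Naive-Bayes-scaled count features.

The pipeline is the classic interpolated NB/SVM construction for text:

1. build a document-term matrix (binarized by default),
2. compute log-count ratios r = log( p̂ / q̂ ), where p̂ and q̂ are the
   alpha-smoothed, L1-normalized per-class term-count vectors,
3. train a linear max-margin classifier on features x_i = f_i ∘ r
   (elementwise product of the document's count row and r).

Scores are mapped to [0, 1] through a logistic link on the margin so they
can be fused with other probabilistic classifiers on a common scale.
Optionally the learned weights can be interpolated toward their mean
magnitude w̄ (w̃ = (1 − β)·w̄ + β·w); β = 1 — no interpolation — is the
default.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import scipy.sparse as sp
from scipy.special import expit
from sklearn.svm import LinearSVC

__all__ = [
    "DocTermMatrix",
    "LinearTextModel",
    "LogCountRatios",
    "build_dtm",
    "log_count_ratios",
    "train_nbsvm",
]


@dataclass(frozen=True)
class DocTermMatrix:
    """Documents × vocabulary count matrix.

    ``vocabulary`` is lexicographically sorted; row i corresponds to input
    document i; entries are 0/1 when ``binarized``.
    """

    vocabulary: tuple[str, ...]
    counts: sp.csr_matrix
    binarized: bool

    @property
    def n_docs(self) -> int:
        return self.counts.shape[0]

    def vectorize(self, tokens: Sequence[str]) -> np.ndarray:
        """Count row for an unseen document over this vocabulary."""
        index = {term: j for j, term in enumerate(self.vocabulary)}
        row = np.zeros(len(self.vocabulary))
        for tok in tokens:
            j = index.get(tok)
            if j is not None:
                row[j] += 1.0
        if self.binarized:
            row = (row > 0).astype(float)
        return row


def build_dtm(
    corpus: Iterable[Sequence[str]],
    *,
    binarize: bool = True,
    min_df: int = 1,
) -> DocTermMatrix:
    """Build a document-term matrix from tokenized documents.

    ``min_df`` drops terms occurring in fewer than that many documents;
    binarization (the standard NBSVM choice, default on) clips counts to 1.
    """
    docs = [list(doc) for doc in corpus]
    if not docs:
        raise ValueError("corpus is empty")
    if min_df < 1:
        raise ValueError(f"min_df must be >= 1, got {min_df}")
    df: dict[str, int] = {}
    for doc in docs:
        for term in set(doc):
            df[term] = df.get(term, 0) + 1
    vocabulary = tuple(sorted(t for t, n in df.items() if n >= min_df))
    if not vocabulary:
        raise ValueError(f"min_df={min_df} eliminates every term")
    index = {term: j for j, term in enumerate(vocabulary)}
    rows, cols, data = [], [], []
    for i, doc in enumerate(docs):
        seen: dict[int, int] = {}
        for tok in doc:
            j = index.get(tok)
            if j is not None:
                seen[j] = seen.get(j, 0) + 1
        for j, n in seen.items():
            rows.append(i)
            cols.append(j)
            data.append(1 if binarize else n)
    counts = sp.csr_matrix(
        (data, (rows, cols)), shape=(len(docs), len(vocabulary)), dtype=np.float64
    )
    return DocTermMatrix(vocabulary=vocabulary, counts=counts, binarized=binarize)


@dataclass(frozen=True)
class LogCountRatios:
    """Naive-Bayes log-count ratios over a vocabulary.

    ``r[j] = log( (alpha + p_j)/||alpha + p||_1 ) − log( (alpha + q_j)/||alpha + q||_1 )``
    with p, q the per-class term-count sums.  Swapping the class labels
    negates r exactly.
    """

    r: np.ndarray
    alpha: float
    class_prior_log_odds: float


def _as_binary_labels(labels) -> np.ndarray:
    y = np.asarray(labels).astype(int)
    if not set(np.unique(y)) <= {0, 1}:
        raise ValueError("labels must be binary 0/1")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes required")
    return y


def log_count_ratios(
    dtm: DocTermMatrix, labels, alpha: float = 1.0
) -> LogCountRatios:
    """Smoothed log-count ratios of the positive over the negative class."""
    if alpha <= 0:
        raise ValueError(f"alpha must be > 0, got {alpha}")
    y = _as_binary_labels(labels)
    if len(y) != dtm.n_docs:
        raise ValueError("labels length does not match document count")
    counts = dtm.counts
    p = alpha + np.asarray(counts[y == 1].sum(axis=0)).ravel()
    q = alpha + np.asarray(counts[y == 0].sum(axis=0)).ravel()
    r = np.log(p / p.sum()) - np.log(q / q.sum())
    prior = float(np.log((y == 1).sum() / (y == 0).sum()))
    return LogCountRatios(r=r, alpha=alpha, class_prior_log_odds=prior)


@dataclass
class LinearTextModel:
    """A trained linear text classifier over a fixed vocabulary.

    ``transform`` is ``"nb-scaled"`` for NBSVM features (count row ∘ r) or
    ``"plain"`` for raw counts.  ``predict_scores`` maps margins through a
    logistic link to [0, 1]; hard labels threshold at 0.5.
    """

    dtm: DocTermMatrix
    weights: np.ndarray
    intercept: float
    transform: str = "nb-scaled"
    ratios: LogCountRatios | None = None
    trained: bool = True

    def _features(self, tokens: Sequence[str]) -> np.ndarray:
        row = self.dtm.vectorize(tokens)
        if self.transform == "nb-scaled":
            assert self.ratios is not None
            row = row * self.ratios.r
        return row

    def decision_function(self, docs: Iterable[Sequence[str]]) -> np.ndarray:
        return np.array(
            [float(self._features(d) @ self.weights) + self.intercept for d in docs]
        )

    def predict_scores(self, docs: Iterable[Sequence[str]]) -> np.ndarray:
        """Positive-class scores in [0, 1] (logistic link on the margin)."""
        return expit(self.decision_function(docs))

    def predict_labels(self, docs: Iterable[Sequence[str]]) -> np.ndarray:
        return (self.predict_scores(docs) >= 0.5).astype(int)

    def to_dict(self) -> dict:
        payload = {
            "format": "vaxsent-linear-model/1",
            "vocabulary": list(self.dtm.vocabulary),
            "binarized": self.dtm.binarized,
            "weights": self.weights.tolist(),
            "intercept": self.intercept,
            "transform": self.transform,
        }
        if self.ratios is not None:
            payload["ratios"] = {
                "r": self.ratios.r.tolist(),
                "alpha": self.ratios.alpha,
                "class_prior_log_odds": self.ratios.class_prior_log_odds,
            }
        return payload

    @classmethod
    def from_dict(cls, payload: dict) -> "LinearTextModel":
        if payload.get("format") != "vaxsent-linear-model/1":
            raise ValueError("unrecognized model payload")
        vocab = tuple(payload["vocabulary"])
        dtm = DocTermMatrix(
            vocabulary=vocab,
            counts=sp.csr_matrix((0, len(vocab))),
            binarized=payload["binarized"],
        )
        ratios = None
        if "ratios" in payload:
            ratios = LogCountRatios(
                r=np.asarray(payload["ratios"]["r"]),
                alpha=payload["ratios"]["alpha"],
                class_prior_log_odds=payload["ratios"]["class_prior_log_odds"],
            )
        return cls(
            dtm=dtm,
            weights=np.asarray(payload["weights"]),
            intercept=payload["intercept"],
            transform=payload["transform"],
            ratios=ratios,
        )


def train_nbsvm(
    dtm: DocTermMatrix,
    labels,
    *,
    alpha: float = 1.0,
    regularization: float = 1.0,
    beta: float = 1.0,
    seed: int = 0,
    max_iter: int = 20000,
) -> LinearTextModel:
    """Train the NBSVM linear model.

    Parameters
    ----------
    alpha
        Smoothing pseudo-count for the log-count ratios.
    regularization
        Inverse-strength C of the squared-hinge margin objective.
    beta
        Interpolation of the learned weights toward their mean magnitude
        (w̃ = (1 − β)·w̄ + β·w); 1.0 (default) leaves the weights as learned.
    """
    y = _as_binary_labels(labels)
    ratios = log_count_ratios(dtm, y, alpha=alpha)
    features = dtm.counts.multiply(ratios.r[None, :]).tocsr()
    clf = LinearSVC(
        C=regularization,
        loss="squared_hinge",
        tol=1e-8,
        max_iter=max_iter,
        random_state=seed,
    )
    clf.fit(features, y)
    w = clf.coef_.ravel().astype(float)
    if not 0.0 <= beta <= 1.0:
        raise ValueError(f"beta must lie in [0, 1], got {beta}")
    if beta < 1.0:
        w_bar = np.abs(w).mean()
        w = (1.0 - beta) * w_bar + beta * w
    return LinearTextModel(
        dtm=dtm,
        weights=w,
        intercept=float(clf.intercept_[0]),
        transform="nb-scaled",
        ratios=ratios,
    )
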