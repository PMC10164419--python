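"""Transformer classification head and the weighted-sum model fusion.

The encoder is a compact, self-contained transformer implemented in numpy:
hashed token embeddings plus learned positions, a stack of self-attention
encoder layers, and a softmax classification head applied to the [CLS]
representation C, i.e. P = softmax(C·Wᵀ + b).  The built-in configuration
is ``"tiny-random"`` (2 layers, hidden 32, 4 heads), sized so fine-tuning
and inference run on one CPU in seconds.  Fine-tuning freezes the encoder
and trains the head with Adam on a cross-entropy loss.

Fusion is a weighted sum of the encoder's and NBSVM's positive-class
scores, s = (w_b·p_b + w_n·p_n)/(w_b + w_n) by default (the divisor is
dropped in raw mode); the weight pair is picked by an exhaustive grid
search on validation accuracy.  Following the two-model scheme, one fused
model is trained for positive-vs-rest and one for negative-vs-rest.
"""

from __future__ import annotations

import re
import zlib
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from .metrics import ConfusionCounts, MetricsReport, compute_metrics
from .nbsvm import DocTermMatrix, LinearTextModel, build_dtm, train_nbsvm

__all__ = [
    "EncoderClassifier",
    "EnsembleWeights",
    "FusedSentimentModel",
    "SentimentModelPair",
    "classify_proba",
    "ensemble_score",
    "fine_tune",
    "grid_search_weights",
    "train_polarity_pair",
]

_CLS, _SEP = 0, 1
_WORD_RE = re.compile(r"[\w']+")


def _softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    z = x - x.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def _gelu(x: np.ndarray) -> np.ndarray:
    return 0.5 * x * (1.0 + np.tanh(np.sqrt(2 / np.pi) * (x + 0.044715 * x**3)))


def _layer_norm(x: np.ndarray, eps: float = 1e-5) -> np.ndarray:
    mu = x.mean(axis=-1, keepdims=True)
    var = x.var(axis=-1, keepdims=True)
    return (x - mu) / np.sqrt(var + eps)


@dataclass
class EncoderClassifier:
    """A fixed random transformer encoder with a trainable softmax head.

    Token ids come from a stable CRC32 hashing trick over lowercased word
    tokens, so tokenization needs no fitted vocabulary and is identical
    across runs and platforms.  Inference is deterministic; texts longer
    than ``max_len`` (including [CLS]/[SEP]) are truncated.
    """

    encoder_id: str = "tiny-random"
    hidden_size: int = 32
    n_layers: int = 2
    n_heads: int = 4
    max_len: int = 64
    hash_dim: int = 512
    n_classes: int = 2
    seed: int = 0
    trained: bool = False
    _params: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if self.encoder_id != "tiny-random":
            raise ValueError(
                f"unknown encoder {self.encoder_id!r}; the built-in "
                "configuration is 'tiny-random'"
            )
        if self.hidden_size % self.n_heads:
            raise ValueError("hidden_size must be divisible by n_heads")
        if not self._params:
            self._params = self._init_params()

    def _init_params(self) -> dict:
        rng = np.random.default_rng(self.seed)
        h = self.hidden_size
        scale = 1.0 / np.sqrt(h)
        params = {
            "embed": rng.normal(0.0, scale, size=(self.hash_dim + 2, h)),
            "pos": rng.normal(0.0, scale, size=(self.max_len, h)),
            "head_w": rng.normal(0.0, scale, size=(self.n_classes, h)),
            "head_b": np.zeros(self.n_classes),
        }
        for layer in range(self.n_layers):
            for name in ("wq", "wk", "wv", "wo"):
                params[f"l{layer}.{name}"] = rng.normal(0.0, scale, size=(h, h))
            params[f"l{layer}.ff1"] = rng.normal(0.0, scale, size=(h, 4 * h))
            params[f"l{layer}.ff2"] = rng.normal(0.0, scale, size=(4 * h, h))
        return params

    # -- tokenization -----------------------------------------------------
    def _token_ids(self, text: str) -> np.ndarray:
        ids = [_CLS]
        for tok in _WORD_RE.findall(text.lower()):
            ids.append(2 + zlib.crc32(tok.encode("utf-8")) % self.hash_dim)
        ids.append(_SEP)
        return np.asarray(ids[: self.max_len])

    # -- forward pass ------------------------------------------------------
    def encode(self, text: str) -> np.ndarray:
        """[CLS] representation C (length ``hidden_size``) of one text."""
        if not self._params:
            raise RuntimeError("encoder is uninitialized")
        p = self._params
        ids = self._token_ids(text)
        x = p["embed"][ids] + p["pos"][: len(ids)]
        h, n_heads = self.hidden_size, self.n_heads
        d = h // n_heads
        for layer in range(self.n_layers):
            q = x @ p[f"l{layer}.wq"]
            k = x @ p[f"l{layer}.wk"]
            v = x @ p[f"l{layer}.wv"]
            heads = []
            for i in range(n_heads):
                sl = slice(i * d, (i + 1) * d)
                att = _softmax(q[:, sl] @ k[:, sl].T / np.sqrt(d))
                heads.append(att @ v[:, sl])
            x = _layer_norm(x + np.concatenate(heads, axis=1) @ p[f"l{layer}.wo"])
            ff = _gelu(x @ p[f"l{layer}.ff1"]) @ p[f"l{layer}.ff2"]
            x = _layer_norm(x + ff)
        return x[0]

    def encode_batch(self, texts: Iterable[str]) -> np.ndarray:
        return np.vstack([self.encode(t) for t in texts])

    def logits(self, texts: Iterable[str]) -> np.ndarray:
        C = self.encode_batch(texts)
        return C @ self._params["head_w"].T + self._params["head_b"]

    def classify_proba(self, texts: Iterable[str]) -> np.ndarray:
        """Per-text class probabilities, each row summing to 1."""
        return _softmax(self.logits(texts), axis=1)

    def predict_scores(self, texts: Iterable[str]) -> np.ndarray:
        """Positive-class (class-1) probability per text."""
        return self.classify_proba(texts)[:, 1]

    def predict_labels(self, texts: Iterable[str]) -> np.ndarray:
        return (self.predict_scores(texts) >= 0.5).astype(int)

    def copy(self) -> "EncoderClassifier":
        clone = replace(self, _params={k: v.copy() for k, v in self._params.items()})
        return clone


def classify_proba(model: EncoderClassifier, texts: Iterable[str]) -> np.ndarray:
    """Functional alias for :meth:`EncoderClassifier.classify_proba`."""
    return model.classify_proba(texts)


def fine_tune(
    model: EncoderClassifier,
    corpus: Sequence[tuple[str, int]],
    *,
    epochs: int = 5,
    batch_size: int = 8,
    learning_rate: float = 0.05,
    seed: int = 0,
) -> tuple[EncoderClassifier, list[float]]:
    """Train the classification head with Adam on cross-entropy loss.

    The encoder body stays frozen (feature-extraction fine-tuning), so the
    head problem is convex.  Returns a new model and the per-epoch mean
    minibatch loss trace (one entry per epoch; ``epochs=0`` returns the
    model unchanged with an empty trace).  With a fixed seed the trace and
    the resulting model are fully reproducible.
    """
    if epochs < 0:
        raise ValueError("epochs must be >= 0")
    labels = np.asarray([lab for _, lab in corpus], dtype=int)
    if len(set(labels.tolist())) < 2:
        raise ValueError("both classes required in the fine-tuning corpus")
    out = model.copy()
    if epochs == 0:
        return out, []

    C = out.encode_batch([t for t, _ in corpus])           # frozen features
    W = out._params["head_w"]
    b = out._params["head_b"]
    mW, vW = np.zeros_like(W), np.zeros_like(W)
    mb, vb = np.zeros_like(b), np.zeros_like(b)
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    rng = np.random.default_rng(seed)
    onehot = np.eye(out.n_classes)[labels]
    step = 0
    trace: list[float] = []
    for _ in range(epochs):
        order = rng.permutation(len(corpus))
        batch_losses = []
        for start in range(0, len(corpus), batch_size):
            idx = order[start: start + batch_size]
            Cb, yb = C[idx], onehot[idx]
            probs = _softmax(Cb @ W.T + b, axis=1)
            loss = -np.mean(np.sum(yb * np.log(probs + 1e-12), axis=1))
            batch_losses.append(loss)
            grad_logits = (probs - yb) / len(idx)
            gW = grad_logits.T @ Cb
            gb = grad_logits.sum(axis=0)
            step += 1
            for g, m, v, theta in ((gW, mW, vW, W), (gb, mb, vb, b)):
                m *= beta1
                m += (1 - beta1) * g
                v *= beta2
                v += (1 - beta2) * g**2
                m_hat = m / (1 - beta1**step)
                v_hat = v / (1 - beta2**step)
                theta -= learning_rate * m_hat / (np.sqrt(v_hat) + eps)
        trace.append(float(np.mean(batch_losses)))
    out.trained = True
    return out, trace


@dataclass(frozen=True)
class EnsembleWeights:
    """Non-negative fusion weights for the encoder and NBSVM scores."""

    w_bert: float = 0.87
    w_nbsvm: float = 0.08
    normalize: bool = True

    def __post_init__(self) -> None:
        if self.w_bert < 0 or self.w_nbsvm < 0:
            raise ValueError("weights must be non-negative")
        if self.w_bert == 0 and self.w_nbsvm == 0:
            raise ValueError("at least one weight must be positive")


def ensemble_score(p_bert: float, p_nbsvm: float, w: EnsembleWeights) -> float:
    """Weighted-sum fusion of two [0, 1] scores.

    With ``normalize`` (default) the raw sum is divided by the weight sum
    so the fused score stays in [0, 1]; the hard label thresholds at 0.5.
    """
    p_bert = np.asarray(p_bert, dtype=float)
    p_nbsvm = np.asarray(p_nbsvm, dtype=float)
    if np.any((p_bert < 0) | (p_bert > 1)) or np.any((p_nbsvm < 0) | (p_nbsvm > 1)):
        raise ValueError("scores must lie in [0, 1]")
    raw = w.w_bert * p_bert + w.w_nbsvm * p_nbsvm
    if w.normalize:
        raw = raw / (w.w_bert + w.w_nbsvm)
    if raw.ndim == 0:
        return float(raw)
    return raw


def grid_search_weights(
    val_scores: Sequence[tuple[float, float, int]],
    grid_step: float = 0.1,
) -> tuple[EnsembleWeights, float]:
    """Exhaustive scan of (w_bert, w_nbsvm) over {0, step, …, 1}² \\ {(0,0)}.

    Returns the weight pair maximizing validation accuracy of the
    0.5-thresholded fused score.  Accuracy ties break toward the larger
    minimum decision margin (the most confident separation, so an
    anti-correlated member is zeroed out rather than merely out-voted),
    then toward larger w_bert, then larger w_nbsvm.  Deterministic and
    invariant to row order.
    """
    if not val_scores:
        raise ValueError("validation set is empty")
    if not 0.0 < grid_step <= 1.0:
        raise ValueError(f"grid_step must lie in (0, 1], got {grid_step}")
    p_b = np.array([s[0] for s in val_scores])
    p_n = np.array([s[1] for s in val_scores])
    y = np.array([s[2] for s in val_scores], dtype=int)
    n_steps = int(round(1.0 / grid_step))
    grid = [round(i * grid_step, 12) for i in range(n_steps + 1)]
    if grid[-1] != 1.0:
        grid.append(1.0)
    best: tuple[float, float, float, float] | None = None  # (acc, margin, w_b, w_n)
    for w_b in grid:
        for w_n in grid:
            if w_b == 0 and w_n == 0:
                continue
            fused = (w_b * p_b + w_n * p_n) / (w_b + w_n)
            acc = float(np.mean((fused >= 0.5).astype(int) == y))
            margin = round(float(np.min(np.abs(fused - 0.5))), 12)
            key = (acc, margin, w_b, w_n)
            if best is None or key > best:
                best = key
    acc, _, w_b, w_n = best
    return EnsembleWeights(w_bert=w_b, w_nbsvm=w_n), acc


@dataclass
class FusedSentimentModel:
    """One fused encoder + NBSVM binary sentiment model."""

    target: str
    encoder: EncoderClassifier
    nbsvm: LinearTextModel
    weights: EnsembleWeights
    validation_metrics: MetricsReport | None = None

    def predict_scores(self, texts: Sequence[str]) -> np.ndarray:
        p_b = self.encoder.predict_scores(texts)
        p_n = self.nbsvm.predict_scores([_WORD_RE.findall(t.lower()) for t in texts])
        return np.asarray(ensemble_score(p_b, p_n, self.weights))

    def predict_labels(self, texts: Sequence[str]) -> np.ndarray:
        return (self.predict_scores(texts) >= 0.5).astype(int)


@dataclass
class SentimentModelPair:
    """The two-model scheme: positive-vs-rest and negative-vs-rest."""

    positive_model: FusedSentimentModel
    negative_model: FusedSentimentModel
    metadata: dict = field(default_factory=dict)


def _train_member(
    target: str,
    texts: Sequence[str],
    tokens: Sequence[Sequence[str]],
    class3: Sequence[str],
    *,
    val_fraction: float,
    epochs: int,
    batch_size: int,
    learning_rate: float,
    grid_step: float,
    alpha: float,
    regularization: float,
    seed: int,
) -> FusedSentimentModel:
    y = np.array([1 if c == target else 0 for c in class3], dtype=int)
    if y.sum() == 0:
        raise ValueError(f"target class {target!r} absent from the corpus")
    if y.sum() == len(y):
        raise ValueError("both classes required (corpus is all target)")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(y))
    n_val = max(1, int(round(val_fraction * len(y))))
    val_idx, train_idx = order[:n_val], order[n_val:]
    # ensure both classes in the training split
    if len(set(y[train_idx].tolist())) < 2:
        raise ValueError("training split lost a class; corpus too small")

    dtm = build_dtm([tokens[i] for i in train_idx])
    nbsvm = train_nbsvm(
        dtm, y[train_idx], alpha=alpha, regularization=regularization, seed=seed
    )
    encoder = EncoderClassifier(seed=seed)
    encoder, _ = fine_tune(
        encoder,
        [(texts[i], int(y[i])) for i in train_idx],
        epochs=epochs,
        batch_size=batch_size,
        learning_rate=learning_rate,
        seed=seed,
    )
    val_texts = [texts[i] for i in val_idx]
    val_tokens = [tokens[i] for i in val_idx]
    p_b = encoder.predict_scores(val_texts)
    p_n = nbsvm.predict_scores(val_tokens)
    triples = list(zip(p_b.tolist(), p_n.tolist(), y[val_idx].tolist()))
    weights, _ = grid_search_weights(triples, grid_step=grid_step)
    fused = np.asarray(ensemble_score(p_b, p_n, weights))
    counts = ConfusionCounts.from_predictions(
        (fused >= 0.5).astype(int), y[val_idx]
    )
    report = compute_metrics(counts)
    return FusedSentimentModel(
        target=target,
        encoder=encoder,
        nbsvm=nbsvm,
        weights=weights,
        validation_metrics=report,
    )


def train_polarity_pair(
    corpus: Sequence[tuple[str, Sequence[str], str]],
    *,
    val_fraction: float = 0.2,
    epochs: int = 5,
    batch_size: int = 8,
    learning_rate: float = 0.05,
    grid_step: float = 0.1,
    alpha: float = 1.0,
    regularization: float = 1.0,
    seed: int = 0,
) -> SentimentModelPair:
    """Train the positive-vs-rest and negative-vs-rest fused models.

    ``corpus`` rows are (raw-or-clean text, tokens, class3 label); "rest"
    includes neutral tweets, so both binary tasks cover the whole corpus.
    Each member gets its own grid-searched fusion weights and validation
    metrics.
    """
    texts = [row[0] for row in corpus]
    tokens = [row[1] for row in corpus]
    class3 = [row[2] for row in corpus]
    members = {}
    for target in ("positive", "negative"):
        members[target] = _train_member(
            target,
            texts,
            tokens,
            class3,
            val_fraction=val_fraction,
            epochs=epochs,
            batch_size=batch_size,
            learning_rate=learning_rate,
            grid_step=grid_step,
            alpha=alpha,
            regularization=regularization,
            seed=seed,
        )
    return SentimentModelPair(
        positive_model=members["positive"],
        negative_model=members["negative"],
        metadata={
            "label_scheme": "one-vs-rest (rest includes neutral)",
            "val_fraction": val_fraction,
            "epochs": epochs,
            "batch_size": batch_size,
            "grid_step": grid_step,
            "seed": seed,
        },
    )
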