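"""Transformer head, fine-tuning, weighted-sum fusion and grid search."""

import numpy as np
import pytest

from vaxsent import CorpusSpec, gen_tweets
from vaxsent.ensemble import (
    EncoderClassifier,
    EnsembleWeights,
    ensemble_score,
    fine_tune,
    grid_search_weights,
    train_polarity_pair,
)

TEXTS = [
    "good vaccine experience",
    "bad fever after the shot",
    "second dose done",
    "happy and safe now",
]


class TestEncoder:
    def test_probabilities_form_a_simplex(self):
        model = EncoderClassifier(seed=1)
        probs = model.classify_proba(TEXTS)
        assert probs.shape == (4, 2)
        assert np.all(probs >= 0)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_batching_does_not_change_results(self):
        model = EncoderClassifier(seed=1)
        whole = model.classify_proba(TEXTS)
        singles = np.vstack([model.classify_proba([t]) for t in TEXTS])
        np.testing.assert_allclose(whole, singles, atol=1e-6)

    def test_deterministic_given_seed(self):
        p1 = EncoderClassifier(seed=3).classify_proba(TEXTS)
        p2 = EncoderClassifier(seed=3).classify_proba(TEXTS)
        np.testing.assert_array_equal(p1, p2)

    def test_long_text_truncated_not_rejected(self):
        model = EncoderClassifier(seed=0, max_len=16)
        long_text = " ".join(["word"] * 500)
        assert model.classify_proba([long_text]).shape == (1, 2)

    def test_unknown_encoder_rejected(self):
        with pytest.raises(ValueError, match="tiny-random"):
            EncoderClassifier(encoder_id="bert-large")

    def test_softmax_closed_forms(self):
        model = EncoderClassifier(seed=0)
        # force known logits through the head: zero weights, chosen biases
        model._params["head_w"] = np.zeros_like(model._params["head_w"])
        model._params["head_b"] = np.array([0.0, 0.0])
        np.testing.assert_allclose(
            model.classify_proba(["x"])[0], [0.5, 0.5], atol=1e-12
        )
        model._params["head_b"] = np.array([np.log(3.0), 0.0])
        np.testing.assert_allclose(
            model.classify_proba(["x"])[0], [0.75, 0.25], atol=1e-12
        )


@pytest.fixture(scope="module")
def labeled_corpus():
    tweets = gen_tweets(CorpusSpec(n_per_class=30, seed=11))
    return [
        (t.text, 1 if t.label == "positive" else 0)
        for t in tweets
        if t.label != "neutral"
    ]


class TestFineTune:
    def test_zero_epochs_is_identity(self, labeled_corpus):
        model = EncoderClassifier(seed=0)
        before = model.classify_proba([t for t, _ in labeled_corpus[:5]])
        tuned, trace = fine_tune(model, labeled_corpus, epochs=0)
        after = tuned.classify_proba([t for t, _ in labeled_corpus[:5]])
        np.testing.assert_array_equal(before, after)
        assert trace == []

    def test_loss_decreases_on_separable_corpus(self, labeled_corpus):
        model = EncoderClassifier(seed=0)
        _, trace = fine_tune(model, labeled_corpus, epochs=5, seed=0)
        assert len(trace) == 5
        assert trace[-1] < trace[0]

    def test_same_seed_same_trace(self, labeled_corpus):
        model = EncoderClassifier(seed=0)
        _, t1 = fine_tune(model, labeled_corpus, epochs=3, seed=9)
        _, t2 = fine_tune(model, labeled_corpus, epochs=3, seed=9)
        assert t1 == t2

    def test_original_model_untouched(self, labeled_corpus):
        model = EncoderClassifier(seed=0)
        before = model.classify_proba(["good shot"])
        fine_tune(model, labeled_corpus, epochs=2)
        np.testing.assert_array_equal(before, model.classify_proba(["good shot"]))

    def test_single_class_rejected(self):
        model = EncoderClassifier(seed=0)
        with pytest.raises(ValueError, match="both classes"):
            fine_tune(model, [("a", 1), ("b", 1)], epochs=1)


class TestEnsembleScore:
    def test_degenerate_weight_reduces_to_encoder(self):
        w = EnsembleWeights(w_bert=1.0, w_nbsvm=0.0)
        assert ensemble_score(0.9, 0.1, w) == pytest.approx(0.9)

    def test_printed_weight_arithmetic(self):
        w = EnsembleWeights(w_bert=0.87, w_nbsvm=0.08, normalize=True)
        expected = (0.87 * 0.8 + 0.08 * 0.5) / 0.95
        assert ensemble_score(0.8, 0.5, w) == pytest.approx(expected)
        assert expected == pytest.approx(0.7747, abs=1e-4)

    def test_boundary_preserved_under_normalization(self):
        w = EnsembleWeights()
        assert ensemble_score(1.0, 1.0, w) == pytest.approx(1.0)
        assert ensemble_score(0.0, 0.0, w) == pytest.approx(0.0)

    def test_raw_mode_skips_normalization(self):
        w = EnsembleWeights(w_bert=0.87, w_nbsvm=0.08, normalize=False)
        assert ensemble_score(0.8, 0.5, w) == pytest.approx(0.87 * 0.8 + 0.08 * 0.5)

    def test_monotone_in_each_input(self):
        w = EnsembleWeights()
        grid = np.linspace(0, 1, 11)
        scores = [ensemble_score(p, 0.4, w) for p in grid]
        assert all(a <= b + 1e-12 for a, b in zip(scores, scores[1:]))
        scores = [ensemble_score(0.4, p, w) for p in grid]
        assert all(a <= b + 1e-12 for a, b in zip(scores, scores[1:]))

    def test_invalid_weights_rejected(self):
        with pytest.raises(ValueError):
            EnsembleWeights(w_bert=0.0, w_nbsvm=0.0)
        with pytest.raises(ValueError):
            EnsembleWeights(w_bert=-0.1, w_nbsvm=0.5)
        with pytest.raises(ValueError):
            ensemble_score(1.2, 0.5, EnsembleWeights())


class TestGridSearch:
    def test_recovers_zero_weight_for_anticorrelated_model(self):
        """Encoder perfect, NBSVM anti-correlated, on a 10-point fixture."""
        labels = [0, 1] * 5
        triples = [(float(y), 1.0 - y, y) for y in labels]
        weights, acc = grid_search_weights(triples, grid_step=0.1)
        assert weights.w_nbsvm == 0.0
        assert acc == 1.0

    def test_identical_models_tie_break(self):
        triples = [(0.9, 0.9, 1), (0.1, 0.1, 0)]
        weights, acc = grid_search_weights(triples, grid_step=0.5)
        assert acc == 1.0
        assert (weights.w_bert, weights.w_nbsvm) == (1.0, 1.0)

    def test_grid_step_one_scans_three_candidates(self):
        triples = [(0.9, 0.1, 1)]
        weights, _ = grid_search_weights(triples, grid_step=1.0)
        assert (weights.w_bert, weights.w_nbsvm) in {(1.0, 1.0), (1.0, 0.0), (0.0, 1.0)}

    def test_row_order_invariant(self):
        rng = np.random.default_rng(5)
        triples = [
            (float(rng.random()), float(rng.random()), int(rng.integers(2)))
            for _ in range(20)
        ]
        w1, a1 = grid_search_weights(triples, grid_step=0.25)
        w2, a2 = grid_search_weights(list(reversed(triples)), grid_step=0.25)
        assert (w1.w_bert, w1.w_nbsvm, a1) == (w2.w_bert, w2.w_nbsvm, a2)

    def test_empty_validation_rejected(self):
        with pytest.raises(ValueError):
            grid_search_weights([], grid_step=0.5)


@pytest.fixture(scope="module")
def pair():
    tweets = gen_tweets(CorpusSpec(n_per_class=50, seed=13))
    corpus = [(t.text, tuple(t.text.split()), t.label) for t in tweets]
    return train_polarity_pair(corpus, epochs=3, seed=0)


class TestPolarityPair:
    def test_both_members_trained_with_their_targets(self, pair):
        assert pair.positive_model.target == "positive"
        assert pair.negative_model.target == "negative"

    def test_noise_free_validation_is_perfect(self, pair):
        """On the separable corpus the fused positive model is exact."""
        assert pair.positive_model.validation_metrics.accuracy == 1.0

    def test_missing_class_errors(self):
        tweets = gen_tweets(CorpusSpec(n_per_class=20, seed=1))
        corpus = [
            (t.text, tuple(t.text.split()), t.label)
            for t in tweets
            if t.label != "negative"
        ]
        with pytest.raises(ValueError, match="negative"):
            train_polarity_pair(corpus, epochs=1, seed=0)

    def test_zero_nbsvm_weight_reduces_to_encoder_labels(self, pair):
        member = pair.positive_model
        texts = ["good happy covid shot", "bad sick fever dose", "covid people"]
        forced = EnsembleWeights(w_bert=1.0, w_nbsvm=0.0)
        fused = np.asarray(
            [
                (p >= 0.5)
                for p in [
                    ensemble_score(b, n, forced)
                    for b, n in zip(
                        member.encoder.predict_scores(texts),
                        member.nbsvm.predict_scores([t.split() for t in texts]),
                    )
                ]
            ]
        )
        np.testing.assert_array_equal(
            fused, member.encoder.predict_labels(texts).astype(bool)
        )
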