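"""IAT mechanics: tokenization, attention properties, classification heads,
saliency normalization, training contracts. Accuracy-level checks live in
the acceptance suite."""

import numpy as np
import pytest

from cardiopatch import iat, synth
from cardiopatch.nn import Tensor

TINY = iat.IATConfig(slice_len=10, embed_dim=8, n_heads=2, n_layers=1,
                     mlp_dim=16, conv_kernel=3, conv_channels=2,
                     input_len=40, dropout=0.0, seed=0)


@pytest.fixture(scope="module")
def tiny_model():
    return iat.IATModel(TINY)


class TestTokenize:
    def test_token_count_and_spans(self):
        cfg = iat.IATConfig(seed=0)
        model = iat.IATModel(cfg)
        seq = model.tokenize(np.zeros(2500))
        assert seq.tokens.shape == (51, cfg.embed_dim)
        assert seq.slice_spans[0] == (0, 50)
        assert seq.slice_spans[-1] == (2450, 2500)
        assert seq.dropped_samples == 0

    def test_remainder_samples_dropped_and_reported(self, tiny_model):
        seq = tiny_model.tokenize(np.zeros(47))
        assert len(seq.slice_spans) == 4
        assert seq.dropped_samples == 7

    def test_tokenization_is_deterministic(self, tiny_model):
        w = np.random.default_rng(0).standard_normal(40)
        a = tiny_model.tokenize(w)
        b = tiny_model.tokenize(w)
        assert np.array_equal(a.tokens, b.tokens)

    def test_window_shorter_than_slice_rejected(self, tiny_model):
        with pytest.raises(ValueError):
            tiny_model.tokenize(np.zeros(5))


class TestEncode:
    def test_attention_rows_sum_to_one_all_layers_heads(self, tiny_model):
        w = np.random.default_rng(1).standard_normal(40)
        attn = tiny_model.attention_tensor(w)
        assert attn.shape == (1, 2, 5, 5)
        assert np.allclose(attn.sum(axis=-1), 1.0, atol=1e-6)

    def test_eval_forward_is_deterministic(self, tiny_model):
        w = np.random.default_rng(2).standard_normal((3, 40))
        a = tiny_model.predict_proba(w)
        b = tiny_model.predict_proba(w)
        assert np.array_equal(a, b)


class TestClassify:
    def test_probabilities_sum_to_one(self, tiny_model):
        w = np.random.default_rng(3).standard_normal((4, 40))
        probs = iat.classify(tiny_model, w)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-9)

    def test_zero_weight_head_gives_uniform(self, tiny_model):
        tiny_model.head.W.data[:] = 0
        tiny_model.head.b.data[:] = 0
        probs = iat.classify(tiny_model, np.random.default_rng(4)
                             .standard_normal(40))
        assert np.allclose(probs, 0.25, atol=1e-12)


class TestSaliency:
    def test_uniform_attention_gives_uniform_saliency(self):
        n_tok = 4
        attn = np.full((1, 2, n_tok + 1, n_tok + 1), 1.0 / (n_tok + 1))
        spans = [(i * 10, (i + 1) * 10) for i in range(n_tok)]
        sal = iat.saliency(attn, spans, 40)
        assert np.allclose(sal.per_sample, 1.0 / 40)

    @pytest.mark.parametrize("method", ["cls", "rollout"])
    def test_saliency_sums_to_one_and_nonnegative(self, tiny_model, method):
        w = np.random.default_rng(5).standard_normal(40)
        sal = iat.saliency_for_window(tiny_model, w, method=method)
        assert sal.per_sample.sum() == pytest.approx(1.0, abs=1e-6)
        assert np.all(sal.per_sample >= 0)

    def test_saliency_constant_within_slices(self, tiny_model):
        w = np.random.default_rng(6).standard_normal(40)
        sal = iat.saliency_for_window(tiny_model, w)
        for on, off in tiny_model.tokenize(w).slice_spans:
            assert np.ptp(sal.per_sample[on:off]) == 0

    def test_saliency_invariant_to_input_scaling(self, tiny_model):
        """End-to-end: window normalization makes saliency gain-invariant."""
        from cardiopatch import preprocess
        rng = np.random.default_rng(7)
        x = rng.standard_normal(40)
        w1, _ = preprocess.normalize(x)
        w2, _ = preprocess.normalize(3.7 * x + 0.5)
        s1 = iat.saliency_for_window(tiny_model, w1).per_sample
        s2 = iat.saliency_for_window(tiny_model, w2).per_sample
        assert np.allclose(s1, s2, atol=1e-12)


class TestTraining:
    def test_parameter_count_matches_closed_form(self):
        model = iat.IATModel(TINY)
        c = TINY
        conv_pos = c.slice_len - c.conv_kernel + 1
        expected = (
            c.conv_kernel * c.conv_channels + c.conv_channels      # conv
            + (conv_pos * c.conv_channels + 1) * c.embed_dim       # projection
            + c.embed_dim                                          # CLS
            + (c.n_tokens + 1) * c.embed_dim                       # positions
            + c.n_layers * (
                4 * (c.embed_dim + 1) * c.embed_dim                # q,k,v,o
                + (c.embed_dim + 1) * c.mlp_dim
                + (c.mlp_dim + 1) * c.embed_dim
                + 4 * c.embed_dim)                                 # 2 layer norms
            + 2 * c.embed_dim                                      # final norm
            + c.n_classes * c.embed_dim                            # class queries
            + 2 * (c.embed_dim + 1) * c.embed_dim                  # readout k, v
            + (c.embed_dim + 1) * c.n_classes)                     # head
        assert model.n_parameters() == expected

    def test_training_reduces_loss_and_is_seed_deterministic(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((24, 40))
        X[::2] += 2.0
        y = np.array(["NR", "MI"] * 12)
        cfg = iat.IATConfig(**{**TINY.__dict__, "epochs": 5})
        _, w1 = iat.train(None, y, cfg, windows=X)
        _, w2 = iat.train(None, y, cfg, windows=X)
        assert w1.loss_log[-1] < w1.loss_log[0]
        assert abs(w1.loss_log[-1] - w2.loss_log[-1]) < 1e-6

    def test_single_class_dataset_rejected(self):
        X = np.zeros((8, 40))
        with pytest.raises(ValueError):
            iat.train(None, np.array(["NR"] * 8), TINY, windows=X)


class TestEvaluate:
    def test_agreeing_labels_yield_diagonal_confusion(self, tiny_model):
        """Labelling windows with the model's own predictions must give
        accuracy 1 and a purely diagonal confusion matrix."""
        X = np.random.default_rng(8).standard_normal((4, 40))
        labels = [synth.CLASS_LABELS[p] for p in
                  np.argmax(tiny_model.predict_proba(X), axis=1)]
        res = iat.evaluate(tiny_model, None, labels, windows=X)
        assert res["accuracy"] == 1.0
        assert np.trace(res["confusion"]) == 4

    def test_empty_test_set_rejected(self, tiny_model):
        with pytest.raises(ValueError):
            iat.evaluate(tiny_model, None, np.array([]),
                         windows=np.zeros((0, 40)))
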