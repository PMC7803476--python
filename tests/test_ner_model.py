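"""Sequence labeler: autodiff, CRF, auxiliary losses, reconstruction,
feature encoding and a small end-to-end training sanity check."""

import itertools

import numpy as np
import pytest

from famhx.autodiff import Adam, Tensor, bce_with_logits, concat
from famhx.docmodel import Document, Token
from famhx.ner_model import (
    TAG2ID,
    LabeledSentence,
    ModelConfig,
    NERModel,
    _path_score,
    build_vocab,
    crf_nll,
    ed_loss,
    encode_external_features,
    make_labeled_sentences,
    predict_entities,
    reconstruct_entities,
    total_loss,
    train_cv,
    train_model,
    viterbi_decode,
)
from famhx.observation import DiseaseDictionary
from famhx.preprocess import TAGSET, tokenize_words
from famhx.synthgen import GenConfig, generate_corpus


def _tok(i, start, end, surface, word):
    return Token(0, start, end, surface, word)


class TestAutodiff:
    def test_matmul_and_broadcast_gradients_match_numeric(self):
        rng = np.random.default_rng(0)
        a = Tensor(rng.normal(size=(3, 4)), requires_grad=True)
        b = Tensor(rng.normal(size=(4, 2)), requires_grad=True)
        c = Tensor(rng.normal(size=(2,)), requires_grad=True)
        loss = (((a @ b) + c).tanh() ** 2.0).sum()
        loss.backward()
        eps = 1e-6
        for tensor in (a, b, c):
            numeric = np.zeros_like(tensor.data)
            flat = tensor.data.reshape(-1)
            for i in range(flat.size):
                orig = flat[i]
                flat[i] = orig + eps
                lp = (((a.data @ b.data) + c.data)).copy()
                lp = (np.tanh(lp) ** 2).sum()
                flat[i] = orig - eps
                lm = (((a.data @ b.data) + c.data)).copy()
                lm = (np.tanh(lm) ** 2).sum()
                flat[i] = orig
                numeric.reshape(-1)[i] = (lp - lm) / (2 * eps)
            assert np.allclose(numeric, tensor.grad, atol=1e-6)

    def test_logsumexp_softmax_consistency(self):
        x = Tensor(np.array([[1.0, 2.0, 3.0]]), requires_grad=True)
        sm = x.softmax(axis=1)
        assert np.allclose(sm.data.sum(), 1.0)
        sm.sum().backward()
        assert np.allclose(x.grad, 0.0, atol=1e-12)  # softmax rows sum to 1

    def test_bce_with_logits_matches_formula(self):
        z = Tensor(np.array([0.5, -1.2, 3.0]), requires_grad=True)
        y = np.array([1.0, 0.0, 1.0])
        loss = bce_with_logits(z, y)
        sig = 1 / (1 + np.exp(-z.data))
        expected = -(y * np.log(sig) + (1 - y) * np.log(1 - sig)).mean()
        assert np.isclose(loss.data, expected)
        loss.backward()
        assert np.allclose(z.grad, (sig - y) / 3)

    def test_adam_reduces_quadratic(self):
        x = Tensor(np.array([5.0, -3.0]), requires_grad=True)
        opt = Adam([x], lr=0.1)
        for _ in range(200):
            opt.zero_grad()
            loss = (x**2.0).sum()
            loss.backward()
            opt.step()
        assert np.abs(x.data).max() < 0.1

    def test_getitem_scatter_add(self):
        e = Tensor(np.zeros((4, 3)), requires_grad=True)
        idx = np.array([1, 1, 2])
        out = e[idx].sum()
        out.backward()
        assert e.grad[1].sum() == 6.0  # row used twice
        assert e.grad[0].sum() == 0.0


class TestCRF:
    def _random_instance(self, rng, n, t=5):
        return (
            rng.normal(size=(n, t)),
            rng.normal(size=(t, t)),
            rng.normal(size=t),
            rng.normal(size=t),
        )

    def test_single_tag_tagset_loss_zero(self):
        e = np.array([[0.3], [0.7]])
        loss = crf_nll(Tensor(e), [0, 0], Tensor([[0.1]]), Tensor([0.2]), Tensor([0.5]))
        assert np.isclose(loss.data, 0.0)

    def test_nll_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            n = int(rng.integers(1, 4))
            t = 3
            e, tr, st, en = self._random_instance(rng, n, t)
            tags = rng.integers(0, t, size=n).tolist()
            nll = crf_nll(Tensor(e), tags, Tensor(tr), Tensor(st), Tensor(en)).data
            scores = [
                _path_score(e, list(p), tr, st, en)
                for p in itertools.product(range(t), repeat=n)
            ]
            expected = np.logaddexp.reduce(scores) - _path_score(e, tags, tr, st, en)
            assert np.isclose(nll, expected, atol=1e-10)
            assert nll >= -1e-10

    def test_path_probabilities_sum_to_one(self):
        rng = np.random.default_rng(2)
        e, tr, st, en = self._random_instance(rng, 3, 4)
        total = 0.0
        for path in itertools.product(range(4), repeat=3):
            nll = crf_nll(Tensor(e), list(path), Tensor(tr), Tensor(st), Tensor(en))
            total += np.exp(-nll.data)
        assert np.isclose(total, 1.0, atol=1e-9)

    def test_viterbi_equals_exhaustive_argmax(self):
        rng = np.random.default_rng(3)
        for _ in range(25):
            n = int(rng.integers(1, 7))
            e, tr, st, en = self._random_instance(rng, n, 5)
            best = max(
                itertools.product(range(5), repeat=n),
                key=lambda p: _path_score(e, list(p), tr, st, en),
            )
            assert tuple(viterbi_decode(e, tr, st, en)) == best

    def test_viterbi_tie_breaks_to_lower_index(self):
        e = np.zeros((3, 4))
        tr = np.zeros((4, 4))
        assert viterbi_decode(e, tr, np.zeros(4), np.zeros(4)) == [0, 0, 0]

    def test_peaked_emissions_neutral_transitions(self):
        e = np.array([[9.0, 0, 0, 0, 0], [0, 9.0, 0, 0, 0], [0, 0, 0, 0, 9.0]])
        path = viterbi_decode(e, np.zeros((5, 5)), np.zeros(5), np.zeros(5))
        assert path == [0, 1, 4]


class TestAuxiliaryLosses:
    def test_perfect_logits_drive_loss_to_zero(self):
        tags = [TAG2ID["B-Obs"], TAG2ID["O"]]
        logits = Tensor(np.array([30.0, -30.0]))
        assert ed_loss(logits, tags).data < 1e-9

    def test_hand_computed_three_token_case(self):
        tags = [TAG2ID["O"], TAG2ID["B-Obs"], TAG2ID["I-Obs"]]
        z = np.array([0.0, 1.0, -1.0])
        expected = np.mean(
            [
                -np.log(1 - 1 / (1 + np.exp(-0.0))),
                -np.log(1 / (1 + np.exp(-1.0))),
                -np.log(1 / (1 + np.exp(1.0))),
            ]
        )
        assert np.isclose(ed_loss(Tensor(z), tags).data, expected)

    def test_total_loss_combination(self):
        ner = Tensor(2.0)
        ed = Tensor(4.0)
        assert total_loss(ner, ed, 0.5, True).data == pytest.approx(3.0)
        assert total_loss(ner, ed, 0.5, False).data == pytest.approx(2.0)
        assert total_loss(ner, None, 0.5, True).data == pytest.approx(2.0)


class TestExternalFeatures:
    def test_zero_one_two_coding_normalized(self):
        toks = [_tok(0, 0, 3, "has", 0), _tok(0, 4, 8, "lung", 1), _tok(0, 9, 15, "cancer", 2)]
        feats = encode_external_features(toks, [(4, 15)])
        assert feats.tolist() == [0.0, 0.5, 1.0]

    def test_no_annotations_all_zero(self):
        toks = [_tok(0, 0, 3, "has", 0)]
        assert encode_external_features(toks, []).tolist() == [0.0]

    def test_single_token_annotation(self):
        toks = [_tok(0, 0, 3, "has", 0), _tok(0, 4, 10, "cancer", 1)]
        assert encode_external_features(toks, [(4, 10)]).tolist() == [0.0, 0.5]


class TestReconstruction:
    def _pieces(self):
        return [
            _tok(0, 0, 3, "car", 0),
            _tok(0, 3, 6, "##cin", 0),
            _tok(0, 6, 9, "##oma", 0),
        ]

    def test_partial_word_promoted_to_whole_entity(self):
        tags = ["O", "B-Obs", "I-Obs"]
        assert reconstruct_entities(self._pieces(), tags) == [
            "B-Obs", "I-Obs", "I-Obs",
        ]

    def test_whole_word_tags_unchanged(self):
        tags = ["B-Obs", "I-Obs", "I-Obs"]
        assert reconstruct_entities(self._pieces(), tags) == tags

    def test_all_o_unchanged(self):
        assert reconstruct_entities(self._pieces(), ["O", "O", "O"]) == ["O"] * 3

    def test_conflicting_classes_majority_then_earliest(self):
        toks = self._pieces() + [_tok(0, 9, 12, "##x", 0)]
        tags = ["B-Obs", "I-PFM", "I-PFM", "O"]
        assert reconstruct_entities(toks, tags) == ["B-PFM"] + ["I-PFM"] * 3
        tags_tie = ["B-Obs", "I-PFM", "O", "O"]
        assert reconstruct_entities(toks, tags_tie) == ["B-Obs"] + ["I-Obs"] * 3

    def test_idempotent_and_never_shorter_on_random_sequences(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            n_words = int(rng.integers(1, 5))
            toks, pos = [], 0
            for w in range(n_words):
                for _p in range(int(rng.integers(1, 4))):
                    toks.append(_tok(0, pos, pos + 2, "xx", w))
                    pos += 2
            tags = [TAGSET[i] for i in rng.integers(0, len(TAGSET), size=len(toks))]
            once = reconstruct_entities(toks, tags)
            assert reconstruct_entities(toks, once) == once
            entity_before = sum(t != "O" for t in tags)
            entity_after = sum(t != "O" for t in once)
            assert entity_after >= entity_before


class TestTraining:
    def _tiny_corpus(self):
        docs, _gold = generate_corpus(GenConfig(n_docs=12, seed=3))
        return make_labeled_sentences(docs)

    def test_memorization_on_tiny_corpus(self):
        corpus = self._tiny_corpus()[:20]
        cfg = ModelConfig(
            embed_dim=16, hidden=24, epochs=12, iters_per_epoch=25, batch=16,
            patience=12, seed=0,
        )
        model, history = train_model(corpus, corpus, cfg)
        from famhx.ner_model import span_prf

        metrics = span_prf(model, corpus)
        assert metrics["overall"]["f1"] > 0.8  # overfits its own training set

    def test_training_is_deterministic(self):
        corpus = self._tiny_corpus()[:12]
        cfg = ModelConfig(
            embed_dim=8, hidden=8, epochs=2, iters_per_epoch=5, batch=4, seed=1
        )
        m1, h1 = train_model(corpus, corpus, cfg)
        m2, h2 = train_model(corpus, corpus, cfg)
        assert h1 == h2
        for name in m1.params:
            assert np.array_equal(m1.params[name].data, m2.params[name].data)

    def test_empty_training_partition_fatal(self):
        cfg = ModelConfig(embed_dim=8, hidden=8)
        with pytest.raises(ValueError, match="empty"):
            train_model([], [], cfg)

    def test_cv_produces_fold_reports_and_respects_seed(self):
        corpus = self._tiny_corpus()
        cfg = ModelConfig(
            embed_dim=8, hidden=8, epochs=1, iters_per_epoch=4, batch=4,
            folds=3, seed=2,
        )
        models, reports = train_cv(corpus, cfg)
        assert len(models) == len(reports) == 3
        _models2, reports2 = train_cv(corpus, cfg)
        assert reports == reports2

    def test_forward_shape_and_inference_determinism(self):
        corpus = self._tiny_corpus()[:5]
        cfg = ModelConfig(embed_dim=8, hidden=8, seed=0)
        model = NERModel(cfg, build_vocab(corpus))
        sent = corpus[0]
        emissions, _ = model.forward(sent.tokens)
        assert emissions.shape == (len(sent.tokens), len(TAGSET))
        again, _ = model.forward(sent.tokens)
        assert np.array_equal(emissions.data, again.data)

    def test_empty_document_predicts_nothing(self):
        cfg = ModelConfig(embed_dim=8, hidden=8, seed=0)
        model = NERModel(cfg, {"<unk>": 0})
        members, obs = predict_entities(Document("d", ""), model)
        assert members == [] and obs == []

    def test_checkpoint_round_trip(self, tmp_path):
        corpus = self._tiny_corpus()[:8]
        cfg = ModelConfig(embed_dim=8, hidden=8, epochs=1, iters_per_epoch=3,
                          batch=4, seed=0)
        model, _ = train_model(corpus, corpus, cfg)
        path = tmp_path / "model.json"
        model.save(path)
        loaded = NERModel.load(path)
        sent = corpus[0]
        assert loaded.decode(sent.tokens) == model.decode(sent.tokens)

    def test_subword_predictions_align_with_word_boundaries(self):
        docs, _gold = generate_corpus(GenConfig(n_docs=6, seed=8))
        cfg = ModelConfig(
            embed_dim=8, hidden=8, epochs=1, iters_per_epoch=3, batch=4,
            seed=0, tokenizer="subword",
        )
        corpus = make_labeled_sentences(docs, config=cfg)
        model, _ = train_model(corpus, corpus, cfg)
        doc = docs[0]
        _members, obs = predict_entities(doc, model)
        from famhx.preprocess import split_sentences

        sents = {s.index: s for s in split_sentences(doc)}
        for o in obs:
            s = sents[o.span[0]]
            before = s.text[o.span[1] - 1 : o.span[1]]
            after = s.text[o.span[2] : o.span[2] + 1]
            assert before in ("", " ") or not before.isalnum()
            assert after in ("", " ") or not after.isalnum()
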