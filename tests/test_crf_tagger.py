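import itertools

import numpy as np
import pytest

from subtag.annotation_io import AnnotatedDocument, EntitySpan, Scheme
from subtag.crf_tagger import (
    BiRnnCrfTagger,
    CrfParameters,
    TaggerConfig,
    crf_log_partition,
    crf_negative_log_likelihood,
    crf_nll_and_grad,
    crf_viterbi,
)
from subtag.labeling import decode_entities, gold_label_sequence


def enumerate_path_scores(emissions, params):
    L, T = emissions.shape
    out = {}
    for path in itertools.product(range(T), repeat=L):
        s = params.start[path[0]] + params.end[path[-1]]
        s += sum(emissions[t, y] for t, y in enumerate(path))
        s += sum(params.transitions[path[t], path[t + 1]]
                 for t in range(L - 1))
        out[path] = s
    return out


def random_instance(rng, max_len=6, max_tags=4):
    L = int(rng.integers(1, max_len + 1))
    T = int(rng.integers(2, max_tags + 1))
    emissions = rng.normal(scale=2.0, size=(L, T))
    params = CrfParameters(rng.normal(size=(T, T)), rng.normal(size=T),
                           rng.normal(size=T))
    return emissions, params


class TestCrfPrimitives:
    def test_uniform_scores_closed_form(self):
        params = CrfParameters.zeros(2)
        emissions = np.zeros((2, 2))
        assert crf_log_partition(emissions, params) == pytest.approx(np.log(4))

    def test_single_position_is_logsumexp(self):
        rng = np.random.default_rng(1)
        emissions = rng.normal(size=(1, 3))
        params = CrfParameters(rng.normal(size=(3, 3)), rng.normal(size=3),
                               rng.normal(size=3))
        expected = np.logaddexp.reduce(params.start + emissions[0] + params.end)
        assert crf_log_partition(emissions, params) == pytest.approx(expected)

    def test_partition_matches_enumeration(self):
        rng = np.random.default_rng(7)
        for _ in range(60):
            emissions, params = random_instance(rng)
            scores = enumerate_path_scores(emissions, params)
            expected = np.logaddexp.reduce(np.array(list(scores.values())))
            assert crf_log_partition(emissions, params) == pytest.approx(
                expected, abs=1e-8)

    def test_viterbi_matches_enumerated_argmax(self):
        rng = np.random.default_rng(8)
        for _ in range(60):
            emissions, params = random_instance(rng)
            scores = enumerate_path_scores(emissions, params)
            path, score = crf_viterbi(emissions, params)
            best = max(scores.values())
            assert score == pytest.approx(best, abs=1e-9)
            assert scores[tuple(path)] == pytest.approx(best, abs=1e-9)

    def test_viterbi_score_never_exceeds_partition(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            emissions, params = random_instance(rng)
            _, score = crf_viterbi(emissions, params)
            assert score <= crf_log_partition(emissions, params) + 1e-9

    def test_viterbi_strong_emissions_follow_them(self):
        emissions = np.array([[0.0, 10.0]] * 5)
        path, _ = crf_viterbi(emissions, CrfParameters.zeros(2))
        assert path == [1] * 5

    def test_viterbi_ties_break_to_lower_index(self):
        path, _ = crf_viterbi(np.zeros((4, 3)), CrfParameters.zeros(3))
        assert path == [0] * 4

    def test_non_finite_emissions_rejected(self):
        params = CrfParameters.zeros(2)
        with pytest.raises(ValueError, match="non-finite"):
            crf_log_partition(np.array([[np.inf, 0.0]]), params)


class TestCrfNll:
    def test_single_tag_alphabet_zero_loss(self):
        params = CrfParameters.zeros(1)
        nll = crf_negative_log_likelihood(np.zeros((4, 1)), params, [0] * 4)
        assert nll == pytest.approx(0.0, abs=1e-12)

    def test_uniform_two_tag_loss_is_log4(self):
        params = CrfParameters.zeros(2)
        for gold in ([0, 0], [0, 1], [1, 1]):
            nll = crf_negative_log_likelihood(np.zeros((2, 2)), params, gold)
            assert nll == pytest.approx(np.log(4))

    def test_nll_nonnegative(self):
        rng = np.random.default_rng(10)
        for _ in range(30):
            emissions, params = random_instance(rng)
            gold = rng.integers(0, emissions.shape[1], size=emissions.shape[0])
            assert crf_negative_log_likelihood(emissions, params, gold) >= -1e-10

    def test_gold_outside_alphabet_rejected(self):
        params = CrfParameters.zeros(2)
        with pytest.raises(ValueError, match="alphabet"):
            crf_negative_log_likelihood(np.zeros((2, 2)), params, [0, 5])

    def test_gradients_match_finite_differences(self):
        rng = np.random.default_rng(11)
        eps = 1e-6
        for _ in range(10):
            emissions, params = random_instance(rng, max_len=5, max_tags=3)
            L, T = emissions.shape
            gold = rng.integers(0, T, size=L)
            nll, d_emis, d_trans, d_start, d_end = crf_nll_and_grad(
                emissions, params, gold)
            for _c in range(3):
                i, j = int(rng.integers(L)), int(rng.integers(T))
                e2 = emissions.copy(); e2[i, j] += eps
                e3 = emissions.copy(); e3[i, j] -= eps
                num = (crf_negative_log_likelihood(e2, params, gold)
                       - crf_negative_log_likelihood(e3, params, gold)) / (2 * eps)
                assert abs(num - d_emis[i, j]) <= 1e-4 * (1 + abs(num))
            i, j = int(rng.integers(T)), int(rng.integers(T))
            t2 = params.transitions.copy(); t2[i, j] += eps
            t3 = params.transitions.copy(); t3[i, j] -= eps
            num = (crf_negative_log_likelihood(emissions, CrfParameters(t2, params.start, params.end), gold)
                   - crf_negative_log_likelihood(emissions, CrfParameters(t3, params.start, params.end), gold)) / (2 * eps)
            assert abs(num - d_trans[i, j]) <= 1e-4 * (1 + abs(num))


def tiny_config(**kw):
    defaults = dict(char_embedding_dim=16, hidden_dim=24, epochs=8, seed=3,
                    batch_size=8)
    defaults.update(kw)
    return TaggerConfig(**defaults)


def one_sentence_doc():
    return AnnotatedDocument(
        "t", "dora bada mute", (EntitySpan(0, 4, "DZ"), EntitySpan(10, 14, "BP")))


class TestBiRnnCrfTagger:
    def test_memorizes_repeated_sentence(self):
        docs = [one_sentence_doc()] * 50
        tagger = BiRnnCrfTagger(tiny_config(epochs=15)).fit(docs)
        pred = tagger.predict(docs[0])
        assert pred.labels == gold_label_sequence(docs[0], Scheme.IOB_CHAR).labels

    def test_same_seed_identical_parameters(self):
        docs = [one_sentence_doc()] * 10
        a = BiRnnCrfTagger(tiny_config(epochs=2)).fit(docs)
        b = BiRnnCrfTagger(tiny_config(epochs=2)).fit(docs)
        for k in a.params:
            assert np.array_equal(a.params[k], b.params[k])

    def test_training_loss_decreases(self):
        docs = [one_sentence_doc()] * 30
        tagger = BiRnnCrfTagger(tiny_config(epochs=10)).fit(docs)
        assert tagger.loss_history[-1] < tagger.loss_history[0]

    def test_empty_corpus_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            BiRnnCrfTagger(tiny_config()).fit([])

    def test_prediction_length_and_scheme(self):
        docs = [one_sentence_doc()] * 10
        tagger = BiRnnCrfTagger(tiny_config(epochs=2)).fit(docs)
        pred = tagger.predict(docs[0])
        assert pred.scheme is Scheme.IOB_CHAR
        assert len(pred) == len(docs[0].text)

    def test_unseen_characters_do_not_fail(self):
        docs = [one_sentence_doc()] * 10
        tagger = BiRnnCrfTagger(tiny_config(epochs=2)).fit(docs)
        pred = tagger.predict("Zq# xy")
        assert len(pred) == 6

    def test_all_o_training_predicts_all_o(self):
        docs = [AnnotatedDocument("o", "dora bada", ())] * 20
        tagger = BiRnnCrfTagger(tiny_config(epochs=10)).fit(docs)
        assert set(tagger.predict(docs[0]).labels) == {"O"}

    def test_predictions_decodable(self):
        docs = [one_sentence_doc()] * 30
        tagger = BiRnnCrfTagger(tiny_config(epochs=15)).fit(docs)
        decoded = decode_entities(docs[0].text, tagger.predict(docs[0]))
        assert decoded.spans == list(docs[0].spans)

    def test_checkpoint_round_trip(self, tmp_path):
        docs = [one_sentence_doc()] * 10
        tagger = BiRnnCrfTagger(tiny_config(epochs=2)).fit(docs)
        path = tmp_path / "model.npz"
        tagger.save(path)
        again = BiRnnCrfTagger.load(path)
        assert again.predict(docs[0]).labels == tagger.predict(docs[0]).labels

    def test_untrained_predict_rejected(self):
        with pytest.raises(ValueError, match="not trained"):
            BiRnnCrfTagger(tiny_config()).predict("abc")

    def test_config_validation(self):
        with pytest.raises(ValueError, match="positive"):
            TaggerConfig(hidden_dim=0)
        with pytest.raises(ValueError, match="include O"):
            TaggerConfig(label_alphabet=("B-DZ",))
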