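"""Character-level bidirectional-RNN CRF benchmark tagger.

The benchmark reads a document as its character sequence (whitespace made
visible as a placeholder character), embeds each character, runs a
bidirectional recurrent (tanh) encoder, and scores label paths with a
linear-chain CRF: a path's score is the sum of per-position emission scores
and tag-bigram transition scores, plus start/end scores, normalized by the
log-sum over all paths (the forward algorithm).  Training minimizes the
negative log-likelihood of the gold char-level IOB path; decoding is
Viterbi.

Everything — forward/backward recursions, CRF marginals, and
backpropagation through time — is implemented directly on numpy arrays so
the tagger trains at desk scale on one CPU and is deterministic for a given
seed.  The single-sequence CRF primitives (:func:`crf_log_partition`,
:func:`crf_viterbi`, :func:`crf_negative_log_likelihood`) are the public
contract and are written for clarity; training uses batched, masked
versions of the same recursions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .annotation_io import AnnotatedDocument, LabelSequence, Scheme, DEFAULT_TAG_SET
from .labeling import DEFAULT_WHITESPACE_CHAR, gold_label_sequence, trad_units

__all__ = [
    "TaggerConfig",
    "CrfParameters",
    "crf_log_partition",
    "crf_viterbi",
    "crf_negative_log_likelihood",
    "crf_nll_and_grad",
    "BiRnnCrfTagger",
    "default_label_alphabet",
    "BERT_FINETUNE_DEFAULTS",
]

# Hyperparameters of the transformer fine-tuning route (max sequence length,
# train batch size, learning rate, epochs), recorded here for the optional
# export adapter; the benchmark tagger below does not use them.
BERT_FINETUNE_DEFAULTS = {
    "max_seq_length": 128,
    "train_batch_size": 32,
    "learning_rate": 2e-5,
    "epochs": 16,
}

UNK_CHAR_ID = 0  # characters unseen at training time


def default_label_alphabet(tag_set: Sequence[str] = DEFAULT_TAG_SET) -> tuple[str, ...]:
    """O first, then B-T/I-T per type, in tag-set order."""
    labels = ["O"]
    for t in tag_set:
        labels += [f"B-{t}", f"I-{t}"]
    return tuple(labels)


@dataclass(frozen=True)
class TaggerConfig:
    label_alphabet: tuple[str, ...] = field(default_factory=default_label_alphabet)
    char_embedding_dim: int = 64
    hidden_dim: int = 128
    learning_rate: float = 1e-3
    epochs: int = 30
    batch_size: int = 32
    seed: int = 0
    whitespace_char: str = DEFAULT_WHITESPACE_CHAR
    grad_clip: float = 5.0

    def __post_init__(self) -> None:
        if self.char_embedding_dim <= 0 or self.hidden_dim <= 0:
            raise ValueError("embedding and hidden dimensions must be positive")
        if "O" not in self.label_alphabet:
            raise ValueError("label alphabet must include O")


@dataclass
class CrfParameters:
    """Linear-chain CRF scores: tag-bigram transitions plus start/end."""

    transitions: np.ndarray  # (T, T): score of tag i followed by tag j
    start: np.ndarray        # (T,)
    end: np.ndarray          # (T,)

    def __post_init__(self) -> None:
        t = self.transitions.shape
        if len(t) != 2 or t[0] != t[1]:
            raise ValueError("transition matrix must be square")
        if self.start.shape != (t[0],) or self.end.shape != (t[0],):
            raise ValueError("start/end score shapes must match the alphabet")

    @classmethod
    def zeros(cls, n_tags: int) -> "CrfParameters":
        return cls(np.zeros((n_tags, n_tags)), np.zeros(n_tags), np.zeros(n_tags))


def _check_emissions(emissions: np.ndarray, params: CrfParameters) -> np.ndarray:
    emissions = np.asarray(emissions, dtype=float)
    if emissions.ndim != 2 or emissions.shape[0] < 1:
        raise ValueError("emissions must be a (L >= 1, n_tags) matrix")
    if emissions.shape[1] != params.transitions.shape[0]:
        raise ValueError("emission width does not match the tag alphabet")
    if not np.all(np.isfinite(emissions)):
        raise ValueError("non-finite emission scores")
    return emissions


def _logsumexp(a: np.ndarray, axis: int) -> np.ndarray:
    m = np.max(a, axis=axis, keepdims=True)
    return (m + np.log(np.sum(np.exp(a - m), axis=axis, keepdims=True))).squeeze(axis)


def crf_log_partition(emissions: np.ndarray, params: CrfParameters) -> float:
    """Log of the sum over all tag paths of exp(path score).

    Computed in log space by the forward recursion; finite for finite
    inputs.
    """
    emissions = _check_emissions(emissions, params)
    alpha = params.start + emissions[0]
    for t in range(1, len(emissions)):
        alpha = emissions[t] + _logsumexp(alpha[:, None] + params.transitions, axis=0)
    return float(_logsumexp(alpha + params.end, axis=0))


def crf_viterbi(emissions: np.ndarray, params: CrfParameters
                ) -> tuple[list[int], float]:
    """Highest-scoring tag path and its score.

    Ties are broken toward the lower tag index at each backpointer.
    """
    emissions = _check_emissions(emissions, params)
    L, T = emissions.shape
    delta = params.start + emissions[0]
    back = np.zeros((L, T), dtype=int)
    for t in range(1, L):
        scores = delta[:, None] + params.transitions  # (from, to)
        back[t] = np.argmax(scores, axis=0)  # first max = lowest index
        delta = emissions[t] + np.max(scores, axis=0)
    delta = delta + params.end
    best = int(np.argmax(delta))
    path = [best]
    for t in range(L - 1, 0, -1):
        best = int(back[t, best])
        path.append(best)
    path.reverse()
    return path, float(np.max(delta))


def _path_score(emissions: np.ndarray, params: CrfParameters,
                path: Sequence[int]) -> float:
    score = params.start[path[0]] + params.end[path[-1]]
    for t, y in enumerate(path):
        score += emissions[t, y]
    for t in range(len(path) - 1):
        score += params.transitions[path[t], path[t + 1]]
    return float(score)


def _check_gold(gold: Sequence[int], L: int, T: int) -> np.ndarray:
    gold = np.asarray(gold, dtype=int)
    if gold.shape != (L,):
        raise ValueError(f"gold path length {gold.shape} does not match L={L}")
    if np.any(gold < 0) or np.any(gold >= T):
        raise ValueError("gold label outside the tag alphabet")
    return gold


def crf_negative_log_likelihood(emissions: np.ndarray, params: CrfParameters,
                                gold: Sequence[int]) -> float:
    """log-partition minus the gold path score; >= 0 up to rounding."""
    emissions = _check_emissions(emissions, params)
    gold = _check_gold(gold, *emissions.shape)
    return crf_log_partition(emissions, params) - _path_score(emissions, params, gold)


def _forward_backward(emissions: np.ndarray, params: CrfParameters
                      ) -> tuple[float, np.ndarray, np.ndarray]:
    """logZ, per-position tag marginals, and summed pairwise marginals."""
    L, T = emissions.shape
    alpha = np.zeros((L, T))
    alpha[0] = params.start + emissions[0]
    for t in range(1, L):
        alpha[t] = emissions[t] + _logsumexp(
            alpha[t - 1][:, None] + params.transitions, axis=0)
    log_z = float(_logsumexp(alpha[-1] + params.end, axis=0))
    beta = np.zeros((L, T))
    beta[-1] = params.end
    for t in range(L - 2, -1, -1):
        beta[t] = _logsumexp(
            params.transitions + (emissions[t + 1] + beta[t + 1])[None, :], axis=1)
    marginals = np.exp(alpha + beta - log_z)
    pairwise = np.zeros((T, T))
    for t in range(L - 1):
        pairwise += np.exp(
            alpha[t][:, None] + params.transitions
            + (emissions[t + 1] + beta[t + 1])[None, :] - log_z)
    return log_z, marginals, pairwise


def crf_nll_and_grad(emissions: np.ndarray, params: CrfParameters,
                     gold: Sequence[int]
                     ) -> tuple[float, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """NLL and its analytic gradients.

    Returns ``(nll, d_emissions, d_transitions, d_start, d_end)``; each
    gradient is the corresponding marginal expectation minus the gold
    indicator.
    """
    emissions = _check_emissions(emissions, params)
    L, T = emissions.shape
    gold = _check_gold(gold, L, T)
    log_z, marginals, pairwise = _forward_backward(emissions, params)
    nll = log_z - _path_score(emissions, params, gold)
    d_emis = marginals.copy()
    d_emis[np.arange(L), gold] -= 1.0
    d_trans = pairwise.copy()
    for t in range(L - 1):
        d_trans[gold[t], gold[t + 1]] -= 1.0
    d_start = marginals[0].copy()
    d_start[gold[0]] -= 1.0
    d_end = marginals[-1].copy()
    d_end[gold[-1]] -= 1.0
    return nll, d_emis, d_trans, d_start, d_end


# ---------------------------------------------------------------------------
# batched CRF (training internals)
# ---------------------------------------------------------------------------

def _batched_logsumexp(a: np.ndarray, axis: int) -> np.ndarray:
    m = np.max(a, axis=axis, keepdims=True)
    return np.squeeze(m + np.log(np.sum(np.exp(a - m), axis=axis, keepdims=True)),
                      axis=axis)


def _batch_crf_grads(emis: np.ndarray, lengths: np.ndarray, gold: np.ndarray,
                     params: CrfParameters):
    """Mean NLL over a padded batch plus gradients (emission grad padded)."""
    B, L, T = emis.shape
    trans = params.transitions
    idx = np.arange(B)
    alpha = np.zeros((B, L, T))
    alpha[:, 0] = params.start + emis[:, 0]
    for t in range(1, L):
        new = emis[:, t] + _batched_logsumexp(
            alpha[:, t - 1][:, :, None] + trans[None], axis=1)
        live = (t < lengths)[:, None]
        alpha[:, t] = np.where(live, new, alpha[:, t - 1])
    last = lengths - 1
    log_z = _batched_logsumexp(alpha[idx, last] + params.end, axis=1)

    beta = np.zeros((B, L, T))
    beta[idx, last] = params.end
    for t in range(L - 2, -1, -1):
        nxt = emis[:, t + 1] + beta[:, t + 1]
        cand = _batched_logsumexp(trans[None] + nxt[:, None, :], axis=2)
        live = (t < last)[:, None]
        beta[:, t] = np.where(live, cand, beta[:, t])

    mask = np.arange(L)[None, :] < lengths[:, None]
    marg = np.exp(alpha + beta - log_z[:, None, None]) * mask[:, :, None]

    # gold path scores
    pos_scores = np.take_along_axis(emis, gold[:, :, None], axis=2)[:, :, 0]
    gold_score = (pos_scores * mask).sum(axis=1)
    gold_score += params.start[gold[:, 0]] + params.end[gold[idx, last]]
    pair_mask = np.arange(L - 1)[None, :] < last[:, None]
    trans_scores = trans[gold[:, :-1], gold[:, 1:]]
    gold_score += (trans_scores * pair_mask).sum(axis=1)
    nll = float(np.mean(log_z - gold_score))

    d_emis = marg.copy()
    np.subtract.at(d_emis.reshape(B * L, T),
                   (np.arange(B * L)[mask.ravel()],
                    gold.ravel()[mask.ravel()]), 1.0)
    d_trans = np.zeros((T, T))
    for t in range(L - 1):
        live = t < last
        if not np.any(live):
            break
        pm = np.exp(alpha[:, t][:, :, None] + trans[None]
                    + (emis[:, t + 1] + beta[:, t + 1])[:, None, :]
                    - log_z[:, None, None])
        d_trans += (pm * live[:, None, None]).sum(axis=0)
        np.subtract.at(d_trans, (gold[live, t], gold[live, t + 1]), 1.0)
    d_start = marg[:, 0].sum(axis=0)
    np.subtract.at(d_start, gold[:, 0], 1.0)
    d_end = marg[idx, last].sum(axis=0)
    np.subtract.at(d_end, gold[idx, last], 1.0)
    return nll, d_emis / B, d_trans / B, d_start / B, d_end / B


# ---------------------------------------------------------------------------
# the tagger
# ---------------------------------------------------------------------------

CHECKPOINT_VERSION = 1


class BiRnnCrfTagger:
    """Character bi-RNN encoder + linear-chain CRF, trained by Adam.

    Deterministic for a given :class:`TaggerConfig` seed.  The character
    inventory is built from the training data with one unknown-character
    slot; characters unseen at training map to it, never to an error.
    """

    def __init__(self, config: TaggerConfig | None = None,
                 tag_set: Sequence[str] = DEFAULT_TAG_SET):
        self.config = config or TaggerConfig()
        self.tag_set = tuple(tag_set)
        self.labels = tuple(self.config.label_alphabet)
        self.label_index = {lab: i for i, lab in enumerate(self.labels)}
        self.char_index: dict[str, int] = {}
        self.params: dict[str, np.ndarray] = {}
        self._adam_m: dict[str, np.ndarray] = {}
        self._adam_v: dict[str, np.ndarray] = {}
        self._adam_t = 0
        self.loss_history: list[float] = []

    # -- vocabulary / encoding ------------------------------------------

    def _encode_chars(self, text: str) -> np.ndarray:
        units = trad_units(text, self.config.whitespace_char)
        return np.array([self.char_index.get(c, UNK_CHAR_ID) for c in units],
                        dtype=int)

    def _encode_labels(self, labseq: LabelSequence) -> np.ndarray:
        return np.array([self.label_index[lab] for lab in labseq], dtype=int)

    # -- parameter init --------------------------------------------------

    def _init_params(self, n_chars: int, rng: np.random.Generator) -> None:
        d, h, T = (self.config.char_embedding_dim, self.config.hidden_dim,
                   len(self.labels))
        def mat(rows, cols, scale):
            return rng.normal(0.0, scale, size=(rows, cols))
        self.params = {
            "E": mat(n_chars, d, 0.1),
            "Wxf": mat(d, h, 1.0 / np.sqrt(d)),
            "Whf": mat(h, h, 1.0 / np.sqrt(h)),
            "bf": np.zeros(h),
            "Wxb": mat(d, h, 1.0 / np.sqrt(d)),
            "Whb": mat(h, h, 1.0 / np.sqrt(h)),
            "bb": np.zeros(h),
            "Wo": mat(2 * h, T, 1.0 / np.sqrt(2 * h)),
            "bo": np.zeros(T),
            "trans": np.zeros((T, T)),
            "start": np.zeros(T),
            "end": np.zeros(T),
        }
        self._adam_m = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_v = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_t = 0

    @property
    def crf_params(self) -> CrfParameters:
        return CrfParameters(self.params["trans"], self.params["start"],
                             self.params["end"])

    # -- encoder forward / backward --------------------------------------

    def _encoder_forward(self, X: np.ndarray, mask: np.ndarray):
        p = self.params
        B, L = X.shape
        h = self.config.hidden_dim
        emb = p["E"][X]                                 # (B, L, d)
        hf = np.zeros((B, L, h))
        hb = np.zeros((B, L, h))
        prev = np.zeros((B, h))
        for t in range(L):
            a = emb[:, t] @ p["Wxf"] + prev @ p["Whf"] + p["bf"]
            prev = np.tanh(a) * mask[:, t][:, None]
            hf[:, t] = prev
        prev = np.zeros((B, h))
        for t in range(L - 1, -1, -1):
            a = emb[:, t] @ p["Wxb"] + prev @ p["Whb"] + p["bb"]
            prev = np.tanh(a) * mask[:, t][:, None]
            hb[:, t] = prev
        concat = np.concatenate([hf, hb], axis=2)       # (B, L, 2h)
        emis = concat @ p["Wo"] + p["bo"]               # (B, L, T)
        return emis, (X, mask, emb, hf, hb, concat)

    def _encoder_backward(self, d_emis: np.ndarray, cache,
                          grads: dict[str, np.ndarray]) -> None:
        p = self.params
        X, mask, emb, hf, hb, concat = cache
        B, L = X.shape
        h = self.config.hidden_dim
        grads["Wo"] += np.einsum("blk,blt->kt", concat, d_emis)
        grads["bo"] += d_emis.sum(axis=(0, 1))
        d_concat = d_emis @ p["Wo"].T
        d_hf = d_concat[:, :, :h]
        d_hb = d_concat[:, :, h:]
        d_emb = np.zeros_like(emb)
        # forward direction: BPTT from the end
        carry = np.zeros((B, h))
        for t in range(L - 1, -1, -1):
            dh = (d_hf[:, t] + carry) * mask[:, t][:, None]
            da = dh * (1.0 - hf[:, t] ** 2)
            grads["Wxf"] += emb[:, t].T @ da
            prev = hf[:, t - 1] if t > 0 else np.zeros((B, h))
            grads["Whf"] += prev.T @ da
            grads["bf"] += da.sum(axis=0)
            d_emb[:, t] += da @ p["Wxf"].T
            carry = da @ p["Whf"].T
        # backward direction: BPTT from the start
        carry = np.zeros((B, h))
        for t in range(L):
            dh = (d_hb[:, t] + carry) * mask[:, t][:, None]
            da = dh * (1.0 - hb[:, t] ** 2)
            grads["Wxb"] += emb[:, t].T @ da
            prev = hb[:, t + 1] if t < L - 1 else np.zeros((B, h))
            grads["Whb"] += prev.T @ da
            grads["bb"] += da.sum(axis=0)
            d_emb[:, t] += da @ p["Wxb"].T
            carry = da @ p["Whb"].T
        np.add.at(grads["E"], X.ravel(),
                  d_emb.reshape(B * L, -1))

    # -- optimization -----------------------------------------------------

    def _adam_step(self, grads: dict[str, np.ndarray]) -> None:
        clip = self.config.grad_clip
        norm = np.sqrt(sum(float(np.sum(g * g)) for g in grads.values()))
        if clip and norm > clip:
            scale = clip / norm
            for g in grads.values():
                g *= scale
        self._adam_t += 1
        lr, b1, b2, eps = self.config.learning_rate, 0.9, 0.999, 1e-8
        t = self._adam_t
        for k, g in grads.items():
            m = self._adam_m[k] = b1 * self._adam_m[k] + (1 - b1) * g
            v = self._adam_v[k] = b2 * self._adam_v[k] + (1 - b2) * g * g
            mhat = m / (1 - b1 ** t)
            vhat = v / (1 - b2 ** t)
            self.params[k] -= lr * mhat / (np.sqrt(vhat) + eps)

    # -- training ---------------------------------------------------------

    def fit(self, docs: Sequence[AnnotatedDocument]) -> "BiRnnCrfTagger":
        if not docs:
            raise ValueError("empty training corpus")
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        chars = sorted({c for doc in docs
                        for c in trad_units(doc.text, cfg.whitespace_char)})
        self.char_index = {c: i + 1 for i, c in enumerate(chars)}  # 0 = unk
        self._init_params(len(chars) + 1, rng)
        seqs = [(self._encode_chars(doc.text),
                 self._encode_labels(gold_label_sequence(doc, Scheme.IOB_CHAR)))
                for doc in docs]
        n = len(seqs)
        self.loss_history = []
        for _epoch in range(cfg.epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            for lo in range(0, n, cfg.batch_size):
                batch = [seqs[i] for i in order[lo:lo + cfg.batch_size]]
                loss = self._train_batch(batch)
                epoch_loss += loss * len(batch)
            self.loss_history.append(epoch_loss / n)
        return self

    def _train_batch(self, batch: list[tuple[np.ndarray, np.ndarray]]) -> float:
        B = len(batch)
        lengths = np.array([len(x) for x, _ in batch], dtype=int)
        L = int(lengths.max())
        X = np.zeros((B, L), dtype=int)
        Y = np.zeros((B, L), dtype=int)
        for i, (x, y) in enumerate(batch):
            X[i, :len(x)] = x
            Y[i, :len(y)] = y
        mask = np.arange(L)[None, :] < lengths[:, None]
        emis, cache = self._encoder_forward(X, mask)
        nll, d_emis, d_trans, d_start, d_end = _batch_crf_grads(
            emis, lengths, Y, self.crf_params)
        grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        grads["trans"] += d_trans
        grads["start"] += d_start
        grads["end"] += d_end
        self._encoder_backward(d_emis, cache, grads)
        self._adam_step(grads)
        return nll

    # -- inference --------------------------------------------------------

    def emissions(self, text: str) -> np.ndarray:
        x = self._encode_chars(text)
        X = x[None, :]
        mask = np.ones_like(X, dtype=bool)
        emis, _ = self._encoder_forward(X, mask)
        return emis[0]

    def predict(self, doc: AnnotatedDocument | str) -> LabelSequence:
        """One char-level IOB label per character (whitespace forced to O,
        as the scheme defines)."""
        text = doc.text if isinstance(doc, AnnotatedDocument) else doc
        if not self.params:
            raise ValueError("tagger is not trained")
        path, _score = crf_viterbi(self.emissions(text), self.crf_params)
        labels = [self.labels[i] for i in path]
        labels = ["O" if text[i].isspace() else lab
                  for i, lab in enumerate(labels)]
        return LabelSequence(Scheme.IOB_CHAR, tuple(labels), self.tag_set)

    # -- serialization ----------------------------------------------------

    def save(self, path) -> None:
        header = {
            "format": "subtag-birnn-crf",
            "version": CHECKPOINT_VERSION,
            "labels": list(self.labels),
            "tag_set": list(self.tag_set),
            "chars": [c for c, _ in sorted(self.char_index.items(),
                                           key=lambda kv: kv[1])],
            "config": {
                "char_embedding_dim": self.config.char_embedding_dim,
                "hidden_dim": self.config.hidden_dim,
                "learning_rate": self.config.learning_rate,
                "epochs": self.config.epochs,
                "batch_size": self.config.batch_size,
                "seed": self.config.seed,
                "whitespace_char": self.config.whitespace_char,
            },
        }
        np.savez(path, __header__=np.frombuffer(
            json.dumps(header).encode("utf-8"), dtype=np.uint8),
            **self.params)

    @classmethod
    def load(cls, path) -> "BiRnnCrfTagger":
        with np.load(path) as data:
            header = json.loads(bytes(data["__header__"]).decode("utf-8"))
            if header.get("format") != "subtag-birnn-crf":
                raise ValueError("not a subtag checkpoint")
            if header["version"] > CHECKPOINT_VERSION:
                raise ValueError(f"checkpoint version {header['version']} "
                                 f"newer than supported {CHECKPOINT_VERSION}")
            cfg = TaggerConfig(label_alphabet=tuple(header["labels"]),
                               **header["config"])
            tagger = cls(cfg, tag_set=tuple(header["tag_set"]))
            tagger.char_index = {c: i + 1 for i, c in enumerate(header["chars"])}
            tagger.params = {k: data[k] for k in data.files if k != "__header__"}
        return tagger
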