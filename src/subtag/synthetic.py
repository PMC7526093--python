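"""Seeded generator of diagnosis-style annotated corpora.

The generator emulates the structure of a clinical question-answering
corpus in an agglutinative language without reproducing any real text:
dictionary-drawn entities of three types (disease DZ, symptom SX, body part
BP), entities optionally followed by a postposition glued without
whitespace, short documents of at most a few sentences, and a
"question-style" shifted domain in which symptom surface forms change
(mimetic / adjectival shapes) while disease and body-part forms stay fixed.

Two writing systems are supported.  The default ASCII mode builds
pseudo-syllables as consonant+vowel pairs; the hangul mode emits real
syllable blocks.  In both, postpositions are drawn from an inventory whose
first character can never occur word-internally in a generated stem
(vowel-initial romanizations in ASCII mode, a reserved onset in hangul
mode).  This guarantees that a greedy longest-match subword vocabulary
built from the corpus (:func:`build_vocab`) always places a token boundary
exactly at the entity/postposition seam, so glued postpositions surface as
continuation pieces — the phenomenon the postposition labeling rule is
about — and every gold span starts and ends on a token boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .annotation_io import AnnotatedDocument, EntitySpan, DEFAULT_TAG_SET
from .tokenization import SubwordVocab, basic_tokenize, DEFAULT_SPECIALS

__all__ = [
    "GeneratorConfig",
    "make_dictionaries",
    "make_fillers",
    "generate_corpus",
    "domain_shift",
    "corpus_stats",
    "build_vocab",
    "default_templates",
]

# consonant/vowel inventories for ASCII pseudo-syllables; no vowel ever
# starts a syllable, so vowel-initial postpositions cannot be parsed as a
# stem continuation
_CONSONANTS = "bcdghjklmnprstwz"
_VOWELS = "aeiou"
_ASCII_JOSA = ("i", "eun", "eul", "e", "eseo", "euro", "ui")

# hangul mode: stems avoid the empty onset (and the two onsets used by
# josa-internal syllables), josa are common vowel-initial particles
_HANGUL_LEADS = (0, 1, 2, 3, 4, 6, 7, 8, 10, 12, 15, 16, 17)  # no ㅇ ㅅ ㄹ
_HANGUL_VOWELS = (0, 2, 4, 8, 13, 18, 20)
_HANGUL_JOSA = ("이", "은", "을", "에", "에서", "으로", "의")


def default_templates() -> tuple[tuple[str, ...], ...]:
    """Sentence shapes with typed slots, balanced so that every entity type
    occurs in every structural position ("F" = filler word)."""
    shapes = [
        ("F", "F", "F"),
        ("F", "F", "F", "F", "F"),
        ("E0", "F", "F"),
        ("F", "F", "F", "E0"),
        ("F", "E0", "F"),
        ("F", "F", "E0", "F"),
        ("E0", "F", "F", "E1"),
        ("F", "E0", "F", "F", "E1", "F"),
        ("F", "F", "E0", "E1", "F"),
        ("E0", "E1", "F", "E2", "F", "F"),
    ]
    types = DEFAULT_TAG_SET
    templates: list[tuple[str, ...]] = []
    for shape in shapes:
        n_slots = sum(1 for s in shape if s.startswith("E"))
        combos = [[]]
        for _ in range(n_slots):
            combos = [c + [t] for c in combos for t in types]
        for combo in combos:
            templates.append(tuple(
                combo[int(s[1])] if s.startswith("E") else "F" for s in shape
            ))
    return tuple(templates)


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions of the emulated corpus.

    ``dict_sizes`` defaults to the dictionary sizes of the emulated
    annotation resource (2,191 disease names, 142 symptoms, 139 body
    parts); tests use smaller dictionaries.  ``attach_prob`` is the
    probability that an entity is followed by a glued postposition; the
    true corpus rate is unreported, 0.4 is this package's documented
    choice.  Documents hold at most ``sentences_per_doc`` sentences.
    """

    dict_sizes: dict[str, int] = field(
        default_factory=lambda: {"DZ": 2191, "SX": 142, "BP": 139})
    postposition_inventory: tuple[str, ...] = _ASCII_JOSA
    attach_prob: float = 0.4
    sentences_per_doc: int = 5
    templates: tuple[tuple[str, ...], ...] = field(default_factory=default_templates)
    domain: str = "answer"
    alphabet: str = "ascii"
    n_fillers: int = 40
    novel_filler_prob: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.attach_prob <= 1.0:
            raise ValueError("attach_prob must lie in [0, 1]")
        if not 0.0 <= self.novel_filler_prob <= 1.0:
            raise ValueError("novel_filler_prob must lie in [0, 1]")
        if any(v < 1 for v in self.dict_sizes.values()):
            raise ValueError("dictionary sizes must be >= 1")
        if self.domain not in ("answer", "question"):
            raise ValueError(f"unknown domain {self.domain!r}")
        if self.alphabet not in ("ascii", "hangul"):
            raise ValueError(f"unknown alphabet {self.alphabet!r}")
        known = set(self.dict_sizes) | {"F"}
        for tpl in self.templates:
            for slot in tpl:
                if slot not in known:
                    raise ValueError(f"template slot {slot!r} not configured")
        if self.alphabet == "hangul" and self.postposition_inventory == _ASCII_JOSA:
            object.__setattr__(self, "postposition_inventory", _HANGUL_JOSA)


def _syllable(rng: np.random.Generator, alphabet: str) -> str:
    if alphabet == "hangul":
        lead = _HANGUL_LEADS[rng.integers(len(_HANGUL_LEADS))]
        vowel = _HANGUL_VOWELS[rng.integers(len(_HANGUL_VOWELS))]
        return chr(0xAC00 + (lead * 21 + vowel) * 28)
    return (_CONSONANTS[rng.integers(len(_CONSONANTS))]
            + _VOWELS[rng.integers(len(_VOWELS))])


def _word(rng: np.random.Generator, n_syllables: int, alphabet: str) -> str:
    return "".join(_syllable(rng, alphabet) for _ in range(n_syllables))


def _capacity(n_syllables: int, alphabet: str) -> int:
    base = (len(_HANGUL_LEADS) * len(_HANGUL_VOWELS)
            if alphabet == "hangul" else len(_CONSONANTS) * len(_VOWELS))
    return base ** n_syllables


def _draw_unique(rng: np.random.Generator, n: int, used: set[str],
                 shape_fn, capacity: int, what: str) -> tuple[str, ...]:
    if n > capacity // 2:
        raise ValueError(
            f"requested {n} {what} forms exceeds combinatorial capacity {capacity}")
    out: list[str] = []
    attempts = 0
    while len(out) < n:
        form = shape_fn(rng)
        attempts += 1
        if attempts > 200 * n + 1000:
            raise ValueError(f"cannot draw {n} unique {what} forms")
        if form in used:
            continue
        used.add(form)
        out.append(form)
    return tuple(out)


def _dz_shape(alphabet: str):
    def draw(rng):
        n_words = int(rng.choice([1, 2, 3], p=[0.45, 0.4, 0.15]))
        return " ".join(_word(rng, int(rng.integers(2, 5)), alphabet)
                        for _ in range(n_words))
    return draw


def _sx_answer_shape(alphabet: str):
    # noun-like symptoms: one word, 2-3 syllables
    def draw(rng):
        return _word(rng, int(rng.integers(2, 4)), alphabet)
    return draw


def _sx_question_shape(alphabet: str):
    # mimetic (a reduplicated two-syllable base) or adjectival (a base plus
    # a fixed adjectival ending) symptom forms: morphology that never occurs
    # in the noun-like answer-domain shapes, and 4-5 syllables long, so the
    # two domains' symptom sets are disjoint by construction
    ending = "하다" if alphabet == "hangul" else "hada"
    def draw(rng):
        base = _word(rng, 2, alphabet)
        if rng.random() < 0.5:
            return base + base
        return base + _syllable(rng, alphabet) + ending
    return draw


def _bp_shape(alphabet: str):
    def draw(rng):
        return _word(rng, 2, alphabet)
    return draw


def make_dictionaries(config: GeneratorConfig) -> dict[str, tuple[str, ...]]:
    """Seeded entity dictionaries, disjoint across types.

    Disease and body-part dictionaries depend only on the seed, not on the
    domain; the symptom dictionary additionally depends on the domain, with
    question-domain surface shapes (mimetic/adjectival) replacing the
    answer-domain noun shapes entirely.
    """
    a = config.alphabet
    used: set[str] = set()
    dz = _draw_unique(np.random.default_rng([config.seed, 1]),
                      config.dict_sizes.get("DZ", 0), used, _dz_shape(a),
                      _capacity(2, a) ** 2, "DZ")
    bp = _draw_unique(np.random.default_rng([config.seed, 3]),
                      config.dict_sizes.get("BP", 0), used, _bp_shape(a),
                      _capacity(2, a), "BP")
    # fillers are drawn here (same stream order in both domains) so that the
    # symptom dictionary of either domain avoids them symmetrically
    fillers = _draw_unique(np.random.default_rng([config.seed, 4]),
                           config.n_fillers, used,
                           lambda rng: _word(rng, int(rng.integers(1, 4)), a),
                           _capacity(1, a), "filler")
    sx_shape = (_sx_question_shape(a) if config.domain == "question"
                else _sx_answer_shape(a))
    domain_tag = 2 if config.domain == "answer" else 5
    sx = _draw_unique(np.random.default_rng([config.seed, domain_tag]),
                      config.dict_sizes.get("SX", 0), used, sx_shape,
                      _capacity(2, a), "SX")
    out = {"DZ": dz, "SX": sx, "BP": bp, "_fillers": fillers}
    return {k: v for k, v in out.items() if k == "_fillers" or k in config.dict_sizes}


def make_fillers(config: GeneratorConfig) -> tuple[str, ...]:
    """The non-entity carrier words, identical across domains."""
    return make_dictionaries(config)["_fillers"]


def generate_corpus(config: GeneratorConfig, n_docs: int
                    ) -> list[AnnotatedDocument]:
    """Generate ``n_docs`` validated annotated documents, deterministically.

    Every entity surface form comes from the dictionaries; a glued
    postposition (probability ``attach_prob``) lies inside the same
    whitespace-delimited word but outside the entity span.
    """
    if n_docs < 1:
        raise ValueError("n_docs must be >= 1")
    dicts = make_dictionaries(config)
    fillers = dicts.pop("_fillers")
    etypes = [t for t in dicts if dicts[t]]
    entity_forms = {f for forms in dicts.values() for f in forms}
    by_shape: dict[tuple[str, ...], list[tuple[str, ...]]] = {}
    for tpl in config.templates:
        skel = tuple("E" if s != "F" else "F" for s in tpl)
        by_shape.setdefault(skel, []).append(tpl)
    shapes = sorted(by_shape)
    rng = np.random.default_rng([config.seed, 7])

    def draw_filler() -> str:
        # non-entity vocabulary is open: besides the carrier lexicon, fresh
        # words appear with probability novel_filler_prob, as in real text
        if rng.random() >= config.novel_filler_prob:
            return fillers[rng.integers(len(fillers))]
        while True:
            w = _word(rng, int(rng.integers(1, 6)), config.alphabet)
            if w not in entity_forms:
                return w

    docs = []
    for i in range(n_docs):
        n_sent = int(rng.integers(1, config.sentences_per_doc + 1))
        parts: list[str] = []
        spans: list[EntitySpan] = []
        pos = 0

        def add_part(word: str) -> int:
            nonlocal pos
            if parts:
                pos += 1  # the joining space
            start = pos
            parts.append(word)
            pos += len(word)
            return start

        for _s in range(n_sent):
            # shape first, then its typed variant, so that sentence shapes
            # are uniform rather than weighted by their number of typed
            # instantiations
            skel = shapes[rng.integers(len(shapes))]
            group = by_shape[skel]
            tpl = group[rng.integers(len(group))]
            for slot in tpl:
                if slot == "F":
                    # particles attach to ordinary nouns too, so a glued
                    # postposition is not by itself an entity cue
                    word = draw_filler()
                    if rng.random() < config.attach_prob:
                        word = word + config.postposition_inventory[
                            rng.integers(len(config.postposition_inventory))]
                    add_part(word)
                else:
                    etype = slot if slot in dicts else etypes[rng.integers(len(etypes))]
                    form = dicts[etype][rng.integers(len(dicts[etype]))]
                    glued = form
                    if rng.random() < config.attach_prob:
                        josa = config.postposition_inventory[
                            rng.integers(len(config.postposition_inventory))]
                        glued = form + josa
                    start = add_part(glued)
                    spans.append(EntitySpan(start, start + len(form), etype))
            add_part(".")
        text = " ".join(parts)
        docs.append(AnnotatedDocument(
            f"{config.domain}-{i:05d}", text, tuple(spans),
            tag_set=tuple(dicts.keys())))
    return docs


def domain_shift(config: GeneratorConfig, shift: bool = True) -> GeneratorConfig:
    """The question-domain counterpart of an answer-domain configuration.

    Shares the disease and body-part dictionaries exactly; regenerates the
    symptom dictionary with shifted surface shapes.  ``shift=False`` returns
    the configuration unchanged.
    """
    if not shift:
        return config
    return replace(config, domain="question")


def corpus_stats(docs: Sequence[AnnotatedDocument]) -> dict:
    """Per-type counts of annotated entities and unique surface forms."""
    total: dict[str, int] = {}
    unique: dict[str, set[str]] = {}
    for doc in docs:
        for sp in doc.spans:
            total[sp.etype] = total.get(sp.etype, 0) + 1
            unique.setdefault(sp.etype, set()).add(doc.surface(sp))
    return {
        "n_documents": len(docs),
        "per_type": {
            t: {"annotated": total[t], "unique": len(unique[t])}
            for t in sorted(total)
        },
    }


def build_vocab(docs: Sequence[AnnotatedDocument],
                specials: Sequence[str] = DEFAULT_SPECIALS) -> SubwordVocab:
    """A subword vocabulary aligned with the corpus annotations.

    Words not touching an entity boundary become whole-word tokens; a word
    containing an entity boundary (a glued postposition) is split exactly at
    the boundary into a stem token and a ``##`` continuation.  All observed
    single characters are included as a fallback, so no word in the corpus
    degrades to the unknown token.
    """
    pieces: set[str] = set()
    whole_words: set[str] = set()
    cut_words: set[str] = set()
    chars: set[str] = set()
    for doc in docs:
        boundaries_all = sorted({b for sp in doc.spans
                                 for b in (sp.char_start, sp.char_end)})
        for word, ws, we in basic_tokenize(doc.text):
            chars.update(word)
            cuts = [b - ws for b in boundaries_all if ws < b < we]
            if not cuts:
                whole_words.add(word)
                continue
            cut_words.add(word)
            edges = [0] + cuts + [len(word)]
            for k in range(len(edges) - 1):
                piece = word[edges[k]:edges[k + 1]]
                pieces.add(piece if k == 0 else "##" + piece)
    # a word string needing an internal split anywhere must never also be a
    # whole-word token, or greedy matching would overrun the split there
    tokens = pieces | (whole_words - cut_words)
    for c in sorted(chars):
        tokens.add(c)
        tokens.add("##" + c)
    ordered = list(specials) + sorted(tokens - set(specials))
    return SubwordVocab(tokens=tuple(ordered))
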