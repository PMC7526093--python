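"""Projection of character-offset entity spans onto subword tokens or
characters, conversions among labeling schemes, and span decoding.

The package distinguishes five schemes over the same annotation:

* ``BERT`` (token-level, training-facing): the first subword of an entity is
  ``B-T``; later subwords of the same word inside the entity are ``X``; a
  word-initial subword inside a multi-word entity is ``I-T``.  The
  postposition override: a continuation subword lying wholly *outside* every
  entity — typically a josa glued to an entity without whitespace — is
  labeled ``O``, never ``X``, so the entity/particle boundary is visible to
  the model even though no whitespace marks it.
* ``WP`` (token-level, evaluation-facing): each ``X`` replaced by a literal
  copy of the preceding token's label.
* ``IOB_TOKEN`` (token-level): standard IOB; in-entity continuations are
  ``I-T``.
* ``TRAD_CHAR`` (character-level): whitespace rendered as a visible
  placeholder character; in-entity whitespace labeled ``I-T``.
* ``IOB_CHAR`` (character-level): as TRAD but whitespace is always ``O``.

Decoding predicted label sequences back to character spans repairs invalid
transitions conlleval-style (``I-T`` with no open entity becomes a fresh
``B-T``) and reports the number of repairs so evaluation can account for
them.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .annotation_io import (
    AnnotatedDocument,
    EntitySpan,
    LabelSequence,
    Scheme,
    DEFAULT_TAG_SET,
)
from .tokenization import SubwordToken

__all__ = [
    "ProjectionConfig",
    "DecodedEntities",
    "project_bert_labels",
    "bert_to_wp",
    "bert_to_iob_token",
    "project_trad_labels",
    "trad_units",
    "trad_to_iob_char",
    "char_iob_from_spans",
    "token_labels_to_char_iob",
    "decode_entities",
    "gold_label_sequence",
    "count_straddles",
]

DEFAULT_WHITESPACE_CHAR = "^"


@dataclass(frozen=True)
class ProjectionConfig:
    """Conventions the schemes leave open.

    ``wp_mode`` selects how WP resolves ``X``: ``"literal"`` copies the
    precedent label verbatim (default), ``"inside"`` converts to ``I-T``.
    Straddling tokens (an entity boundary strictly inside a token) are
    assigned by their first character's membership.
    """

    tag_set: tuple[str, ...] = DEFAULT_TAG_SET
    whitespace_char: str = DEFAULT_WHITESPACE_CHAR
    wp_mode: str = "literal"

    def __post_init__(self) -> None:
        if len(self.whitespace_char) != 1:
            raise ValueError("whitespace_char must be a single character")
        if self.wp_mode not in ("literal", "inside"):
            raise ValueError(f"unknown wp_mode {self.wp_mode!r}")


@dataclass
class DecodedEntities:
    """Spans recovered from a label sequence, plus the repair count."""

    spans: list[EntitySpan]
    repairs: int = 0


def _tag_type(label: str) -> str:
    return label.split("-", 1)[1]


def _check_tokens(doc_len: int, tokens: Sequence[SubwordToken]) -> None:
    for tok in tokens:
        if tok.char_start < 0 or tok.char_end > doc_len:
            raise ValueError(
                f"token {tok.text!r} spans [{tok.char_start}, {tok.char_end}) "
                f"outside text of length {doc_len}"
            )


# ---------------------------------------------------------------------------
# projections
# ---------------------------------------------------------------------------

def project_bert_labels(doc: AnnotatedDocument,
                        tokens: Sequence[SubwordToken]) -> LabelSequence:
    """Project gold spans onto subword tokens in the BERT scheme.

    Membership is decided by each token's first character (first-char-wins
    for straddling tokens).  A continuation token outside every entity — the
    glued-postposition case — receives ``O`` rather than ``X``.
    """
    _check_tokens(len(doc.text), tokens)
    labels = []
    for tok in tokens:
        sp = doc.span_at(tok.char_start)
        if sp is None:
            labels.append("O")
        elif tok.char_start == sp.char_start:
            labels.append(f"B-{sp.etype}")
        elif tok.is_continuation:
            labels.append("X")
        else:
            labels.append(f"I-{sp.etype}")
    return LabelSequence(Scheme.BERT, tuple(labels), doc.tag_set)


def count_straddles(doc: AnnotatedDocument,
                    tokens: Sequence[SubwordToken]) -> int:
    """Tokens containing an entity boundary strictly inside their span."""
    n = 0
    for tok in tokens:
        for sp in doc.spans:
            if tok.char_start < sp.char_start < tok.char_end or \
               tok.char_start < sp.char_end < tok.char_end:
                n += 1
                break
    return n


def bert_to_wp(labels: LabelSequence,
               tokens: Sequence[SubwordToken] | None = None,
               config: ProjectionConfig | None = None) -> LabelSequence:
    """Replace each ``X`` by the nearest preceding non-X label.

    Default is a literal copy (``B-T`` stays ``B-T`` on the continuation),
    taking the replacement rule at face value; ``config.wp_mode="inside"``
    converts copies to ``I-T`` instead.  ``X`` never survives.
    """
    cfg = config or ProjectionConfig(tag_set=labels.tag_set)
    out: list[str] = []
    for i, lab in enumerate(labels):
        if lab != "X":
            out.append(lab)
            continue
        if i == 0:
            raise ValueError("X at position 0 has no precedent label")
        prev = out[-1]
        if prev == "O" or cfg.wp_mode == "literal":
            out.append(prev)
        else:
            out.append(f"I-{_tag_type(prev)}")
    return LabelSequence(Scheme.WP, tuple(out), labels.tag_set)


def bert_to_iob_token(labels: LabelSequence,
                      tokens: Sequence[SubwordToken] | None = None
                      ) -> LabelSequence:
    """Convert BERT labels to standard token-level IOB.

    Entity-internal ``X`` becomes ``I-T`` of the open entity's type; an
    ``X`` following ``O`` is outside any entity and becomes ``O``.
    """
    out: list[str] = []
    for i, lab in enumerate(labels):
        if lab != "X":
            out.append(lab)
            continue
        if i == 0:
            raise ValueError("X at position 0 has no precedent label")
        prev = out[-1]
        out.append("O" if prev == "O" else f"I-{_tag_type(prev)}")
    return LabelSequence(Scheme.IOB_TOKEN, tuple(out), labels.tag_set)


def trad_units(text: str, whitespace_char: str = DEFAULT_WHITESPACE_CHAR) -> str:
    """The character units of the TRAD scheme: whitespace made visible."""
    return "".join(whitespace_char if c.isspace() else c for c in text)


def project_trad_labels(doc: AnnotatedDocument,
                        config: ProjectionConfig | None = None) -> LabelSequence:
    """Character-level TRAD labels: one label per character of the text.

    The entity-initial character is ``B-T``; every other character inside
    the span — including internal whitespace — is ``I-T``; all else ``O``.
    Pair with :func:`trad_units` for the placeholder-substituted characters.
    """
    labels = ["O"] * len(doc.text)
    for sp in doc.spans:
        labels[sp.char_start] = f"B-{sp.etype}"
        for p in range(sp.char_start + 1, sp.char_end):
            labels[p] = f"I-{sp.etype}"
    return LabelSequence(Scheme.TRAD_CHAR, tuple(labels), doc.tag_set)


def trad_to_iob_char(labels: LabelSequence, text: str) -> LabelSequence:
    """IOB_CHAR from TRAD_CHAR: whitespace positions become ``O``."""
    if len(labels) != len(text):
        raise ValueError(
            f"label/text length mismatch: {len(labels)} vs {len(text)}"
        )
    out = tuple(
        "O" if text[i].isspace() else lab for i, lab in enumerate(labels)
    )
    return LabelSequence(Scheme.IOB_CHAR, out, labels.tag_set)


def char_iob_from_spans(text: str, spans: Sequence[EntitySpan],
                        tag_set: Sequence[str] = DEFAULT_TAG_SET
                        ) -> LabelSequence:
    """IOB_CHAR labels directly from spans (whitespace always ``O``)."""
    labels = ["O"] * len(text)
    for sp in spans:
        labels[sp.char_start] = f"B-{sp.etype}"
        for p in range(sp.char_start + 1, sp.char_end):
            labels[p] = "O" if text[p].isspace() else f"I-{sp.etype}"
    return LabelSequence(Scheme.IOB_CHAR, tuple(labels), tuple(tag_set))


def token_labels_to_char_iob(tokens: Sequence[SubwordToken],
                             labels: LabelSequence,
                             text: str) -> LabelSequence:
    """Re-express token-level labels at character level (IOB_CHAR).

    Makes token-scheme predictions comparable to character-level taggers:
    ``X`` is resolved via the WP copy rule first, the labels are decoded to
    spans, and the spans are re-projected onto characters.
    """
    _check_tokens(len(text), tokens)
    if labels.scheme is Scheme.BERT:
        labels = bert_to_wp(labels, tokens)
    decoded = decode_entities(tokens, labels)
    return char_iob_from_spans(text, decoded.spans, labels.tag_set)


# ---------------------------------------------------------------------------
# decoding
# ---------------------------------------------------------------------------

def decode_entities(units, labels: LabelSequence,
                    scheme: Scheme | None = None) -> DecodedEntities:
    """Recover typed character spans from a label sequence.

    ``units`` is the token sequence for token-level schemes and the raw text
    for character-level schemes.  Invalid starts (``I-T`` with no open
    entity of type T) are repaired to ``B-T`` per the conlleval convention;
    a dangling ``X`` (no open entity to continue) carries no type and is
    treated as ``O``.  Both repairs are counted.
    """
    scheme = scheme or labels.scheme
    if scheme != labels.scheme:
        raise ValueError(
            f"labels carry scheme {labels.scheme.value}, asked to decode as {scheme.value}"
        )
    if scheme.alignment == "token":
        return _decode_token_level(units, labels, scheme)
    if scheme is Scheme.TRAD_CHAR:
        return _decode_trad(units, labels)
    if scheme is Scheme.IOB_CHAR:
        return _decode_iob_char(units, labels)
    raise ValueError(f"unknown scheme {scheme!r}")


def _decode_token_level(tokens: Sequence[SubwordToken], labels: LabelSequence,
                        scheme: Scheme) -> DecodedEntities:
    if len(tokens) != len(labels):
        raise ValueError(
            f"token/label length mismatch: {len(tokens)} vs {len(labels)}"
        )
    spans: list[EntitySpan] = []
    repairs = 0
    cur: list | None = None  # [type, start, end]

    def close():
        nonlocal cur
        if cur is not None:
            spans.append(EntitySpan(cur[1], cur[2], cur[0]))
            cur = None

    for tok, lab in zip(tokens, labels):
        if lab == "O":
            close()
        elif lab == "X":
            if cur is not None:
                cur[2] = tok.char_end
            else:
                repairs += 1  # untyped dangling X: treated as O
        elif lab.startswith("B-"):
            t = _tag_type(lab)
            # under WP, a literal copy on a continuation piece extends the
            # open entity rather than starting a new one
            if (scheme is Scheme.WP and cur is not None and cur[0] == t
                    and tok.is_continuation):
                cur[2] = tok.char_end
            else:
                close()
                cur = [t, tok.char_start, tok.char_end]
        else:  # I-T
            t = _tag_type(lab)
            if cur is not None and cur[0] == t:
                cur[2] = tok.char_end
            else:
                close()
                repairs += 1
                cur = [t, tok.char_start, tok.char_end]
    close()
    return DecodedEntities(spans, repairs)


def _decode_trad(text: str, labels: LabelSequence) -> DecodedEntities:
    if len(text) != len(labels):
        raise ValueError(
            f"text/label length mismatch: {len(text)} vs {len(labels)}"
        )
    spans: list[EntitySpan] = []
    repairs = 0
    cur: list | None = None

    def close():
        nonlocal cur
        if cur is not None:
            spans.append(EntitySpan(cur[1], cur[2], cur[0]))
            cur = None

    for p, lab in enumerate(labels):
        if lab == "O":
            close()
        elif lab.startswith("B-"):
            close()
            cur = [_tag_type(lab), p, p + 1]
        else:
            t = _tag_type(lab)
            if cur is not None and cur[0] == t:
                cur[2] = p + 1
            else:
                close()
                repairs += 1
                cur = [t, p, p + 1]
    close()
    return DecodedEntities(spans, repairs)


def _decode_iob_char(text: str, labels: LabelSequence) -> DecodedEntities:
    if len(text) != len(labels):
        raise ValueError(
            f"text/label length mismatch: {len(text)} vs {len(labels)}"
        )
    spans: list[EntitySpan] = []
    repairs = 0
    cur: list | None = None

    def close():
        nonlocal cur
        if cur is not None:
            spans.append(EntitySpan(cur[1], cur[2], cur[0]))
            cur = None

    for p, lab in enumerate(labels):
        is_ws = text[p].isspace()
        if lab == "O":
            # whitespace is O by construction; an open entity may resume
            # after it (in-entity whitespace), so keep it open here
            if not is_ws:
                close()
        elif lab.startswith("B-"):
            close()
            cur = [_tag_type(lab), p, p + 1]
        else:
            t = _tag_type(lab)
            if cur is not None and cur[0] == t:
                cur[2] = p + 1
            else:
                close()
                repairs += 1
                cur = [t, p, p + 1]
    close()
    return DecodedEntities(spans, repairs)


# ---------------------------------------------------------------------------
# gold-label convenience
# ---------------------------------------------------------------------------

def gold_label_sequence(doc: AnnotatedDocument, scheme: Scheme,
                        tokens: Sequence[SubwordToken] | None = None,
                        config: ProjectionConfig | None = None) -> LabelSequence:
    """Gold labels for a document in any scheme.

    Token-level schemes require the document's subword tokens.
    """
    if scheme.alignment == "token":
        if tokens is None:
            raise ValueError(f"scheme {scheme.value} needs the token sequence")
        bert = project_bert_labels(doc, tokens)
        if scheme is Scheme.BERT:
            return bert
        if scheme is Scheme.WP:
            return bert_to_wp(bert, tokens, config)
        return bert_to_iob_token(bert, tokens)
    trad = project_trad_labels(doc, config)
    if scheme is Scheme.TRAD_CHAR:
        return trad
    return trad_to_iob_char(trad, doc.text)
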