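"""Annotated-document data model and standoff / CoNLL readers and writers.

Conventions used everywhere in the package:

* character offsets are 0-based, half-open ``[start, end)``;
* entity spans are flat — sorted, pairwise non-overlapping, and never start
  or end inside a whitespace run;
* label files are two-column TAB-separated with a blank line between
  sentences and an optional ``# scheme: NAME`` header comment.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Sequence

__all__ = [
    "DEFAULT_TAG_SET",
    "EntitySpan",
    "AnnotatedDocument",
    "Scheme",
    "LabelSequence",
    "ValidationError",
    "read_standoff",
    "write_standoff",
    "read_conll",
    "write_conll",
]

DEFAULT_TAG_SET = ("DZ", "SX", "BP")  # disease, symptom, body part


class ValidationError(ValueError):
    """An annotation file violated the documented invariants."""


@dataclass(frozen=True, order=True)
class EntitySpan:
    """A typed character interval over raw text, 0-based half-open."""

    char_start: int
    char_end: int
    etype: str

    def __post_init__(self) -> None:
        if self.char_start >= self.char_end:
            raise ValidationError(
                f"inverted/empty span ({self.char_start}, {self.char_end})"
            )

    def covers(self, pos: int) -> bool:
        return self.char_start <= pos < self.char_end


@dataclass(frozen=True)
class AnnotatedDocument:
    """Raw text plus flat typed entity spans (gold or decoded)."""

    doc_id: str
    text: str
    spans: tuple[EntitySpan, ...]
    tag_set: tuple[str, ...] = DEFAULT_TAG_SET

    def __post_init__(self) -> None:
        object.__setattr__(self, "spans", tuple(sorted(self.spans)))
        self.validate()

    def validate(self) -> None:
        tagset = set(self.tag_set)
        prev_end = -1
        for sp in self.spans:
            where = f"document {self.doc_id!r}, span ({sp.char_start}, {sp.char_end}, {sp.etype})"
            if sp.etype not in tagset:
                raise ValidationError(f"{where}: unknown entity type")
            if sp.char_end > len(self.text):
                raise ValidationError(f"{where}: extends past end of text")
            if sp.char_start < prev_end:
                raise ValidationError(f"{where}: overlaps the preceding span")
            if self.text[sp.char_start].isspace() or self.text[sp.char_end - 1].isspace():
                raise ValidationError(f"{where}: starts or ends inside whitespace")
            prev_end = sp.char_end

    def span_at(self, pos: int) -> EntitySpan | None:
        """The entity span covering character ``pos``, if any."""
        for sp in self.spans:
            if sp.covers(pos):
                return sp
            if sp.char_start > pos:
                break
        return None

    def surface(self, span: EntitySpan) -> str:
        return self.text[span.char_start:span.char_end]


class Scheme(str, Enum):
    """The five labeling schemes: how labels align to text units.

    BERT      token-level; non-initial in-entity subwords carry X, glued
              postposition subwords carry O (the postposition override).
    WP        token-level; each X replaced by a literal copy of the
              preceding token's label.
    IOB_TOKEN token-level standard IOB.
    TRAD_CHAR character-level; whitespace rendered as a placeholder char and
              in-entity whitespace labeled I-T.
    IOB_CHAR  character-level; whitespace always O.
    """

    BERT = "bert"
    WP = "wp"
    IOB_TOKEN = "iob-token"
    TRAD_CHAR = "trad"
    IOB_CHAR = "iob-char"

    @property
    def alignment(self) -> str:
        return "char" if self in (Scheme.TRAD_CHAR, Scheme.IOB_CHAR) else "token"

    @property
    def allows_x(self) -> bool:
        return self is Scheme.BERT


def _check_alphabet(scheme: Scheme, labels: Sequence[str],
                    tag_set: Sequence[str]) -> None:
    valid = {"O"}
    for t in tag_set:
        valid.add(f"B-{t}")
        valid.add(f"I-{t}")
    if scheme.allows_x:
        valid.add("X")
    for i, lab in enumerate(labels):
        if lab not in valid:
            raise ValidationError(
                f"label {lab!r} at position {i} outside the {scheme.value} alphabet"
            )


@dataclass(frozen=True)
class LabelSequence:
    """A scheme-tagged label sequence aligned to tokens or characters."""

    scheme: Scheme
    labels: tuple[str, ...]
    tag_set: tuple[str, ...] = DEFAULT_TAG_SET

    def __post_init__(self) -> None:
        object.__setattr__(self, "labels", tuple(self.labels))
        _check_alphabet(self.scheme, self.labels, self.tag_set)

    @property
    def alignment(self) -> str:
        return self.scheme.alignment

    def __len__(self) -> int:
        return len(self.labels)

    def __iter__(self):
        return iter(self.labels)

    def with_labels(self, labels: Iterable[str], scheme: Scheme | None = None
                    ) -> "LabelSequence":
        return LabelSequence(scheme or self.scheme, tuple(labels), self.tag_set)


# ---------------------------------------------------------------------------
# standoff JSON
# ---------------------------------------------------------------------------

def read_standoff(path, tag_set: Sequence[str] = DEFAULT_TAG_SET
                  ) -> list[AnnotatedDocument]:
    """Read documents from the standoff JSON schema.

    Schema: ``[{"doc_id": str, "text": str,
    "spans": [{"start": int, "end": int, "type": str}, ...]}, ...]``.
    Invariants are validated on read; failures name the document and span.
    """
    with open(path, encoding="utf-8") as fh:
        raw = json.load(fh)
    docs = []
    for rec in raw:
        spans = tuple(
            EntitySpan(s["start"], s["end"], s["type"]) for s in rec["spans"]
        )
        docs.append(AnnotatedDocument(rec["doc_id"], rec["text"], spans,
                                      tag_set=tuple(tag_set)))
    return docs


def write_standoff(docs: Sequence[AnnotatedDocument], path) -> None:
    payload = [
        {
            "doc_id": d.doc_id,
            "text": d.text,
            "spans": [
                {"start": s.char_start, "end": s.char_end, "type": s.etype}
                for s in d.spans
            ],
        }
        for d in docs
    ]
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, ensure_ascii=False, indent=1)
        fh.write("\n")


# ---------------------------------------------------------------------------
# CoNLL-style TSV
# ---------------------------------------------------------------------------

def read_conll(path, scheme: Scheme | None = None,
               tag_set: Sequence[str] = DEFAULT_TAG_SET
               ) -> list[tuple[list[str], LabelSequence]]:
    """Read ``(units, LabelSequence)`` pairs, one per sentence.

    The scheme is taken from a ``# scheme: NAME`` first-line comment unless
    supplied explicitly (an explicit argument wins).
    """
    sentences: list[tuple[list[str], LabelSequence]] = []
    units: list[str] = []
    labels: list[str] = []
    file_scheme = scheme
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if lineno == 1 and line.startswith("# scheme:"):
                declared = Scheme(line.split(":", 1)[1].strip())
                if file_scheme is None:
                    file_scheme = declared
                continue
            if not line.strip():
                if units:
                    sentences.append(_finish_sentence(units, labels, file_scheme, tag_set))
                    units, labels = [], []
                continue
            cols = line.split("\t")
            if len(cols) != 2:
                raise ValidationError(
                    f"{path}: line {lineno}: expected 2 TAB-separated columns, got {len(cols)}"
                )
            units.append(cols[0])
            labels.append(cols[1])
    if units:
        sentences.append(_finish_sentence(units, labels, file_scheme, tag_set))
    return sentences


def _finish_sentence(units, labels, scheme, tag_set):
    if scheme is None:
        raise ValidationError("no scheme header and none supplied")
    return (list(units), LabelSequence(scheme, tuple(labels), tuple(tag_set)))


def write_conll(sentences: Sequence[tuple[Sequence[str], LabelSequence]],
                path) -> None:
    if not sentences:
        raise ValidationError("refusing to write an empty label file")
    scheme = sentences[0][1].scheme
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# scheme: {scheme.value}\n")
        for units, labseq in sentences:
            if len(units) != len(labseq):
                raise ValidationError(
                    f"unit/label length mismatch: {len(units)} vs {len(labseq)}"
                )
            for u, lab in zip(units, labseq):
                fh.write(f"{u}\t{lab}\n")
            fh.write("\n")
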