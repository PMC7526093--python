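"""Basic and WordPiece tokenization with character offsets.

WordPiece segments each whitespace/punctuation-delimited word greedily,
longest-match-first, marking non-initial pieces with a ``##`` prefix.  Every
token keeps its character span into the source text so that entity
annotations given as character offsets can be projected onto tokens exactly
and projected back.  A word with no valid segmentation (or longer than
``max_word_chars``) degrades to a single unknown token spanning the word.

Offsets always refer to the NFC-normalized text; normalization is applied
once at ingestion (``normalize``), never silently inside the tokenizer.
"""

from __future__ import annotations

import unicodedata
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

__all__ = [
    "SubwordVocab",
    "SubwordToken",
    "normalize",
    "basic_tokenize",
    "wordpiece_tokenize",
    "tokenize_with_offsets",
    "detokenize",
]

CONTINUATION_PREFIX = "##"
DEFAULT_SPECIALS = ("[CLS]", "[SEP]", "[UNK]")


def normalize(text: str) -> str:
    """NFC-normalize text once at ingestion; offsets refer to this form."""
    return unicodedata.normalize("NFC", text)


def _is_punctuation(ch: str) -> bool:
    # ASCII symbol ranges are treated as punctuation even where Unicode
    # classifies them otherwise (`$`, `+`, `~`, ...), matching the common
    # BERT basic-tokenizer convention.
    cp = ord(ch)
    if (33 <= cp <= 47) or (58 <= cp <= 64) or (91 <= cp <= 96) or (123 <= cp <= 126):
        return True
    return unicodedata.category(ch).startswith("P")


@dataclass(frozen=True)
class SubwordVocab:
    """An ordered subword inventory with the ``##`` continuation convention.

    Parameters
    ----------
    tokens:
        Unique token strings; line order defines token ids when read from a
        ``vocab.txt`` file.
    unk_token:
        Fallback token for unsegmentable words; must be in ``tokens``.
    lowercase, strip_accents:
        Optional input folding applied before matching (both default off;
        the cased multilingual convention).
    """

    tokens: tuple[str, ...]
    unk_token: str = "[UNK]"
    specials: frozenset[str] = frozenset(DEFAULT_SPECIALS)
    lowercase: bool = False
    strip_accents: bool = False
    _index: frozenset[str] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if len(set(self.tokens)) != len(self.tokens):
            seen: set[str] = set()
            dup = next(t for t in self.tokens if t in seen or seen.add(t))
            raise ValueError(f"duplicate vocabulary token: {dup!r}")
        if self.unk_token not in self.tokens:
            raise ValueError(f"unk_token {self.unk_token!r} not in vocabulary")
        for t in self.tokens:
            if t.startswith(CONTINUATION_PREFIX) and len(t) == len(CONTINUATION_PREFIX):
                raise ValueError("continuation token must have >=1 character after '##'")
        object.__setattr__(self, "_index", frozenset(self.tokens))

    @classmethod
    def from_tokens(cls, tokens: Iterable[str], **kwargs) -> "SubwordVocab":
        toks = list(tokens)
        unk = kwargs.get("unk_token", "[UNK]")
        if unk not in toks:
            toks = [unk] + toks
        return cls(tokens=tuple(toks), **kwargs)

    def __contains__(self, token: str) -> bool:
        return token in self._index

    def __len__(self) -> int:
        return len(self.tokens)

    def fold(self, word: str) -> str:
        if self.lowercase:
            word = word.lower()
        if self.strip_accents:
            word = "".join(
                c for c in unicodedata.normalize("NFD", word)
                if unicodedata.category(c) != "Mn"
            )
        return word

    @classmethod
    def read(cls, path, **kwargs) -> "SubwordVocab":
        """Read a ``vocab.txt`` file: one token per line, line index = id."""
        with open(path, encoding="utf-8") as fh:
            toks = [line.rstrip("\n") for line in fh]
        while toks and toks[-1] == "":
            toks.pop()
        return cls(tokens=tuple(toks), **kwargs)

    def write(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for t in self.tokens:
                fh.write(t + "\n")


@dataclass(frozen=True)
class SubwordToken:
    """A subword piece tied to its character span in the source text.

    ``text`` carries the ``##`` prefix iff the piece continues the previous
    piece of the same word.  Stripping the prefix recovers the substring at
    ``[char_start, char_end)`` unless the piece is the unknown token.
    """

    text: str
    char_start: int
    char_end: int

    def __post_init__(self) -> None:
        if self.char_start >= self.char_end:
            raise ValueError(
                f"empty token span [{self.char_start}, {self.char_end})"
            )

    @property
    def is_continuation(self) -> bool:
        return self.text.startswith(CONTINUATION_PREFIX)

    @property
    def piece(self) -> str:
        """Token text without the continuation prefix."""
        if self.is_continuation:
            return self.text[len(CONTINUATION_PREFIX):]
        return self.text


def basic_tokenize(text: str) -> list[tuple[str, int, int]]:
    """Split on whitespace, then split punctuation into single-char words.

    Returns ``(word, char_start, char_end)`` triples covering every
    non-whitespace character of ``text`` in order.
    """
    out: list[tuple[str, int, int]] = []
    start = None
    for i, ch in enumerate(text):
        if ch.isspace():
            if start is not None:
                out.append((text[start:i], start, i))
                start = None
        elif _is_punctuation(ch):
            if start is not None:
                out.append((text[start:i], start, i))
                start = None
            out.append((ch, i, i + 1))
        elif start is None:
            start = i
    if start is not None:
        out.append((text[start:], start, len(text)))
    return out


def wordpiece_tokenize(
    word: str,
    vocab: SubwordVocab,
    max_word_chars: int = 100,
    offset: int = 0,
) -> list[SubwordToken]:
    """Greedy longest-match-first subword segmentation of one word.

    At each position the longest prefix present in the vocabulary (with
    ``##`` prepended after the first piece) is taken.  If no prefix matches
    at any step, or the word exceeds ``max_word_chars``, the whole word
    becomes a single unknown token.  ``offset`` shifts the emitted character
    spans into a larger source text.
    """
    if not word:
        raise ValueError("cannot tokenize an empty word")
    folded = vocab.fold(word)
    # folding that changes length would break offset alignment; degrade to unk
    if len(folded) > max_word_chars or len(folded) != len(word):
        return [SubwordToken(vocab.unk_token, offset, offset + len(word))]
    pieces: list[SubwordToken] = []
    pos = 0
    n = len(folded)
    while pos < n:
        prefix = CONTINUATION_PREFIX if pos > 0 else ""
        end = n
        match = None
        while end > pos:
            candidate = prefix + folded[pos:end]
            if candidate in vocab:
                match = candidate
                break
            end -= 1
        if match is None:
            return [SubwordToken(vocab.unk_token, offset, offset + len(word))]
        pieces.append(SubwordToken(match, offset + pos, offset + end))
        pos = end
    return pieces


def tokenize_with_offsets(text: str, vocab: SubwordVocab,
                          max_word_chars: int = 100) -> list[SubwordToken]:
    """Basic-tokenize then WordPiece each word, with global character spans.

    No special tokens ([CLS]/[SEP]) are inserted; offsets stay text-aligned.
    """
    tokens: list[SubwordToken] = []
    for word, start, _end in basic_tokenize(text):
        tokens.extend(wordpiece_tokenize(word, vocab, max_word_chars, offset=start))
    return tokens


def detokenize(tokens: Sequence[SubwordToken]) -> list[str]:
    """Rejoin subword pieces into word strings (inverse of segmentation)."""
    if tokens and tokens[0].is_continuation:
        raise ValueError("malformed input: first token is a continuation piece")
    words: list[str] = []
    for tok in tokens:
        if tok.is_continuation:
            words[-1] += tok.piece
        else:
            words.append(tok.piece)
    return words


def iter_words(tokens: Sequence[SubwordToken]) -> Iterator[list[SubwordToken]]:
    """Group a token sequence into its whitespace-word constituents."""
    group: list[SubwordToken] = []
    for tok in tokens:
        if tok.is_continuation and group:
            group.append(tok)
        else:
            if group:
                yield group
            group = [tok]
    if group:
        yield group
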