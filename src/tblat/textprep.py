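"""Text normalization: tokenization, cleansing and stop-word removal.

The default tokenizer is a self-contained regex word splitter (alphanumeric
runs); an external callable with the same signature can be plugged in where a
heavier NLP pipeline is preferred. All surfaces are lower-cased and character
offsets are 0-based, half-open into the original text.
"""

from __future__ import annotations

import re
import string
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Sequence

__all__ = [
    "Token",
    "StopWordList",
    "tokenize",
    "cleanse",
    "remove_stopwords",
    "default_stopwords",
    "content_tokens",
]

DEFAULT_MIN_LEN = 4

_WORD_RE = re.compile(r"[^\W_]+", re.UNICODE)
# Alphanumeric-only check used to drop tokens with embedded special characters.
_CLEAN_RE = re.compile(r"^[^\W_]+$", re.UNICODE)
_PUNCT = string.punctuation + "“”‘’«»–—…"


@dataclass(frozen=True)
class Token:
    """A lower-cased token with its character span in the source text."""

    surface: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.surface:
            raise ValueError("token surface must be non-empty")
        if self.end <= self.start:
            raise ValueError("token span must be non-empty (end > start)")

    def __len__(self) -> int:
        return len(self.surface)


class StopWordList:
    """A set of lower-case words with exact membership semantics."""

    def __init__(self, words: Iterable[str] = ()):
        self.words: frozenset[str] = frozenset(w.lower() for w in words if w.strip())

    def __contains__(self, word: str) -> bool:
        return word in self.words

    def __len__(self) -> int:
        return len(self.words)

    def __iter__(self) -> Iterator[str]:
        return iter(self.words)

    @classmethod
    def from_file(cls, path: str | Path) -> "StopWordList":
        text = Path(path).read_text(encoding="utf-8")
        return cls(line.strip() for line in text.splitlines())


def default_stopwords() -> StopWordList:
    """The stop-word list shipped with the package (one word per line)."""
    text = resources.files("tblat.data").joinpath("stopwords.txt").read_text("utf-8")
    return StopWordList(line.strip() for line in text.splitlines())


def tokenize(text: str) -> list[Token]:
    """Split ``text`` into lower-cased word tokens with source offsets.

    Empty input yields an empty list. Punctuation never forms part of a
    token surface.
    """
    return [
        Token(m.group(0).lower(), m.start(), m.end()) for m in _WORD_RE.finditer(text)
    ]


def cleanse(tokens: Sequence[Token], min_len: int = DEFAULT_MIN_LEN) -> list[Token]:
    """Drop noisy tokens, preserving order.

    Leading/trailing punctuation is stripped from a surface (the span is
    narrowed to match); a token whose remaining surface still contains a
    non-alphanumeric character (e.g. ``@`` or ``+``) is dropped wholly, as is
    any token shorter than ``min_len``.
    """
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    out: list[Token] = []
    for tok in tokens:
        surface = tok.surface
        start, end = tok.start, tok.end
        n_lead = len(surface) - len(surface.lstrip(_PUNCT))
        n_trail = len(surface) - len(surface.rstrip(_PUNCT))
        if n_lead + n_trail >= len(surface):
            continue  # nothing but punctuation
        if n_lead or n_trail:
            surface = surface[n_lead : len(surface) - n_trail]
            start, end = start + n_lead, end - n_trail
        if not _CLEAN_RE.match(surface):
            continue
        if len(surface) < min_len:
            continue
        out.append(Token(surface, start, end))
    return out


def remove_stopwords(tokens: Sequence[Token], stoplist: StopWordList) -> list[Token]:
    """Drop tokens whose surface is in ``stoplist``; order preserved."""
    return [tok for tok in tokens if tok.surface not in stoplist]


def content_tokens(
    text: str,
    stoplist: StopWordList | None = None,
    min_len: int = DEFAULT_MIN_LEN,
) -> list[Token]:
    """tokenize -> cleanse -> remove_stopwords, the standard pipeline."""
    toks = cleanse(tokenize(text), min_len=min_len)
    if stoplist is not None:
        toks = remove_stopwords(toks, stoplist)
    return toks
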