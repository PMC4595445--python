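"""Token normalization and stopword removal.

The whole pipeline works on unigrams only.  Each raw word is normalized by
four lightweight rules applied in a fixed order:

1. strip a trailing possessive ``'s`` (straight or curly apostrophe);
2. lowercase;
3. strip a trailing ``ing`` when the remaining stem keeps at least
   ``gerund_min_stem_length`` characters (so "working" -> "work" but "ring"
   and "king" are left alone);
4. strip one trailing ``s`` unless the word ends in ``ss`` ("works" ->
   "work", "miss" -> "miss").

Stopwords are then removed.  The default stopword list is a standard English
IR list shipped as ``data/stopwords_en.txt``; the list is configurable because
ranking metrics are mildly sensitive to it.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Iterator

from .errors import ConfigError

# A word is a run of alphanumerics, optionally carrying a possessive 's so the
# possessive rule sees it before the apostrophe would split the token.
_WORD_RE = re.compile(r"[A-Za-z0-9]+(?:['’][sS])?")

_POSSESSIVE_RE = re.compile(r"['’][sS]$")


def load_stopwords(path: str | None = None) -> frozenset[str]:
    """Load a one-term-per-line stopword file (UTF-8, '#' comments allowed).

    With ``path=None`` the bundled English list is used.
    """
    if path is None:
        text = (
            resources.files("pbcoupling.data")
            .joinpath("stopwords_en.txt")
            .read_text(encoding="utf-8")
        )
    else:
        with open(path, encoding="utf-8") as fh:
            text = fh.read()
    words = frozenset(
        line.strip().lower()
        for line in text.splitlines()
        if line.strip() and not line.lstrip().startswith("#")
    )
    if not words:
        raise ConfigError("stopword list is empty")
    return words


@dataclass(frozen=True)
class PreprocessingConfig:
    """Normalization rule toggles plus the stopword list.

    Parameters
    ----------
    stopwords
        Lowercase stopword set; must be non-empty.
    gerund_min_stem_length
        Minimum stem length left after stripping "ing" for the strip to
        apply.  Default 3 keeps short words ("ring", "sing") intact.
    """

    stopwords: frozenset[str] = field(default_factory=load_stopwords)
    gerund_min_stem_length: int = 3
    apply_possessive_strip: bool = True
    apply_plural_strip: bool = True
    apply_gerund_strip: bool = True

    def __post_init__(self) -> None:
        if not self.stopwords:
            raise ConfigError("stopword list must be non-empty")
        if self.gerund_min_stem_length < 1:
            raise ConfigError("gerund_min_stem_length must be >= 1")


DEFAULT_CONFIG = PreprocessingConfig()


def normalize_token(raw_word: str, config: PreprocessingConfig = DEFAULT_CONFIG) -> str:
    """Normalize one whitespace-free word; may return an empty string.

    Deterministic and idempotent: applying it twice gives the same token.
    """
    word = raw_word
    if config.apply_possessive_strip:
        word = _POSSESSIVE_RE.sub("", word)
    word = word.lower()
    if config.apply_gerund_strip and word.endswith("ing"):
        stem = word[:-3]
        if len(stem) >= config.gerund_min_stem_length:
            word = stem
    if config.apply_plural_strip and word.endswith("s") and not word.endswith("ss"):
        word = word[:-1]
    return word


def _is_stopword(raw: str, normalized: str, config: PreprocessingConfig) -> bool:
    # The list holds surface forms ("was", "is"); the plural rule can mangle
    # them ("wa", "i") before lookup, so both forms are checked.
    return raw.lower() in config.stopwords or normalized in config.stopwords


def iter_tokens(raw_text: str, config: PreprocessingConfig = DEFAULT_CONFIG) -> Iterator[str]:
    """Yield normalized non-stopword tokens of ``raw_text`` in input order."""
    for match in _WORD_RE.finditer(raw_text):
        raw = match.group(0)
        token = normalize_token(raw, config)
        if token and not _is_stopword(raw, token, config):
            yield token


def preprocess_text(
    raw_text: str, config: PreprocessingConfig = DEFAULT_CONFIG
) -> tuple[str, ...]:
    """Split ``raw_text`` on non-alphanumeric boundaries, normalize, and drop
    stopwords and empty results.  Output order follows input order."""
    return tuple(iter_tokens(raw_text, config))


def preprocess_words(
    words: Iterable[str], config: PreprocessingConfig = DEFAULT_CONFIG
) -> tuple[str, ...]:
    """Like :func:`preprocess_text` for pre-split word sequences."""
    out: list[str] = []
    for raw in words:
        token = normalize_token(raw, config)
        if token and not _is_stopword(raw, token, config):
            out.append(token)
    return tuple(out)
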