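"""Tweet text cleaning.

Cleaning is staged, in this order: hashtag-symbol removal (the tag word is
kept), URL removal, @-mention removal (optional, on by default), punctuation
stripping (intra-word apostrophes survive), whitespace tokenization, and
case-insensitive stop-word removal.  Case is preserved throughout; only the
stop-word match is case-folded.  Each stage's output is retained on the
returned :class:`CleanText` so any intermediate view can be audited.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources

__all__ = [
    "CleanText",
    "clean_tweet",
    "default_stopwords",
    "load_stopwords",
    "remove_hashtag_symbol",
    "remove_mentions",
    "remove_urls",
]

# A URL is a maximal non-whitespace run introduced by an http(s) scheme.
_URL_RE = re.compile(r"https?://\S*", flags=re.IGNORECASE)
_MENTION_RE = re.compile(r"@\w+")
# Anything that is not a letter, digit, apostrophe or whitespace goes; a
# second pass drops apostrophes that are not flanked by word characters.
_PUNCT_RE = re.compile(r"[^\w\s']|_", flags=re.UNICODE)
_LONE_APOSTROPHE_RE = re.compile(r"(?<![^\W_])'|'(?![^\W_])")
_WS_RE = re.compile(r"\s+")


def _collapse(text: str) -> str:
    return _WS_RE.sub(" ", text).strip()


def remove_urls(text: str) -> str:
    """Delete every ``http(s)://…`` run and tidy the surrounding whitespace."""
    return _collapse(_URL_RE.sub(" ", text))


def remove_hashtag_symbol(text: str) -> str:
    """Delete every ``#`` character, keeping the tag word verbatim."""
    return text.replace("#", "")


def remove_mentions(text: str) -> str:
    """Delete ``@user`` mentions and tidy the surrounding whitespace."""
    return _collapse(_MENTION_RE.sub(" ", text))


def _strip_punctuation(text: str) -> str:
    text = _PUNCT_RE.sub(" ", text)
    text = _LONE_APOSTROPHE_RE.sub("", text)
    return _collapse(text)


def load_stopwords(path) -> frozenset[str]:
    """Read a one-word-per-line stop-word file; ``#`` lines are comments."""
    words = set()
    with open(path, encoding="utf-8") as handle:
        for line in handle:
            word = line.strip()
            if word and not word.startswith("#"):
                words.add(word.lower())
    return frozenset(words)


_DEFAULT_STOPWORDS: frozenset[str] | None = None


def default_stopwords() -> frozenset[str]:
    """The packaged English stop-word list (lowercase)."""
    global _DEFAULT_STOPWORDS
    if _DEFAULT_STOPWORDS is None:
        ref = resources.files("vaxsent.data").joinpath("stopwords.txt")
        with resources.as_file(ref) as path:
            _DEFAULT_STOPWORDS = load_stopwords(path)
    return _DEFAULT_STOPWORDS


@dataclass(frozen=True)
class CleanText:
    """All stages of cleaning one tweet.

    ``tokens`` joined by single spaces equals ``final``; ``final`` contains
    no URL and no ``#``.
    """

    original: str
    after_hashtag_removal: str
    after_url_removal: str
    final: str
    tokens: tuple[str, ...] = field(default_factory=tuple)


def clean_tweet(
    text: str,
    stopwords: frozenset[str] | set[str] | None = None,
    *,
    drop_mentions: bool = True,
) -> CleanText:
    """Run the full cleaning pipeline on one tweet.

    Parameters
    ----------
    text
        Raw tweet text.
    stopwords
        Lowercase stop-word set; the packaged default list when ``None``.
    drop_mentions
        Remove ``@user`` handles together with URLs (default) or keep them
        as ordinary words.
    """
    if stopwords is None:
        stopwords = default_stopwords()
    after_hashtag = remove_hashtag_symbol(text)
    after_url = remove_urls(after_hashtag)
    if drop_mentions:
        after_url = remove_mentions(after_url)
    no_punct = _strip_punctuation(after_url)
    tokens = tuple(t for t in no_punct.split() if t.lower() not in stopwords)
    return CleanText(
        original=text,
        after_hashtag_removal=after_hashtag,
        after_url_removal=after_url,
        final=" ".join(tokens),
        tokens=tokens,
    )
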