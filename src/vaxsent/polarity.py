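"""Lexicon polarity scoring and sentiment bucketing.

The scorer is a pattern-style lexicon method: each tweet word found in the
sentiment lexicon contributes its polarity, negators inside a two-token
window flip and damp that contribution, an immediately preceding intensity
modifier rescales it, and the tweet score is the arithmetic mean of the
contributions (0 when no lexicon word occurs).  Scores live in [-1, +1] and
are bucketed into seven classes around a pointwise-neutral zero:

========================  =====================
|polarity|                wing class
========================  =====================
0 (exactly)               neutral
(0, weak)                 weakly_{pos,neg}
[weak, strong)            mild_{pos,neg}
[strong, 1]               strongly_{pos,neg}
========================  =====================

with default cutoffs ``weak = 0.3`` and ``strong = 0.6``.
"""

from __future__ import annotations

import csv
import re
from collections import Counter
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping, Sequence

__all__ = [
    "CLASS7_ORDER",
    "PolarityResult",
    "TermFrequencyTable",
    "analyze",
    "bucket7",
    "default_lexicon",
    "load_lexicon",
    "score_polarity",
    "term_frequencies",
    "to_ternary",
]

CLASS7_ORDER: tuple[str, ...] = (
    "strongly_negative",
    "mild_negative",
    "weakly_negative",
    "neutral",
    "weakly_positive",
    "mild_positive",
    "strongly_positive",
)

#: Negation words; any occurrence within the two tokens before a lexicon
#: word flips and damps its polarity by the factor -0.5.
NEGATIONS = frozenset(
    {
        "not", "no", "never", "none", "cannot", "neither", "nor",
        "dont", "don't", "doesnt", "doesn't", "didnt", "didn't",
        "isnt", "isn't", "wasnt", "wasn't", "arent", "aren't",
        "wont", "won't", "cant", "can't", "couldnt", "couldn't",
        "shouldnt", "shouldn't", "wouldnt", "wouldn't",
    }
)

#: Intensity modifiers applied when immediately preceding a lexicon word.
MODIFIERS: Mapping[str, float] = {
    "very": 1.3,
    "really": 1.3,
    "extremely": 1.5,
    "incredibly": 1.5,
    "so": 1.3,
    "too": 1.3,
    "highly": 1.4,
    "quite": 1.2,
    "rather": 1.1,
    "pretty": 1.1,
    "somewhat": 0.8,
    "slightly": 0.7,
    "barely": 0.6,
    "hardly": 0.6,
}

_NEGATION_FACTOR = -0.5
_NEGATION_WINDOW = 2

_TOKEN_STRIP_RE = re.compile(r"^[^\w']+|[^\w']+$")


def _tokenize(text: str) -> list[str]:
    """Lowercase whitespace tokens with edge punctuation stripped.

    Tolerant of raw tweets: a URL token degrades to an out-of-lexicon blob
    and scores nothing.
    """
    tokens = []
    for raw in text.lower().split():
        tok = _TOKEN_STRIP_RE.sub("", raw)
        if tok:
            tokens.append(tok)
    return tokens


def load_lexicon(path) -> dict[str, float]:
    """Read a ``word,polarity`` CSV lexicon; polarities must be in [-1, 1]."""
    lexicon: dict[str, float] = {}
    with open(path, newline="", encoding="utf-8") as handle:
        for row in csv.DictReader(handle):
            value = float(row["polarity"])
            if not -1.0 <= value <= 1.0:
                raise ValueError(
                    f"lexicon polarity out of [-1, 1] for {row['word']!r}: {value}"
                )
            lexicon[row["word"].strip().lower()] = value
    return lexicon


_DEFAULT_LEXICON: dict[str, float] | None = None


def default_lexicon() -> dict[str, float]:
    """The packaged English sentiment lexicon."""
    global _DEFAULT_LEXICON
    if _DEFAULT_LEXICON is None:
        ref = resources.files("vaxsent.data").joinpath("sentiment_lexicon.csv")
        with resources.as_file(ref) as path:
            _DEFAULT_LEXICON = load_lexicon(path)
    return dict(_DEFAULT_LEXICON)


def score_polarity(text: str, lexicon: Mapping[str, float] | None = None) -> float:
    """Polarity of ``text`` in [-1, +1]; 0 when no lexicon word occurs."""
    if lexicon is None:
        lexicon = default_lexicon()
    tokens = _tokenize(text)
    contributions: list[float] = []
    for i, tok in enumerate(tokens):
        if tok not in lexicon:
            continue
        value = lexicon[tok]
        if i > 0 and tokens[i - 1] in MODIFIERS:
            value *= MODIFIERS[tokens[i - 1]]
        window = tokens[max(0, i - _NEGATION_WINDOW): i]
        if any(w in NEGATIONS for w in window):
            value *= _NEGATION_FACTOR
        contributions.append(max(-1.0, min(1.0, value)))
    if not contributions:
        return 0.0
    return sum(contributions) / len(contributions)


def bucket7(polarity: float, *, weak: float = 0.3, strong: float = 0.6) -> str:
    """Map a polarity value to one of the seven sentiment classes.

    Neutral is the single point 0; the thresholds split each wing into
    weakly / mild / strongly.
    """
    if not -1.0 <= polarity <= 1.0:
        raise ValueError(f"polarity must lie in [-1, 1], got {polarity}")
    if not 0.0 < weak < strong <= 1.0:
        raise ValueError(f"need 0 < weak < strong <= 1, got {weak}, {strong}")
    if polarity == 0:
        return "neutral"
    magnitude = abs(polarity)
    if magnitude < weak:
        grade = "weakly"
    elif magnitude < strong:
        grade = "mild"
    else:
        grade = "strongly"
    wing = "positive" if polarity > 0 else "negative"
    return f"{grade}_{wing}"


def to_ternary(class7: str) -> str:
    """Collapse a seven-class label to positive / negative / neutral."""
    if class7 == "neutral":
        return "neutral"
    if class7 not in CLASS7_ORDER:
        raise ValueError(f"unknown class7 label {class7!r}")
    return class7.rsplit("_", 1)[1]


@dataclass(frozen=True)
class PolarityResult:
    """Polarity score plus its seven-class and ternary buckets."""

    polarity: float
    class7: str
    class3: str


def analyze(
    text: str,
    lexicon: Mapping[str, float] | None = None,
    *,
    weak: float = 0.3,
    strong: float = 0.6,
) -> PolarityResult:
    """Score one text and bucket the result."""
    polarity = score_polarity(text, lexicon)
    class7 = bucket7(polarity, weak=weak, strong=strong)
    return PolarityResult(polarity=polarity, class7=class7, class3=to_ternary(class7))


@dataclass(frozen=True)
class TermFrequencyTable:
    """Term counts over one ternary class — the data behind a word cloud."""

    class3: str
    counts: Mapping[str, int]
    total_tokens: int

    def top(self) -> list[tuple[str, int]]:
        return sorted(self.counts.items(), key=lambda kv: (-kv[1], kv[0]))


def term_frequencies(
    corpus: Iterable[tuple[Sequence[str], str]],
    target: str,
    top_k: int,
) -> TermFrequencyTable:
    """Top-``top_k`` case-folded term counts over tweets labeled ``target``.

    Ties are broken alphabetically.  An empty corpus (or a class with no
    tweets) yields an empty table.
    """
    if top_k < 1:
        raise ValueError(f"top_k must be >= 1, got {top_k}")
    counter: Counter[str] = Counter()
    total = 0
    for tokens, label in corpus:
        if label != target:
            continue
        folded = [t.lower() for t in tokens]
        counter.update(folded)
        total += len(folded)
    ranked = sorted(counter.items(), key=lambda kv: (-kv[1], kv[0]))[:top_k]
    return TermFrequencyTable(
        class3=target, counts=dict(ranked), total_tokens=total
    )
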