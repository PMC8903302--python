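"""Log-odds lexicon sentiment scoring and the binary polarity treatment.

A signed seed lexicon (AFINN dialect, integer scores in -5..5) labels tweets
positive/negative/neutral by summed score. Tokens of positive- and
negative-seeded tweets form two reference corpora; each term w is then
scored by the smoothed log2 odds ratio

    Score(w) = log2[ (freq(w,pos)+a) * (freq(neg)+a)
                     / ((freq(w,neg)+a) * (freq(pos)+a)) ]

where freq(pos) / freq(neg) are the total token counts of the two corpora
and a >= 0 is a pseudocount (default 0.5; a = 0 reproduces the unsmoothed
odds ratio exactly when all counts are positive). An account-week's
sentiment score SS sums Score(w) over its token stream with multiplicity;
its polarity SP is 1 if SS > 0, 0 if SS < 0, and "excluded" if SS = 0.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .corpus import EXCLUDED
from .exceptions import DataError, EstimationError

POSITIVE = "positive"
NEGATIVE = "negative"
NEUTRAL = "neutral"


@dataclass(frozen=True)
class Lexicon:
    """Signed term lexicon: lowercase term -> nonzero integer score."""

    scores: Mapping[str, int]

    def __post_init__(self) -> None:
        for term, score in self.scores.items():
            if term != term.lower():
                raise DataError(f"lexicon term {term!r} is not lowercase")
            if not isinstance(score, int) or score == 0:
                raise DataError(f"lexicon score for {term!r} must be a nonzero integer")

    def __len__(self) -> int:
        return len(self.scores)

    def __contains__(self, term: str) -> bool:
        return term in self.scores

    def get(self, term: str, default: int = 0) -> int:
        return self.scores.get(term, default)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "Lexicon":
        """Read a two-column TSV (term<TAB>score); '#' comment lines allowed."""
        scores: dict[str, int] = {}
        for line in Path(path).read_text(encoding="utf-8").splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            term, _, raw = line.partition("\t")
            term = term.strip().lower()
            if term in scores:
                raise DataError(f"duplicate lexicon term {term!r}")
            scores[term] = int(raw.strip())
        return cls(scores)

    def to_tsv(self, path: str | Path) -> None:
        with Path(path).open("w", encoding="utf-8") as fh:
            for term in sorted(self.scores):
                fh.write(f"{term}\t{self.scores[term]}\n")


def lexicon_score(tokens: Sequence[str], lexicon: Lexicon) -> int:
    """Summed lexicon score of a token list (fallback scoring mode)."""
    return sum(lexicon.get(tok) for tok in tokens)


def seed_polarity(tokens: Sequence[str], lexicon: Lexicon) -> str:
    """Seed label of a document: sign of its summed lexicon score."""
    if not len(lexicon):
        raise DataError("lexicon is empty")
    total = lexicon_score(tokens, lexicon)
    if total > 0:
        return POSITIVE
    if total < 0:
        return NEGATIVE
    return NEUTRAL


@dataclass
class TermStats:
    """Per-term counts in the positive and negative reference corpora."""

    pos_counts: Counter = field(default_factory=Counter)
    neg_counts: Counter = field(default_factory=Counter)
    pos_total: int = 0
    neg_total: int = 0
    alpha: float = 0.5

    def validate(self) -> None:
        if self.alpha < 0:
            raise DataError("pseudocount alpha must be >= 0")
        if sum(self.pos_counts.values()) != self.pos_total:
            raise DataError("positive corpus total does not match per-term counts")
        if sum(self.neg_counts.values()) != self.neg_total:
            raise DataError("negative corpus total does not match per-term counts")

    def swapped(self) -> "TermStats":
        """Positive and negative corpora exchanged (for symmetry checks)."""
        return TermStats(
            pos_counts=Counter(self.neg_counts),
            neg_counts=Counter(self.pos_counts),
            pos_total=self.neg_total,
            neg_total=self.pos_total,
            alpha=self.alpha,
        )


def build_term_stats(
    labeled_docs: Iterable[tuple[str, Sequence[str]]],
    alpha: float = 0.5,
) -> TermStats:
    """Accumulate reference-corpus counts from (seed label, tokens) pairs.

    Neutral documents contribute to neither corpus. Raises if either
    reference corpus ends up empty, since the log-odds contrast then has no
    denominator; callers may fall back to pure-lexicon scoring.
    """
    stats = TermStats(alpha=alpha)
    for label, tokens in labeled_docs:
        if label == POSITIVE:
            stats.pos_counts.update(tokens)
        elif label == NEGATIVE:
            stats.neg_counts.update(tokens)
        elif label != NEUTRAL:
            raise DataError(f"unknown seed label {label!r}")
    stats.pos_total = sum(stats.pos_counts.values())
    stats.neg_total = sum(stats.neg_counts.values())
    if stats.pos_total == 0 or stats.neg_total == 0:
        raise EstimationError(
            "a reference corpus is empty; supply more seed-labeled data or use "
            "the lexicon-only scoring mode"
        )
    return stats


def term_log_odds(term: str, stats: TermStats, alpha: float | None = None) -> float:
    """Smoothed log2 odds-ratio score of one term."""
    a = stats.alpha if alpha is None else alpha
    f_wp = stats.pos_counts.get(term, 0)
    f_wn = stats.neg_counts.get(term, 0)
    if a == 0 and (f_wn == 0 or stats.pos_total == 0):
        raise DataError(
            f"log-odds score undefined for term {term!r} with alpha=0 "
            "(zero count in a denominator)"
        )
    return math.log2(
        ((f_wp + a) * (stats.neg_total + a)) / ((f_wn + a) * (stats.pos_total + a))
    )


def weekly_sentiment(
    tokens: Sequence[str], stats: TermStats
) -> tuple[float, int | str]:
    """Sentiment score and polarity of one account-week's token stream.

    SS sums term scores with multiplicity; SP is 1 (positive) if SS > 0,
    0 (negative) if SS < 0, and the "excluded" marker when SS = 0 (such
    weeks never reach the causal stage).
    """
    counts = Counter(tokens)
    ss = sum(n * term_log_odds(term, stats) for term, n in counts.items())
    if ss > 0:
        return ss, 1
    if ss < 0:
        return ss, 0
    return 0.0, EXCLUDED


def term_score_table(stats: TermStats) -> pd.DataFrame:
    """Audit table of every term: corpus counts and log-odds score."""
    terms = sorted(set(stats.pos_counts) | set(stats.neg_counts))
    return pd.DataFrame({
        "term": terms,
        "freq_pos": [stats.pos_counts.get(t, 0) for t in terms],
        "freq_neg": [stats.neg_counts.get(t, 0) for t in terms],
        "score": [term_log_odds(t, stats) for t in terms],
    })


def write_term_scores(stats: TermStats, path: str | Path) -> None:
    term_score_table(stats).to_csv(path, index=False)
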