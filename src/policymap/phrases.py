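"""Frequent multi-word expressions (2-4 lemmas) and their yearly trends.

Phrases are contiguous n-grams over the preprocessed lemma stream (so stop
words never interrupt a phrase) and are counted by document frequency: a
phrase repeated within one summary still counts once. An n-gram wholly
contained in a longer retained n-gram with the same document frequency is
suppressed, so "physical education program" does not also surface as
"physical education" when the two always co-occur.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from sklearn.base import BaseEstimator

from .classify import round_half_away
from .corpus_io import Corpus
from .preprocess import TextPreprocessor


@dataclass
class PhraseRecord:
    """One frequent expression with its corpus statistics."""

    phrase: tuple[str, ...]
    doc_freq: int
    share_pct: float
    per_year: dict[int, int] = field(default_factory=dict)

    @property
    def text(self) -> str:
        return " ".join(self.phrase)


def phrase_share(doc_freq: int, N: int) -> float:
    """Document frequency as a corpus percentage, two decimals."""
    if N < 1:
        raise ValueError("corpus size must be >= 1")
    if not 0 <= doc_freq <= N:
        raise ValueError(f"doc_freq {doc_freq} outside [0, {N}]")
    return round_half_away(100.0 * doc_freq / N, 2)


def _ngrams(lemmas: Sequence[str], nmin: int, nmax: int) -> set[tuple[str, ...]]:
    grams: set[tuple[str, ...]] = set()
    for n in range(nmin, nmax + 1):
        for i in range(len(lemmas) - n + 1):
            grams.add(tuple(lemmas[i:i + n]))
    return grams


def _is_subphrase(short: tuple[str, ...], long: tuple[str, ...]) -> bool:
    if len(short) >= len(long):
        return False
    return any(long[i:i + len(short)] == short
               for i in range(len(long) - len(short) + 1))


def extract_phrases(
    corpus: Corpus,
    nmin: int = 2,
    nmax: int = 4,
    min_df: int = 2,
    preprocessor: Optional[TextPreprocessor] = None,
) -> list[PhraseRecord]:
    """All 2-4-lemma expressions with document frequency >= ``min_df``.

    Sorted by document frequency descending, then alphabetically. Each
    record carries its corpus share (two decimals) and, where documents are
    dated, per-year document frequencies.
    """
    if corpus.corpus_size == 0:
        raise ValueError("cannot extract phrases from an empty corpus")
    if nmin < 2 or nmax < nmin:
        raise ValueError(f"invalid n-gram range [{nmin}, {nmax}]")
    prep = preprocessor or TextPreprocessor()
    doc_freq: dict[tuple[str, ...], int] = {}
    per_year: dict[tuple[str, ...], dict[int, int]] = {}
    for doc in corpus:
        grams = _ngrams(prep.stream(doc).lemmas, nmin, nmax)
        for g in grams:
            doc_freq[g] = doc_freq.get(g, 0) + 1
            if doc.year is not None:
                yearly = per_year.setdefault(g, {})
                yearly[doc.year] = yearly.get(doc.year, 0) + 1

    retained = {g: n for g, n in doc_freq.items() if n >= min_df}
    # maximal-phrase filter: drop g when a longer retained phrase with the
    # same document frequency contains it
    by_len = sorted(retained, key=len, reverse=True)
    suppressed: set[tuple[str, ...]] = set()
    for g in retained:
        for longer in by_len:
            if len(longer) <= len(g):
                break
            if retained[longer] == retained[g] and _is_subphrase(g, longer):
                suppressed.add(g)
                break
    records = [
        PhraseRecord(
            phrase=g, doc_freq=n,
            share_pct=phrase_share(n, corpus.corpus_size),
            per_year=dict(sorted(per_year.get(g, {}).items())),
        )
        for g, n in retained.items() if g not in suppressed
    ]
    records.sort(key=lambda r: (-r.doc_freq, r.phrase))
    return records


def phrase_trend(
    phrase: Sequence[str],
    corpus: Corpus,
    preprocessor: Optional[TextPreprocessor] = None,
) -> dict:
    """Yearly document frequencies of one phrase over the corpus year span.

    Gap years inside the observed span are zero-filled. Returns
    ``{"per_year": {...}, "mean": float, "min": int, "max": int}`` with the
    mean over span years rounded to two decimals.
    """
    phrase = tuple(phrase)
    years = [d.year for d in corpus if d.year is not None]
    if not years:
        raise ValueError("no dated documents in the corpus")
    prep = preprocessor or TextPreprocessor()
    counts: dict[int, int] = {y: 0 for y in range(min(years), max(years) + 1)}
    for doc in corpus:
        if doc.year is None:
            continue
        lemmas = prep.stream(doc).lemmas
        if phrase in _ngrams(lemmas, len(phrase), len(phrase)):
            counts[doc.year] += 1
    values = list(counts.values())
    return {
        "per_year": counts,
        "mean": round_half_away(sum(values) / len(values), 2),
        "min": min(values),
        "max": max(values),
    }


class FrequentPhraseMiner(BaseEstimator):
    """Estimator wrapper around :func:`extract_phrases`.

    ``fit`` mines a corpus and stores the records as ``phrases_``;
    ``transform`` is not defined because the result is a ranked table, not a
    per-document feature matrix.
    """

    def __init__(self, nmin: int = 2, nmax: int = 4, min_df: int = 2,
                 stopwords=None, lemma_exceptions=None,
                 drop_numerals: bool = False):
        self.nmin = nmin
        self.nmax = nmax
        self.min_df = min_df
        self.stopwords = stopwords
        self.lemma_exceptions = lemma_exceptions
        self.drop_numerals = drop_numerals

    def fit(self, X: Corpus, y=None):
        prep = TextPreprocessor(stopwords=self.stopwords,
                                lemma_exceptions=self.lemma_exceptions,
                                drop_numerals=self.drop_numerals)
        self.phrases_ = extract_phrases(X, nmin=self.nmin, nmax=self.nmax,
                                        min_df=self.min_df, preprocessor=prep)
        self.n_documents_ = X.corpus_size
        return self
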