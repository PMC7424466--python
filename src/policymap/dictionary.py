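"""Per-area term dictionaries ("d-words") from a labelled reference corpus.

For each scientific area, every lemma in the area sub-corpus is scored by
TF-IDF (normalized within-document frequency times the log of sub-corpus
size over document frequency), aggregated over the documents containing it,
ranked, and cut at the first percentile of the candidate list. Terms that
survive the cut in two or more areas are ambiguous; each owning area attaches
the two lemmas with highest Jaccard co-occurrence (over document sets) as
context terms, which the classifier later uses for disambiguation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from .corpus_io import AREAS, Corpus
from .preprocess import TextPreprocessor, TokenStream

_LOG = {"e": math.log, 2: math.log2, 10: math.log10,
        "2": math.log2, "10": math.log10}


@dataclass
class DWord:
    """A dictionary term with its aggregated TF-IDF score and context."""

    term: str
    score: float
    rank: int
    context_terms: list[tuple[str, float]] = field(default_factory=list)
    #: True when the term was selected as a d-word in >= 2 areas; such
    #: occurrences only count toward an area when a context term co-occurs.
    ambiguous: bool = False


@dataclass
class AreaDictionary:
    """The ranked d-word list of one scientific area."""

    area: str
    dwords: list[DWord]
    candidate_count: int

    def terms(self) -> list[str]:
        return [d.term for d in self.dwords]


@dataclass
class Taxonomy:
    """All area dictionaries plus the parameters they were built with."""

    dictionaries: dict[str, AreaDictionary]
    build_config: dict

    @property
    def areas(self) -> list[str]:
        return sorted(self.dictionaries)

    def ambiguous_terms(self) -> set[str]:
        """Terms selected as d-words in two or more areas."""
        owners: dict[str, int] = {}
        for d in self.dictionaries.values():
            for t in d.terms():
                owners[t] = owners.get(t, 0) + 1
        return {t for t, n in owners.items() if n >= 2}


@dataclass
class CorpusStats:
    """Document-frequency statistics of a (sub-)corpus."""

    N: int
    doc_freq: dict[str, int]
    doc_sets: dict[str, frozenset[str]]

    @classmethod
    def from_streams(cls, streams: Sequence[TokenStream]) -> "CorpusStats":
        doc_sets: dict[str, set[str]] = {}
        for s in streams:
            for lemma in set(s.lemmas):
                doc_sets.setdefault(lemma, set()).add(s.doc_id)
        frozen = {t: frozenset(ids) for t, ids in doc_sets.items()}
        return cls(N=len(streams),
                   doc_freq={t: len(ids) for t, ids in frozen.items()},
                   doc_sets=frozen)


def term_frequency(term: str, stream: TokenStream) -> float:
    """Occurrences of ``term`` divided by the lemma count of the document."""
    if len(stream) == 0:
        raise ValueError(f"term frequency undefined on empty stream {stream.doc_id!r}")
    return stream.lemmas.count(term) / len(stream)


def inverse_document_frequency(term: str, stats: CorpusStats,
                               base: float | str = "e") -> float:
    """log(N / document frequency of ``term``) in the configured base."""
    df = stats.doc_freq.get(term, 0)
    if df < 1:
        raise ValueError(f"term {term!r} does not occur in the corpus")
    return _LOG.get(base, math.log)(stats.N / df)


def tfidf(term: str, stream: TokenStream, stats: CorpusStats,
          base: float | str = "e") -> float:
    """Normalized term frequency times inverse document frequency."""
    return term_frequency(term, stream) * inverse_document_frequency(term, stats, base)


def rank_terms(
    area_docs: Sequence[TokenStream],
    stats: Optional[CorpusStats] = None,
    *,
    idf_base: float | str = "e",
    aggregation: str = "mean",
    min_term_length: int = 3,
) -> list[tuple[str, float]]:
    """Score and rank every candidate lemma of an area sub-corpus.

    A lemma's score aggregates its TF-IDF over the documents that contain it
    (``mean`` by default; ``max`` and ``sum`` available). Candidates shorter
    than ``min_term_length`` or purely numeric are excluded. Sorted by score
    descending, ties alphabetical.
    """
    if not area_docs or all(len(s) == 0 for s in area_docs):
        raise ValueError("cannot rank terms of an empty sub-corpus")
    if aggregation not in ("mean", "max", "sum"):
        raise ValueError(f"unknown aggregation {aggregation!r}")
    stats = stats or CorpusStats.from_streams(area_docs)
    scores: dict[str, list[float]] = {}
    for stream in area_docs:
        if len(stream) == 0:
            continue
        counts: dict[str, int] = {}
        for lemma in stream.lemmas:
            counts[lemma] = counts.get(lemma, 0) + 1
        for lemma, c in counts.items():
            if len(lemma) < min_term_length or lemma.isdigit():
                continue
            tf = c / len(stream)
            scores.setdefault(lemma, []).append(
                tf * inverse_document_frequency(lemma, stats, idf_base)
            )
    agg = {"mean": lambda v: sum(v) / len(v), "max": max, "sum": sum}[aggregation]
    ranked = [(t, agg(v)) for t, v in scores.items()]
    ranked.sort(key=lambda tv: (-tv[1], tv[0]))
    return ranked


def select_dwords(ranked: Sequence[tuple[str, float]],
                  fraction: float = 0.01) -> list[DWord]:
    """Keep the first ``ceil(fraction * len(ranked))`` candidates as d-words."""
    if not ranked:
        raise ValueError("no ranked candidates to select from")
    if not 0.0 < fraction <= 1.0:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    k = math.ceil(fraction * len(ranked))
    return [DWord(term=t, score=s, rank=i + 1)
            for i, (t, s) in enumerate(ranked[:k])]


def jaccard_terms(a: str, b: str, stats: CorpusStats) -> float:
    """Jaccard coefficient of the two terms' document-occurrence sets."""
    for t in (a, b):
        if t not in stats.doc_sets:
            raise ValueError(f"term {t!r} does not occur in the corpus")
    sa, sb = stats.doc_sets[a], stats.doc_sets[b]
    union = sa | sb
    return len(sa & sb) / len(union) if union else 0.0


def context_terms(term: str, stats: CorpusStats, k: int = 2) -> list[tuple[str, float]]:
    """The ``k`` lemmas with highest Jaccard co-occurrence against ``term``.

    Only lemmas sharing at least one document with ``term`` are candidates;
    fewer than ``k`` pairs are returned when the vocabulary is small. Ties
    break alphabetically.
    """
    if term not in stats.doc_sets:
        raise ValueError(f"term {term!r} does not occur in the corpus")
    own = stats.doc_sets[term]
    cands = []
    for other, docs in stats.doc_sets.items():
        if other == term or not (own & docs):
            continue
        cands.append((other, len(own & docs) / len(own | docs)))
    cands.sort(key=lambda tc: (-tc[1], tc[0]))
    return cands[:k]


def build_taxonomy(
    scientific_corpus: Corpus,
    *,
    fraction: float = 0.01,
    idf_base: float | str = "e",
    aggregation: str = "mean",
    min_term_length: int = 3,
    per_area_idf: bool = True,
    context_k: int = 2,
    areas: Sequence[str] = AREAS,
    stopwords=None,
    lemma_exceptions: Optional[Mapping[str, str]] = None,
    drop_numerals: bool = False,
) -> Taxonomy:
    """Build the full taxonomy from a labelled scientific corpus.

    Per area: preprocess the sub-corpus, compute document-frequency stats,
    rank lemmas by aggregated TF-IDF, cut at ``fraction``; afterwards attach
    context terms (within each owning area) to every term selected in two or
    more areas. Deterministic: the same corpus and configuration serialize to
    a byte-identical dictionary TSV.

    ``per_area_idf=True`` computes IDF within the area sub-corpus (N = area
    size); ``False`` uses pooled corpus statistics.
    """
    prep = TextPreprocessor(stopwords=stopwords, lemma_exceptions=lemma_exceptions,
                            drop_numerals=drop_numerals)
    by_area: dict[str, list[TokenStream]] = {a: [] for a in areas}
    for doc in scientific_corpus:
        if doc.area_label not in by_area:
            raise ValueError(
                f"document {doc.doc_id!r} has area {doc.area_label!r}, "
                f"expected one of {tuple(areas)}"
            )
        by_area[doc.area_label].append(prep.stream(doc))
    for area, streams in by_area.items():
        if not streams:
            raise ValueError(f"area {area!r} has no documents")

    pooled = None
    if not per_area_idf:
        pooled = CorpusStats.from_streams(
            [s for streams in by_area.values() for s in streams]
        )

    area_stats: dict[str, CorpusStats] = {}
    dictionaries: dict[str, AreaDictionary] = {}
    for area, streams in by_area.items():
        stats = CorpusStats.from_streams(streams)
        area_stats[area] = stats
        ranked = rank_terms(
            streams, pooled if pooled is not None else stats,
            idf_base=idf_base, aggregation=aggregation,
            min_term_length=min_term_length,
        )
        dictionaries[area] = AreaDictionary(
            area=area, dwords=select_dwords(ranked, fraction),
            candidate_count=len(ranked),
        )

    taxonomy = Taxonomy(
        dictionaries=dictionaries,
        build_config={
            "fraction": fraction, "idf_base": str(idf_base),
            "aggregation": aggregation, "min_term_length": min_term_length,
            "per_area_idf": per_area_idf, "context_k": context_k,
            "tie_rule": "alphabetical", "areas": list(areas),
        },
    )
    for term in taxonomy.ambiguous_terms():
        for area, adict in dictionaries.items():
            for dw in adict.dwords:
                if dw.term == term:
                    dw.ambiguous = True
                    dw.context_terms = context_terms(term, area_stats[area],
                                                     k=context_k)
    return taxonomy
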