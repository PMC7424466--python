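"""Dictionary-based classification of policy documents into scientific areas.

A document's lemma stream is matched against every area dictionary: an
unambiguous d-word contributes its full occurrence count; a d-word owned by
several areas counts toward an area only when at least one of its two context
terms for that area co-occurs anywhere in the document. The area with the
most occurrences wins (ties: more distinct d-words matched, then
alphabetical); documents matching nothing are "unclassified".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .corpus_io import AREAS, UNCLASSIFIED, Corpus
from .dictionary import AreaDictionary, Taxonomy, build_taxonomy
from .preprocess import TextPreprocessor, TokenStream


def round_half_away(x: float, ndigits: int) -> float:
    """Round half away from zero (the convention used for reported shares)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class ClassificationProfile:
    """Per-area match counts and the assigned area of one document."""

    doc_id: str
    hits: dict[str, int]
    distinct_hits: dict[str, int]
    assigned_area: str = field(default=UNCLASSIFIED)


def match_dwords(stream: TokenStream, adict: AreaDictionary) -> dict[str, int]:
    """Occurrence counts of an area's d-words within one document.

    Ambiguous d-words (those carrying context terms) only count when one of
    their context terms occurs anywhere in the stream; with no context term
    recorded the occurrences cannot be attributed and count as zero.
    """
    present = set(stream.lemmas)
    counts: dict[str, int] = {}
    for dw in adict.dwords:
        if dw.term not in present:
            continue
        if dw.ambiguous:
            if not any(ctx in present for ctx, _ in dw.context_terms):
                continue
        counts[dw.term] = stream.lemmas.count(dw.term)
    return counts


def area_profile(stream: TokenStream, taxonomy: Taxonomy) -> ClassificationProfile:
    """Score one document against every area dictionary and assign an area."""
    hits: dict[str, int] = {}
    distinct: dict[str, int] = {}
    for area in taxonomy.areas:
        counts = match_dwords(stream, taxonomy.dictionaries[area])
        hits[area] = sum(counts.values())
        distinct[area] = len(counts)
    if all(v == 0 for v in hits.values()):
        assigned = UNCLASSIFIED
    else:
        assigned = min(hits, key=lambda a: (-hits[a], -distinct[a], a))
    return ClassificationProfile(doc_id=stream.doc_id, hits=hits,
                                 distinct_hits=distinct, assigned_area=assigned)


def area_shares(
    profiles: Sequence[ClassificationProfile],
    by: str = "documents",
) -> dict[str, float]:
    """Percentage of the corpus assigned to each area, one decimal.

    ``by="documents"`` (primary) counts assigned documents; ``by="hits"``
    shares total d-word occurrences instead. Zero-hit documents are reported
    under "unclassified".
    """
    if not profiles:
        raise ValueError("no profiles to summarize")
    if by == "documents":
        counts: dict[str, float] = {}
        for p in profiles:
            counts[p.assigned_area] = counts.get(p.assigned_area, 0) + 1
        total = len(profiles)
    elif by == "hits":
        counts = {}
        for p in profiles:
            for area, n in p.hits.items():
                counts[area] = counts.get(area, 0) + n
        total = sum(counts.values())
        if total == 0:
            raise ValueError("no d-word occurrences in any profile")
    else:
        raise ValueError(f"unknown share basis {by!r}")
    return {area: round_half_away(100.0 * n / total, 1)
            for area, n in sorted(counts.items())}


@dataclass
class CrossTab:
    """Document counts over two metadata/category axes."""

    row_key: str
    col_key: str
    rows: list[str]
    cols: list[str]
    counts: np.ndarray

    @property
    def row_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def grand_total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.counts, index=self.rows, columns=self.cols)
        frame.index.name = self.row_key
        frame.columns.name = self.col_key
        return frame


def _field_values(doc, profile: Optional[ClassificationProfile], key: str) -> list[str]:
    if key == "state":
        return [doc.state] if doc.state else []
    if key == "year":
        return [str(doc.year)] if doc.year is not None else []
    if key in ("setting", "settings"):
        return list(doc.settings)
    if key in ("area", "assigned_area"):
        return [profile.assigned_area] if profile is not None else []
    if key == "count":  # marginal axis: every document contributes once
        return ["count"]
    raise ValueError(f"unknown cross-tab field {key!r}")


def crosstab(
    corpus: Corpus,
    profiles: Optional[Sequence[ClassificationProfile]],
    row_field: str,
    col_field: str = "count",
) -> CrossTab:
    """Cross-tabulate document counts by two metadata keys.

    Multi-valued keys (``setting``) contribute one count per value, so the
    grand total may exceed the corpus size. ``col_field="count"`` yields the
    one-column marginal table.
    """
    by_id = {p.doc_id: p for p in profiles} if profiles else {}
    cells: dict[tuple[str, str], int] = {}
    for doc in corpus:
        p = by_id.get(doc.doc_id)
        for rv in _field_values(doc, p, row_field):
            for cv in _field_values(doc, p, col_field):
                cells[(rv, cv)] = cells.get((rv, cv), 0) + 1
    if not cells:
        raise ValueError(
            f"fields {row_field!r} x {col_field!r} are absent from every document"
        )
    rows = sorted({r for r, _ in cells})
    cols = sorted({c for _, c in cells})
    counts = np.zeros((len(rows), len(cols)), dtype=int)
    for (r, c), n in cells.items():
        counts[rows.index(r), cols.index(c)] = n
    return CrossTab(row_key=row_field, col_key=col_field, rows=rows,
                    cols=cols, counts=counts)


def relative_frequency_matrix(tab: CrossTab) -> pd.DataFrame:
    """Row-normalize a cross-tabulation; rows with zero total are dropped."""
    totals = tab.row_totals
    if (totals == 0).all():
        raise ValueError("every row of the cross-tabulation is empty")
    keep = totals > 0
    dropped = [r for r, k in zip(tab.rows, keep) if not k]
    if dropped:
        warnings.warn(f"dropping zero-total rows: {dropped}", stacklevel=2)
    rel = tab.counts[keep].astype(float) / totals[keep, None]
    return pd.DataFrame(rel, index=[r for r, k in zip(tab.rows, keep) if k],
                        columns=tab.cols)


class DictionaryClassifier(ClassifierMixin, BaseEstimator):
    """Area classifier: TF-IDF dictionary induction + d-word matching.

    ``fit(X, y)`` takes raw reference texts and their area labels and builds
    the taxonomy (``taxonomy_``); ``predict(X)`` assigns each new text the
    area whose dictionary it matches most. Composes with sklearn pipelines
    and model selection.

    Parameters mirror the dictionary-construction knobs: ``fraction`` is the
    percentile cut on the ranked candidate list (default the first
    percentile), ``idf_base`` the IDF logarithm base, ``aggregation`` the
    per-term aggregation of document TF-IDF values, ``per_area_idf`` whether
    document-frequency statistics are computed within each area sub-corpus.
    """

    def __init__(self, fraction: float = 0.01, idf_base="e",
                 aggregation: str = "mean", min_term_length: int = 3,
                 per_area_idf: bool = True, context_k: int = 2,
                 stopwords=None, lemma_exceptions=None,
                 drop_numerals: bool = False):
        self.fraction = fraction
        self.idf_base = idf_base
        self.aggregation = aggregation
        self.min_term_length = min_term_length
        self.per_area_idf = per_area_idf
        self.context_k = context_k
        self.stopwords = stopwords
        self.lemma_exceptions = lemma_exceptions
        self.drop_numerals = drop_numerals

    def _preprocessor(self) -> TextPreprocessor:
        return TextPreprocessor(stopwords=self.stopwords,
                                lemma_exceptions=self.lemma_exceptions,
                                drop_numerals=self.drop_numerals)

    def fit(self, X, y):
        """Build the taxonomy from reference texts ``X`` labelled by area ``y``."""
        X = list(X)
        y = list(y)
        if len(X) != len(y):
            raise ValueError(f"X and y length mismatch: {len(X)} vs {len(y)}")
        from .corpus_io import Corpus, Document

        corpus = Corpus([
            Document(doc_id=f"ref{i}", text=t, source_kind="scientific",
                     area_label=a)
            for i, (t, a) in enumerate(zip(X, y))
        ])
        self.classes_ = np.array(sorted(set(y)))
        self.taxonomy_ = build_taxonomy(
            corpus, fraction=self.fraction, idf_base=self.idf_base,
            aggregation=self.aggregation, min_term_length=self.min_term_length,
            per_area_idf=self.per_area_idf, context_k=self.context_k,
            areas=sorted(set(y)), stopwords=self.stopwords,
            lemma_exceptions=self.lemma_exceptions,
            drop_numerals=self.drop_numerals,
        )
        return self

    def profile(self, X, doc_ids: Optional[Sequence[str]] = None
                ) -> list[ClassificationProfile]:
        """Full per-area hit profiles for raw texts ``X``."""
        check_is_fitted(self, "taxonomy_")
        prep = self._preprocessor()
        ids = list(doc_ids) if doc_ids is not None else [str(i) for i in range(len(X))]
        out = []
        for doc_id, lemmas in zip(ids, prep.transform(X)):
            stream = TokenStream(doc_id=doc_id, lemmas=lemmas,
                                 raw_token_count=len(lemmas))
            out.append(area_profile(stream, self.taxonomy_))
        return out

    def predict(self, X) -> np.ndarray:
        """Assigned area per text ("unclassified" when nothing matches)."""
        return np.array([p.assigned_area for p in self.profile(X)], dtype=object)


def classify_corpus(corpus: Corpus, taxonomy: Taxonomy,
                    stopwords=None, lemma_exceptions=None,
                    drop_numerals: bool = False) -> list[ClassificationProfile]:
    """Profile every document of a corpus against a prebuilt taxonomy."""
    prep = TextPreprocessor(stopwords=stopwords, lemma_exceptions=lemma_exceptions,
                            drop_numerals=drop_numerals)
    return [area_profile(prep.stream(doc), taxonomy) for doc in corpus]
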