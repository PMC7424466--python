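"""Text preprocessing: tokenization, stop-word removal, rule lemmatization.

Every downstream count (TF-IDF, phrase frequencies, dictionary matching)
operates on the lemma stream produced here. The lemmatizer is a deterministic
exception-table + English suffix-rule reducer rather than a statistical
model, so identical inputs always yield identical streams; it is iterated to
a fixed point, which makes it idempotent by construction.
"""

from __future__ import annotations

import re
import unicodedata
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

from sklearn.base import BaseEstimator, TransformerMixin

from .corpus_io import Document

_TOKEN_RE = re.compile(r"[a-z0-9]+")
_VOWELS = set("aeiou")


def default_stopwords() -> frozenset[str]:
    """The packaged English stop-word list (articles, pronouns, adverbs...)."""
    text = (resources.files("policymap") / "data" / "stopwords_en.txt").read_text(
        encoding="utf-8"
    )
    return frozenset(
        line.strip() for line in text.splitlines()
        if line.strip() and not line.startswith("#")
    )


def load_stopwords(path: str | Path) -> frozenset[str]:
    """Load a stop-word list: one lowercase term per line, UTF-8."""
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    return frozenset(l.strip().lower() for l in lines if l.strip())


def load_lemma_exceptions(path: str | Path) -> dict[str, str]:
    """Load a lemma-exception table: TSV ``term<TAB>lemma``."""
    table: dict[str, str] = {}
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        if not line.strip():
            continue
        term, lemma = line.split("\t")
        table[term.strip().lower()] = lemma.strip().lower()
    return table


def tokenize(text: str, drop_numerals: bool = False) -> list[str]:
    """Split raw text into lowercase word tokens.

    Maximal runs of ASCII letters/digits after NFC normalization; internal
    hyphens therefore split words, and all punctuation (including curly
    quotes) is discarded. Numerals are kept by default because policy texts
    cite bill numbers.
    """
    text = unicodedata.normalize("NFC", text).lower()
    tokens = _TOKEN_RE.findall(text)
    if drop_numerals:
        tokens = [t for t in tokens if not t.isdigit()]
    return tokens


def remove_stopwords(tokens: Sequence[str], stoplist: Iterable[str]) -> list[str]:
    """Order-preserving removal of stop-list terms."""
    stopset = frozenset(stoplist)
    return [t for t in tokens if t not in stopset]


def _has_vowel(s: str) -> bool:
    return any(ch in _VOWELS for ch in s)


def _strip_suffix_once(token: str) -> str:
    """One pass of the suffix rules; returns the token unchanged at a fixed point."""
    if token.endswith("ies") and len(token) > 4:
        return token[:-3] + "y"
    if token.endswith("es") and len(token) > 4:
        stem = token[:-2]
        # only -es forms whose stem could not simply take -s: boxes, dishes
        if stem.endswith(("s", "x", "z", "ch", "sh")):
            return stem
    if token.endswith("s") and not token.endswith(("ss", "us", "is")) and len(token) > 3:
        return token[:-1]
    for suffix in ("ing", "ed"):
        if token.endswith(suffix) and len(token) > len(suffix) + 2:
            stem = token[: -len(suffix)]
            if len(stem) >= 3 and stem[-1] == stem[-2] and stem[-1] not in _VOWELS:
                stem = stem[:-1]  # running -> run, stopped -> stop
            if len(stem) >= 3 and _has_vowel(stem):
                return stem
    return token


def lemmatize(
    tokens: Sequence[str],
    exceptions: Optional[Mapping[str, str]] = None,
) -> list[str]:
    """Map tokens to lemmas via the exception table, then suffix rules.

    The exception table wins outright (``children -> child``). Suffix rules
    cover plural ``-s/-es/-ies`` and verbal ``-ing/-ed`` where a plausible
    stem (>= 3 characters, containing a vowel) remains, and are applied until
    a fixed point, so ``lemmatize(lemmatize(x)) == lemmatize(x)``.
    """
    exceptions = exceptions or {}
    out: list[str] = []
    for token in tokens:
        if token in exceptions:
            out.append(exceptions[token])
            continue
        current = token
        for _ in range(8):  # suffix rules strictly shorten; 8 passes suffice
            nxt = _strip_suffix_once(current)
            if nxt == current:
                break
            current = nxt
        out.append(current)
    return out


@dataclass
class TokenStream:
    """The preprocessed lemma stream of one document."""

    doc_id: str
    lemmas: list[str]
    raw_token_count: int

    def __post_init__(self) -> None:
        if self.raw_token_count < len(self.lemmas):
            raise ValueError(
                f"{self.doc_id}: raw_token_count {self.raw_token_count} < "
                f"{len(self.lemmas)} lemmas"
            )

    def __len__(self) -> int:
        return len(self.lemmas)


def preprocess_document(
    doc: Document,
    stoplist: Optional[Iterable[str]] = None,
    exceptions: Optional[Mapping[str, str]] = None,
    drop_numerals: bool = False,
) -> TokenStream:
    """tokenize -> remove stop words -> lemmatize, as one TokenStream."""
    stoplist = default_stopwords() if stoplist is None else frozenset(stoplist)
    tokens = tokenize(doc.text, drop_numerals=drop_numerals)
    lemmas = lemmatize(remove_stopwords(tokens, stoplist), exceptions)
    return TokenStream(doc_id=doc.doc_id, lemmas=lemmas,
                       raw_token_count=len(tokens))


class TextPreprocessor(TransformerMixin, BaseEstimator):
    """Stateless transformer from raw texts to lemma lists.

    Parameters
    ----------
    stopwords : iterable of str, optional
        Stop-word list; ``None`` uses the packaged English list.
    lemma_exceptions : mapping, optional
        Irregular-form table applied before the suffix rules.
    drop_numerals : bool, default False
        Drop purely numeric tokens.
    """

    def __init__(self, stopwords=None, lemma_exceptions=None,
                 drop_numerals: bool = False):
        self.stopwords = stopwords
        self.lemma_exceptions = lemma_exceptions
        self.drop_numerals = drop_numerals

    def fit(self, X, y=None):
        return self

    def transform(self, X) -> list[list[str]]:
        stoplist = (default_stopwords() if self.stopwords is None
                    else frozenset(self.stopwords))
        return [
            lemmatize(
                remove_stopwords(
                    tokenize(text, drop_numerals=self.drop_numerals), stoplist
                ),
                self.lemma_exceptions,
            )
            for text in X
        ]

    def stream(self, doc: Document) -> TokenStream:
        return preprocess_document(
            doc,
            stoplist=self.stopwords,
            exceptions=self.lemma_exceptions,
            drop_numerals=self.drop_numerals,
        )
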