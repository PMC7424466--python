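"""Synthetic labelled corpora with known ground truth.

The generator emulates the statistical structure the pipeline assumes about
its two inputs: a labelled scientific reference corpus, where each area has
a specialized vocabulary that its documents draw from with probability
``specialization_rate`` (the rest coming from a heavy-tailed shared pool),
and a metadata-rich policy corpus, where each short summary mixes area
vocabularies according to a Dirichlet-distributed mixture with a known
dominant area. Vocabularies are pronounceable consonant-vowel pseudo-words,
so the stop-word list and the lemmatizer never interfere with planted
structure, and every run is byte-deterministic under its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from pydantic import BaseModel, Field, model_validator

from .corpus_io import AREAS, Corpus, Document

US_STATES = (
    "AL AK AZ AR CA CO CT DE DC FL GA HI ID IL IN IA KS KY LA ME MD MA MI MN "
    "MS MO MT NE NV NH NJ NM NY NC ND OH OK OR PA RI SC SD TN TX UT VT VA WA "
    "WV WI WY"
).split()

#: CDC policy settings; one policy may carry several.
SETTINGS = (
    "community",
    "school and after school",
    "restaurant and food retail",
    "early care and education",
    "medical facilities and hospital",
    "workplace",
)

_CONSONANTS = "bcdfghjklmnpqrstvwz"
_VOWELS = "aeiou"
_SYLLABLES = [c + v for c in _CONSONANTS for v in _VOWELS]


class GeneratorConfig(BaseModel):
    """All knobs of the corpus generators; the seed is mandatory.

    ``specialization_rate`` is the probability a scientific-document token
    comes from its own area pool (the complement goes to the shared pool).
    ``dirichlet_alpha`` is rotated per policy document so its largest entry
    sits on that document's dominant area.
    """

    seed: int
    areas: list[str] = Field(default_factory=lambda: list(AREAS))
    vocab_per_area: int = Field(default=40, ge=1)
    shared_vocab: int = Field(default=120, ge=1)
    specialization_rate: float = Field(default=0.7, ge=0.0, le=1.0)
    doc_length_range: tuple[int, int] = (80, 120)
    docs_per_area: int = Field(default=60, ge=1)
    n_policies: int = Field(default=500, ge=1)
    dirichlet_alpha: Optional[list[float]] = None
    background_rate: float = Field(default=0.2, ge=0.0, le=1.0)
    states: list[str] = Field(default_factory=lambda: list(US_STATES))
    years: tuple[int, int] = (2003, 2013)
    settings_pool: list[str] = Field(default_factory=lambda: list(SETTINGS))
    overlap_count: int = Field(default=0, ge=0)
    state_weights: Optional[list[float]] = None
    planted_phrases: list[tuple[list[str], int]] = Field(default_factory=list)

    @model_validator(mode="after")
    def _check(self) -> "GeneratorConfig":
        lo, hi = self.doc_length_range
        if lo < 1 or hi < lo:
            raise ValueError(f"invalid doc_length_range {self.doc_length_range}")
        y0, y1 = self.years
        if y1 < y0:
            raise ValueError(f"invalid year range {self.years}")
        if self.dirichlet_alpha is not None:
            if len(self.dirichlet_alpha) != len(self.areas):
                raise ValueError("dirichlet_alpha length must match areas")
            if any(a <= 0 for a in self.dirichlet_alpha):
                raise ValueError("dirichlet_alpha entries must be positive")
        if self.overlap_count > self.vocab_per_area:
            raise ValueError("overlap_count exceeds vocab_per_area")
        if self.state_weights is not None and len(self.state_weights) != len(self.states):
            raise ValueError("state_weights length must match states")
        return self

    def alpha(self) -> np.ndarray:
        """Default mixture concentration: peaked on the dominant area."""
        if self.dirichlet_alpha is not None:
            return np.asarray(self.dirichlet_alpha, float)
        k = len(self.areas)
        return np.array([6.0] + [0.4] * (k - 1))


@dataclass
class GroundTruth:
    """What the generator planted, for recovery checks."""

    area_pools: dict[str, list[str]]
    shared_pool: list[str]
    doc_area: dict[str, str] = field(default_factory=dict)
    doc_theta: dict[str, list[float]] = field(default_factory=dict)
    planted_phrases: dict[str, list[str]] = field(default_factory=dict)

    def records(self) -> list[dict]:
        out = []
        for doc_id in sorted(set(self.doc_area) | set(self.doc_theta)):
            rec: dict = {"doc_id": doc_id}
            if doc_id in self.doc_area:
                rec["area"] = self.doc_area[doc_id]
            if doc_id in self.doc_theta:
                rec["theta"] = self.doc_theta[doc_id]
            if doc_id in self.planted_phrases:
                rec["planted"] = self.planted_phrases[doc_id]
            out.append(rec)
        return out


def make_vocab(config: GeneratorConfig) -> tuple[dict[str, list[str]], list[str]]:
    """Disjoint pseudo-word pools per area plus a shared background pool.

    Words are three consonant-vowel syllables (six letters), drawn without
    replacement from a seeded permutation of the syllable space; any word
    colliding with the packaged stop-word list is skipped. ``overlap_count``
    plants identical extra terms into the first two area pools to exercise
    ambiguous-term disambiguation.
    """
    from .preprocess import default_stopwords

    rng = np.random.default_rng(config.seed)
    n_words = len(_SYLLABLES) ** 3
    need = (len(config.areas) * config.vocab_per_area + config.shared_vocab
            + config.overlap_count)
    if need > n_words // 2:
        raise ValueError("requested pools exceed the pseudo-word namespace")
    stop = default_stopwords()
    words: list[str] = []
    seen: set[str] = set()
    m = len(_SYLLABLES)
    while len(words) < need:
        for idx in rng.choice(n_words, size=2 * (need - len(words)) + 8,
                              replace=False):
            i, rem = divmod(int(idx), m * m)
            j, k = divmod(rem, m)
            w = _SYLLABLES[i] + _SYLLABLES[j] + _SYLLABLES[k]
            if w in stop or w in seen:
                continue
            seen.add(w)
            words.append(w)
            if len(words) == need:
                break
    pools: dict[str, list[str]] = {}
    pos = 0
    for area in config.areas:
        pools[area] = words[pos:pos + config.vocab_per_area]
        pos += config.vocab_per_area
    shared = words[pos:pos + config.shared_vocab]
    pos += config.shared_vocab
    if config.overlap_count:
        planted = words[pos:pos + config.overlap_count]
        first, second = config.areas[0], config.areas[1]
        pools[first][-config.overlap_count:] = planted
        pools[second][-config.overlap_count:] = planted
    return pools, shared


def _zipf_probs(n: int, exponent: float = 1.0) -> np.ndarray:
    w = 1.0 / np.arange(1, n + 1) ** exponent
    return w / w.sum()


def simulate_scientific_corpus(
    config: GeneratorConfig,
    pools: Optional[tuple[dict[str, list[str]], list[str]]] = None,
) -> tuple[Corpus, GroundTruth]:
    """A labelled reference corpus with planted area vocabularies.

    Each of ``docs_per_area`` documents per area draws every token from the
    own-area pool with probability ``specialization_rate`` (uniform within
    the pool), otherwise from the shared pool under a Zipf(1.0) rank
    distribution.
    """
    rng = np.random.default_rng(config.seed + 1)
    area_pools, shared = pools or make_vocab(config)
    zipf = _zipf_probs(len(shared))
    truth = GroundTruth(area_pools=area_pools, shared_pool=shared)
    docs: list[Document] = []
    lo, hi = config.doc_length_range
    for area in config.areas:
        pool = area_pools[area]
        for i in range(config.docs_per_area):
            doc_id = f"sci_{area}_{i:04d}"
            length = int(rng.integers(lo, hi + 1))
            own = rng.random(length) < config.specialization_rate
            tokens = np.where(
                own,
                rng.choice(pool, size=length),
                rng.choice(shared, size=length, p=zipf),
            )
            docs.append(Document(doc_id=doc_id, text=" ".join(tokens),
                                 source_kind="scientific", area_label=area))
            truth.doc_area[doc_id] = area
    return Corpus(docs), truth


def simulate_policy_corpus(
    config: GeneratorConfig,
    pools: Optional[tuple[dict[str, list[str]], list[str]]] = None,
) -> tuple[Corpus, GroundTruth]:
    """A metadata-rich policy corpus of known area mixtures.

    Per document: a dominant area is drawn uniformly, the Dirichlet
    concentration is rotated so its largest entry sits on that area, and a
    mixture theta is sampled. Each token then comes from the shared pool with
    probability ``background_rate``, otherwise from area pool ``a`` with
    probability ``theta_a``. State, year and 1-2 settings are sampled
    uniformly unless ``state_weights`` skews states. Planted phrases are
    inserted verbatim into the requested number of documents.
    """
    rng = np.random.default_rng(config.seed + 2)
    area_pools, shared = pools or make_vocab(config)
    zipf = _zipf_probs(len(shared))
    areas = list(config.areas)
    base_alpha = config.alpha()
    dominant_slot = int(np.argmax(base_alpha))
    truth = GroundTruth(area_pools=area_pools, shared_pool=shared)
    state_p = None
    if config.state_weights is not None:
        w = np.asarray(config.state_weights, float)
        state_p = w / w.sum()
    docs: list[Document] = []
    lo, hi = config.doc_length_range
    y0, y1 = config.years
    for i in range(config.n_policies):
        doc_id = f"pol_{i:05d}"
        dominant = int(rng.integers(len(areas)))
        alpha = base_alpha.copy()
        alpha[dominant_slot], alpha[dominant] = alpha[dominant], alpha[dominant_slot]
        theta = rng.dirichlet(alpha)
        length = int(rng.integers(lo, hi + 1))
        tokens: list[str] = []
        for _ in range(length):
            if rng.random() < config.background_rate:
                tokens.append(str(rng.choice(shared, p=zipf)))
            else:
                a = areas[int(rng.choice(len(areas), p=theta))]
                tokens.append(str(rng.choice(area_pools[a])))
        n_settings = int(rng.integers(1, min(2, len(config.settings_pool)) + 1))
        settings = [str(s) for s in rng.choice(config.settings_pool,
                                               size=n_settings, replace=False)]
        state = (str(rng.choice(config.states, p=state_p)) if state_p is not None
                 else str(config.states[int(rng.integers(len(config.states)))]))
        docs.append(Document(
            doc_id=doc_id, text=" ".join(tokens), source_kind="policy",
            state=state, year=int(rng.integers(y0, y1 + 1)), settings=settings,
        ))
        truth.doc_theta[doc_id] = [float(t) for t in theta]
        truth.doc_area[doc_id] = areas[int(np.argmax(theta))]
    for phrase, n_docs in config.planted_phrases:
        if n_docs > len(docs):
            raise ValueError(f"cannot plant {phrase} in {n_docs} of {len(docs)} docs")
        chosen = rng.choice(len(docs), size=n_docs, replace=False)
        for j in sorted(int(c) for c in chosen):
            words = docs[j].text.split()
            at = int(rng.integers(0, len(words) + 1))
            docs[j] = Document(
                doc_id=docs[j].doc_id,
                text=" ".join(words[:at] + list(phrase) + words[at:]),
                source_kind="policy", state=docs[j].state, year=docs[j].year,
                settings=docs[j].settings,
            )
            truth.planted_phrases.setdefault(docs[j].doc_id, []).append(
                " ".join(phrase)
            )
    return Corpus(docs), truth
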