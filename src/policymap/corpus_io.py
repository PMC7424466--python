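"""Corpus, dictionary and table I/O.

Corpora are read from JSON-lines (canonical) or CSV with the same column
names. Every record needs a unique ``doc_id`` and a ``text``; documents from
a labelled scientific reference corpus additionally carry an ``area_label``,
policy documents may carry ``state`` (2-letter postal code or DC), ``year``
and a multi-valued ``settings`` list.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

import pandas as pd

#: The five scientific areas of the classification taxonomy.
AREAS = ("health", "life", "multidisciplinary", "physical", "social")

#: Label used for documents matching no dictionary at all.
UNCLASSIFIED = "unclassified"

_SOURCE_KINDS = ("scientific", "policy")


@dataclass
class Document:
    """A single corpus document with optional policy metadata."""

    doc_id: str
    text: str
    source_kind: str = "policy"
    area_label: Optional[str] = None
    state: Optional[str] = None
    year: Optional[int] = None
    settings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.source_kind not in _SOURCE_KINDS:
            raise ValueError(
                f"document {self.doc_id!r}: source_kind must be one of "
                f"{_SOURCE_KINDS}, got {self.source_kind!r}"
            )
        if self.source_kind == "scientific" and not self.area_label:
            raise ValueError(
                f"scientific document {self.doc_id!r} is missing area_label"
            )
        if self.state is not None:
            self.state = str(self.state).strip().upper()
            if len(self.state) != 2 or not self.state.isalpha():
                raise ValueError(
                    f"document {self.doc_id!r}: state must be a 2-letter "
                    f"postal code, got {self.state!r}"
                )
        if self.year is not None:
            self.year = int(self.year)
        self.settings = [str(s) for s in self.settings]


@dataclass
class Corpus:
    """An ordered collection of documents."""

    documents: list[Document]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for doc in self.documents:
            if doc.doc_id in seen:
                raise ValueError(f"duplicate doc_id {doc.doc_id!r} in corpus")
            seen.add(doc.doc_id)

    @property
    def corpus_size(self) -> int:
        return len(self.documents)

    def __len__(self) -> int:
        return len(self.documents)

    def __iter__(self) -> Iterator[Document]:
        return iter(self.documents)

    def texts(self) -> list[str]:
        return [d.text for d in self.documents]

    def doc_ids(self) -> list[str]:
        return [d.doc_id for d in self.documents]


_OPTIONAL_FIELDS = ("source_kind", "area_label", "state", "year", "settings")


def _record_to_document(rec: dict, where: str) -> Document:
    if "doc_id" not in rec or rec["doc_id"] in (None, ""):
        raise ValueError(f"{where}: record is missing doc_id")
    if "text" not in rec or rec["text"] is None or str(rec["text"]) == "nan":
        raise ValueError(f"{where}: record {rec.get('doc_id')!r} is missing text")
    kwargs = {"doc_id": str(rec["doc_id"]), "text": str(rec["text"])}
    for name in _OPTIONAL_FIELDS:
        value = rec.get(name)
        if value is None or (isinstance(value, float) and pd.isna(value)):
            continue
        if name == "settings" and isinstance(value, str):
            value = [s.strip() for s in value.split(";") if s.strip()]
        if name == "area_label" and str(value) == "":
            continue
        kwargs[name] = value
    return Document(**kwargs)


def read_corpus(path: str | Path, format: Optional[str] = None) -> Corpus:
    """Read a corpus from a JSON-lines or CSV file, preserving input order.

    Parameters
    ----------
    path
        Input file. ``format`` defaults to the file suffix (``.jsonl`` /
        ``.csv``).
    format
        ``"jsonl"`` or ``"csv"``.
    """
    path = Path(path)
    if format is None:
        format = "csv" if path.suffix.lower() == ".csv" else "jsonl"
    if format not in ("jsonl", "csv"):
        raise ValueError(f"unknown corpus format {format!r}")
    docs: list[Document] = []
    if format == "jsonl":
        with path.open(encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                rec = json.loads(line)
                docs.append(_record_to_document(rec, f"{path}:{lineno}"))
    else:
        frame = pd.read_csv(path, dtype={"doc_id": str, "state": str})
        for lineno, rec in enumerate(frame.to_dict(orient="records"), start=2):
            docs.append(_record_to_document(rec, f"{path}:{lineno}"))
    return Corpus(docs)


def write_corpus(corpus: Corpus, path: str | Path) -> Path:
    """Write a corpus as JSON-lines (the canonical interchange format)."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for doc in corpus:
            rec: dict = {"doc_id": doc.doc_id, "text": doc.text,
                         "source_kind": doc.source_kind}
            if doc.area_label is not None:
                rec["area_label"] = doc.area_label
            if doc.state is not None:
                rec["state"] = doc.state
            if doc.year is not None:
                rec["year"] = doc.year
            if doc.settings:
                rec["settings"] = doc.settings
            fh.write(json.dumps(rec, sort_keys=True) + "\n")
    return path


def write_table(rows: pd.DataFrame, path: str | Path) -> Path:
    """Write a labelled numeric table as CSV with full numeric precision.

    Re-reading the file with :func:`pandas.read_csv` reproduces the values
    exactly (floats are rendered with ``repr`` round-trip precision).
    """
    if rows is None or len(rows) == 0:
        raise ValueError("refusing to write an empty table")
    path = Path(path)
    rows.to_csv(path, index=True, float_format=None)
    return path


def write_dictionary(taxonomy, path: str | Path) -> Path:
    """Serialize a taxonomy as TSV.

    Columns: ``area, rank, term, score, context_term_1, context_term_2``
    (context cells carry ``term:coefficient`` pairs, empty for unambiguous
    d-words). Rows are ordered area-alphabetically, then by rank, so equal
    taxonomies serialize byte-identically.
    """
    if not taxonomy.dictionaries:
        raise ValueError("taxonomy has no area dictionaries")
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(
            ["area", "rank", "term", "score", "context_term_1", "context_term_2"]
        )
        for area in sorted(taxonomy.dictionaries):
            for dw in taxonomy.dictionaries[area].dwords:
                ctx = [f"{t}:{c:.6f}" for t, c in dw.context_terms]
                ctx += [""] * (2 - len(ctx))
                writer.writerow([area, dw.rank, dw.term, repr(dw.score), *ctx[:2]])
    return path


def read_dictionary(path: str | Path):
    """Read a taxonomy TSV written by :func:`write_dictionary`."""
    from .dictionary import AreaDictionary, DWord, Taxonomy

    per_area: dict[str, list[DWord]] = {}
    with Path(path).open(encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader)
        if header[:4] != ["area", "rank", "term", "score"]:
            raise ValueError(f"{path}: not a taxonomy TSV")
        for row in reader:
            area, rank, term, score, c1, c2 = row
            ctx = []
            for cell in (c1, c2):
                if cell:
                    t, c = cell.rsplit(":", 1)
                    ctx.append((t, float(c)))
            per_area.setdefault(area, []).append(
                DWord(term=term, score=float(score), rank=int(rank),
                      context_terms=ctx, ambiguous=bool(ctx))
            )
    dicts = {
        area: AreaDictionary(area=area, dwords=dws, candidate_count=len(dws))
        for area, dws in per_area.items()
    }
    return Taxonomy(dictionaries=dicts, build_config={"source": str(path)})


def corpus_from_records(records: Iterable[dict]) -> Corpus:
    """Build a corpus from in-memory dict records (same schema as JSONL)."""
    return Corpus([_record_to_document(dict(r), f"record {i}")
                   for i, r in enumerate(records)])


def subset(corpus: Corpus, doc_ids: Sequence[str]) -> Corpus:
    wanted = set(doc_ids)
    return Corpus([d for d in corpus if d.doc_id in wanted])
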