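"""Parsing, filtering and merging of concept-annotated disorder records.

A disorder record (an OMIM-style entry) arrives with two concept
sub-vectors: one parsed from the title and one from the textual
description / clinical synopsis.  This module turns a file of such
records into a :class:`Corpus` of per-record concept-frequency vectors,
applying the cleaning rules of the phenotype-similarity pipeline:

* keep only records whose type prefix marks a phenotype (``#``, ``%``,
  ``none``) rather than a gene;
* strip trailing subtype designators from titles so subtypes of one
  disorder share a main title;
* add the title and text sub-vectors together;
* drop stoplisted generic concepts, concepts confined to a single
  record, and records left with no concepts — iterated to a fixed
  point, since the two removals interact.
"""

from __future__ import annotations

import json
import logging
import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

logger = logging.getLogger(__name__)

#: Record type prefixes that denote a phenotype (disease condition).
DISEASE_PREFIXES = frozenset({"#", "%", "none"})

#: All prefixes accepted in input files.
VALID_PREFIXES = frozenset({"#", "%", "none", "*", "+", "^"})


class ParseError(ValueError):
    """A record file did not conform to the documented dialect."""


class CorpusError(ValueError):
    """Corpus construction produced an unusable (empty) corpus."""


@dataclass(frozen=True)
class RawRecord:
    """One disorder record as read from disk, before any filtering.

    ``title_concepts`` and ``text_concepts`` are ``(concept_id,
    frequency)`` pairs with frequency >= 1; ``references`` lists ids of
    other records this record's text points to (used for the linked-pair
    benchmark).
    """

    record_id: str
    prefix: str
    title: str
    title_concepts: tuple[tuple[str, int], ...]
    text_concepts: tuple[tuple[str, int], ...]
    references: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.prefix not in VALID_PREFIXES:
            raise ValueError(
                f"record {self.record_id!r}: unknown prefix {self.prefix!r}"
            )
        for cid, freq in (*self.title_concepts, *self.text_concepts):
            if freq < 1:
                raise ValueError(
                    f"record {self.record_id!r}: concept {cid!r} has "
                    f"non-positive frequency {freq}"
                )


@dataclass
class ConceptVector:
    """Sparse concept -> value map for one record.

    Values are raw frequencies after corpus construction and weights
    after a weighting scheme is applied.  Zero entries are never stored.
    """

    record_id: str
    weights: dict[str, float]

    def __post_init__(self) -> None:
        self.weights = {c: w for c, w in self.weights.items() if w != 0}

    def __len__(self) -> int:
        return len(self.weights)

    def support(self) -> frozenset[str]:
        return frozenset(self.weights)


@dataclass
class Corpus:
    """A cleaned collection of concept vectors plus its vocabulary.

    ``vocabulary`` maps each concept id to its document count (number of
    records whose vector contains it); after construction every concept
    has document count >= 2 and every record >= 1 concept.
    """

    vectors: dict[str, ConceptVector]
    vocabulary: dict[str, int]

    @property
    def n_records(self) -> int:
        return len(self.vectors)

    def document_count(self, concept_id: str) -> int:
        return self.vocabulary.get(concept_id, 0)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "vectors": {rid: v.weights for rid, v in self.vectors.items()},
            "vocabulary": self.vocabulary,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "Corpus":
        payload = json.loads(Path(path).read_text())
        vectors = {
            rid: ConceptVector(rid, {c: float(w) for c, w in wts.items()})
            for rid, wts in payload["vectors"].items()
        }
        vocab = {c: int(n) for c, n in payload["vocabulary"].items()}
        return cls(vectors=vectors, vocabulary=vocab)


# ---------------------------------------------------------------------------
# reading


def _parse_concept_list(text: str, *, line_no: int) -> tuple[tuple[str, int], ...]:
    text = text.strip()
    if not text:
        return ()
    out = []
    for item in text.split(";"):
        item = item.strip()
        if not item:
            continue
        cid, sep, freq = item.rpartition(":")
        if not sep or not cid:
            raise ParseError(f"line {line_no}: malformed concept entry {item!r}")
        try:
            f = int(freq)
        except ValueError:
            raise ParseError(
                f"line {line_no}: non-integer frequency in {item!r}"
            ) from None
        if f < 1:
            raise ParseError(f"line {line_no}: frequency must be >= 1 in {item!r}")
        out.append((cid, f))
    return tuple(out)


_TSV_COLUMNS = ("record_id", "prefix", "title", "title_concepts", "text_concepts")


def read_records(path: str | Path, format: str | None = None) -> list[RawRecord]:
    """Read disorder records from a TSV or JSON file.

    The TSV dialect has a required header row with columns
    ``record_id, prefix, title, title_concepts, text_concepts`` and an
    optional sixth ``references`` column; concept lists are
    ``id:freq`` pairs joined by ``;``.  The JSON dialect is an array of
    objects with the same field names.  ``format`` defaults to the file
    extension.
    """
    path = Path(path)
    if format is None:
        format = "json" if path.suffix.lower() == ".json" else "tsv"
    if format not in ("tsv", "json"):
        raise ValueError(f"unknown record format {format!r}")

    records: list[RawRecord] = []
    seen: set[str] = set()

    def _add(rec: RawRecord, where: str) -> None:
        if rec.record_id in seen:
            raise ParseError(f"{where}: duplicate record_id {rec.record_id!r}")
        seen.add(rec.record_id)
        records.append(rec)

    if format == "json":
        data = json.loads(path.read_text())
        if not isinstance(data, list):
            raise ParseError("JSON record file must be an array of objects")
        for i, obj in enumerate(data):
            try:
                rec = RawRecord(
                    record_id=str(obj["record_id"]),
                    prefix=str(obj["prefix"]),
                    title=str(obj.get("title", "")),
                    title_concepts=tuple(
                        (str(c), int(f)) for c, f in obj.get("title_concepts", [])
                    ),
                    text_concepts=tuple(
                        (str(c), int(f)) for c, f in obj.get("text_concepts", [])
                    ),
                    references=frozenset(
                        str(r) for r in obj.get("references", [])
                    ),
                )
            except (KeyError, TypeError, ValueError) as exc:
                raise ParseError(f"object {i}: {exc}") from exc
            _add(rec, f"object {i}")
        return records

    with path.open(encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header[:5]) != _TSV_COLUMNS:
            raise ParseError(
                f"line 1: header must start with {list(_TSV_COLUMNS)}, got {header}"
            )
        for line_no, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 5:
                raise ParseError(f"line {line_no}: expected >= 5 columns")
            refs: frozenset[str] = frozenset()
            if len(fields) >= 6 and fields[5].strip():
                refs = frozenset(
                    r.strip() for r in fields[5].split(";") if r.strip()
                )
            try:
                rec = RawRecord(
                    record_id=fields[0],
                    prefix=fields[1],
                    title=fields[2],
                    title_concepts=_parse_concept_list(fields[3], line_no=line_no),
                    text_concepts=_parse_concept_list(fields[4], line_no=line_no),
                    references=refs,
                )
            except ValueError as exc:
                if isinstance(exc, ParseError):
                    raise
                raise ParseError(f"line {line_no}: {exc}") from exc
            _add(rec, f"line {line_no}")
    return records


def filter_by_prefix(records: Sequence[RawRecord]) -> list[RawRecord]:
    """Keep only phenotype records (prefix ``#``, ``%`` or ``none``)."""
    return [r for r in records if r.prefix in DISEASE_PREFIXES]


# ---------------------------------------------------------------------------
# title cleaning

# Strict roman-numeral pattern so ordinary words spelled from roman
# letters (e.g. "MILD") are not stripped.
_ROMAN = re.compile(
    r"^M{0,3}(CM|CD|D?C{0,3})(XC|XL|L?X{0,3})(IX|IV|V?I{0,3})$"
)
_TRAILING_SEP = re.compile(r"[\s,;]+$")
_TYPE_SUFFIX = re.compile(r"(^|[\s,;])TYPE\s+\S+$", re.IGNORECASE)


def _is_designator(token: str) -> bool:
    if not token:
        return False
    if token.isdigit():
        return True
    if len(token) == 1 and token.isalpha():
        return True
    up = token.upper()
    return bool(up and _ROMAN.match(up))


def strip_subtype_designators(title: str) -> str:
    """Remove trailing subtype designators from a record title.

    Terminal arabic numerals, roman numerals, single letters and
    ``TYPE <token>`` suffixes are stripped repeatedly; trailing commas,
    semicolons and whitespace are trimmed.  Internal words are never
    touched, so "EPILEPSY, FAMILIAL FOCAL, 1" becomes
    "EPILEPSY, FAMILIAL FOCAL" while "MARFAN SYNDROME" is unchanged.
    """
    t = _TRAILING_SEP.sub("", title.strip())
    while True:
        m = _TYPE_SUFFIX.search(t)
        if m:
            t = _TRAILING_SEP.sub("", t[: m.start()])
            continue
        tokens = re.split(r"[\s,;]+", t)
        last = tokens[-1] if tokens else ""
        if last and _is_designator(last):
            t = _TRAILING_SEP.sub("", t[: len(t) - len(last)])
            continue
        return t


# ---------------------------------------------------------------------------
# corpus construction


def merge_subvectors(
    title_concepts: Iterable[tuple[str, int]],
    text_concepts: Iterable[tuple[str, int]],
) -> Counter:
    """Entry-wise sum of the title and text concept-frequency sub-vectors."""
    merged: Counter = Counter()
    for cid, freq in title_concepts:
        merged[cid] += freq
    for cid, freq in text_concepts:
        merged[cid] += freq
    return merged


def default_stoplist() -> frozenset[str]:
    """The small shipped stoplist of generic disease-vocabulary concepts."""
    return read_stoplist(Path(__file__).parent / "data" / "stoplist_default.txt")


def read_stoplist(path: str | Path) -> frozenset[str]:
    """Read a stoplist file: one concept id per line, ``#`` comments."""
    out = set()
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            out.add(line)
    return frozenset(out)


def build_corpus(
    records: Sequence[RawRecord],
    stoplist: Iterable[str] = (),
) -> Corpus:
    """Build a cleaned corpus from prefix-filtered records.

    Per record the title and text sub-vectors are merged; stoplisted
    concepts are removed; then records with empty vectors and concepts
    occurring in only one record are removed alternately until a fixed
    point is reached.  Raises :class:`CorpusError` if nothing survives.
    """
    stop = frozenset(stoplist)
    vectors: dict[str, Counter] = {}
    for rec in records:
        merged = merge_subvectors(rec.title_concepts, rec.text_concepts)
        for cid in stop:
            merged.pop(cid, None)
        if merged:
            vectors[rec.record_id] = merged
        else:
            logger.info("record %s dropped: no concepts after stoplist", rec.record_id)

    while True:
        doc_counts: Counter = Counter()
        for vec in vectors.values():
            doc_counts.update(vec.keys())
        singletons = {c for c, n in doc_counts.items() if n == 1}
        if not singletons:
            break
        emptied = []
        for rid, vec in vectors.items():
            for c in singletons.intersection(vec):
                del vec[c]
            if not vec:
                emptied.append(rid)
        for rid in emptied:
            logger.info("record %s dropped: empty after singleton removal", rid)
            del vectors[rid]

    if not vectors:
        raise CorpusError("corpus empty after filtering")

    doc_counts = Counter()
    for vec in vectors.values():
        doc_counts.update(vec.keys())
    return Corpus(
        vectors={
            rid: ConceptVector(rid, {c: float(f) for c, f in vec.items()})
            for rid, vec in vectors.items()
        },
        vocabulary=dict(doc_counts),
    )
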