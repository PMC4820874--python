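"""Concept-vector weighting schemes and the cosine phenotype-similarity matrix.

Two weighting formulas drive the four supported schemes.  Global
weighting is an inverse-document-frequency term that corrects for
differences in record length and down-weights ubiquitous concepts::

    global(concept) = log2(N / n_concept)

with ``N`` the number of records in the corpus and ``n_concept`` the
number of records containing the concept.  Local weighting is an
augmented within-record frequency::

    local(concept, record) = 0.5 + r_concept / (2 * r_max)

with ``r_concept`` the concept's frequency in the record and ``r_max``
the largest concept frequency in that record.  The four schemes are
``unweighted`` (raw frequencies), ``global`` (presence-based IDF),
``local``, and ``global_local`` (their product, the MimMiner-style
weighting).  Record-record similarity is the cosine of the angle
between weighted vectors; weights are non-negative, so scores lie in
[0, 1].
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import scipy.sparse as sp
from sklearn.preprocessing import normalize

from .corpus import ConceptVector, Corpus

logger = logging.getLogger(__name__)

SCHEMES = ("unweighted", "global", "local", "global_local")


def global_weight(N: int, n_concept: int) -> float:
    """IDF-style weight log2(N / n_concept) for a concept.

    ``N`` is the corpus size, ``n_concept`` the concept's document
    count; a concept present in every record gets weight 0.
    """
    if not 1 <= n_concept <= N:
        raise ValueError(f"require 1 <= n_concept <= N, got n_concept={n_concept}, N={N}")
    return math.log2(N / n_concept)


def local_weight(r_concept: int, r_max: int) -> float:
    """Augmented frequency weight 0.5 + r_concept / (2 * r_max).

    Equals 1 for the most frequent concept in a record and tends to 0.5
    for rare ones, damping the influence of verbose records.
    """
    if r_max < 1 or not 1 <= r_concept <= r_max:
        raise ValueError(
            f"require 1 <= r_concept <= r_max, got r_concept={r_concept}, r_max={r_max}"
        )
    return 0.5 + r_concept / (2 * r_max)


def weigh_corpus(corpus: Corpus, scheme: str) -> dict[str, ConceptVector]:
    """Apply a weighting scheme to every vector of a corpus.

    Returns new :class:`ConceptVector` objects; the corpus itself is not
    modified.  Under the ``global`` scheme weighting is presence-based
    (the IDF replaces the frequency), so a concept present in all
    records drops out and a vector may become empty.
    """
    if scheme not in SCHEMES:
        raise ValueError(f"unknown weighting scheme {scheme!r}; expected one of {SCHEMES}")
    N = corpus.n_records
    out: dict[str, ConceptVector] = {}
    for rid, vec in corpus.vectors.items():
        if scheme == "unweighted":
            weights = dict(vec.weights)
        else:
            r_max = max(vec.weights.values())
            weights = {}
            for cid, freq in vec.weights.items():
                if scheme == "local":
                    w = local_weight(int(freq), int(r_max))
                else:
                    w = global_weight(N, corpus.vocabulary[cid])
                    if scheme == "global_local":
                        w *= local_weight(int(freq), int(r_max))
                weights[cid] = w
        out[rid] = ConceptVector(rid, weights)
    return out


def cosine_similarity(v1: ConceptVector, v2: ConceptVector) -> float:
    """Cosine of the angle between two sparse concept vectors."""
    n1 = math.sqrt(sum(w * w for w in v1.weights.values()))
    n2 = math.sqrt(sum(w * w for w in v2.weights.values()))
    if n1 == 0 or n2 == 0:
        raise ValueError("cosine similarity undefined for a zero vector")
    dot = sum(w * v2.weights[c] for c, w in v1.weights.items() if c in v2.weights)
    return min(dot / (n1 * n2), 1.0)


@dataclass
class SimilarityMatrix:
    """Symmetric record x record cosine-score matrix with provenance."""

    record_ids: list[str]
    scores: np.ndarray
    scheme: str

    def __post_init__(self) -> None:
        self._index = {rid: i for i, rid in enumerate(self.record_ids)}

    @property
    def n(self) -> int:
        return len(self.record_ids)

    def score(self, a: str, b: str) -> float:
        return float(self.scores[self._index[a], self._index[b]])

    def __contains__(self, record_id: str) -> bool:
        return record_id in self._index

    def to_tsv(self, path: str | Path) -> None:
        """Write a dense TSV with a header row/column of record ids."""
        with Path(path).open("w", encoding="utf-8") as fh:
            fh.write("record_id\t" + "\t".join(self.record_ids) + "\n")
            for rid, row in zip(self.record_ids, self.scores):
                fh.write(rid + "\t" + "\t".join(f"{x:.12g}" for x in row) + "\n")

    @classmethod
    def from_tsv(cls, path: str | Path, scheme: str = "unknown") -> "SimilarityMatrix":
        with Path(path).open(encoding="utf-8") as fh:
            header = fh.readline().rstrip("\n").split("\t")
            ids = header[1:]
            rows = []
            for line in fh:
                fields = line.rstrip("\n").split("\t")
                rows.append([float(x) for x in fields[1:]])
        return cls(record_ids=ids, scores=np.asarray(rows, dtype=float), scheme=scheme)

    def to_triplets(self, path: str | Path, threshold: float = 0.0) -> None:
        """Write the upper triangle as ``id_a<TAB>id_b<TAB>score`` rows."""
        with Path(path).open("w", encoding="utf-8") as fh:
            fh.write("id_a\tid_b\tscore\n")
            for i, a in enumerate(self.record_ids):
                for j in range(i + 1, self.n):
                    s = self.scores[i, j]
                    if s > threshold:
                        fh.write(f"{a}\t{self.record_ids[j]}\t{s:.12g}\n")


def build_similarity_matrix(corpus: Corpus, scheme: str) -> SimilarityMatrix:
    """Score every unordered record pair of a corpus under one scheme.

    Records whose vector is zeroed by weighting (possible under the
    ``global`` scheme) are dropped with a logged warning.
    """
    weighted = weigh_corpus(corpus, scheme)
    kept = [rid for rid, v in weighted.items() if len(v) > 0]
    dropped = [rid for rid in weighted if len(weighted[rid]) == 0]
    for rid in dropped:
        logger.warning("record %s dropped: zero vector under scheme %s", rid, scheme)
    if not kept:
        raise ValueError(f"no records left after weighting with scheme {scheme!r}")

    concept_index = {c: k for k, c in enumerate(sorted({c for rid in kept for c in weighted[rid].weights}))}
    rows, cols, vals = [], [], []
    for i, rid in enumerate(kept):
        for cid, w in weighted[rid].weights.items():
            rows.append(i)
            cols.append(concept_index[cid])
            vals.append(w)
    X = sp.csr_matrix(
        (vals, (rows, cols)), shape=(len(kept), len(concept_index)), dtype=np.float64
    )
    Xn = normalize(X, norm="l2", axis=1)
    S = (Xn @ Xn.T).toarray()
    S = np.clip((S + S.T) / 2.0, 0.0, 1.0)
    np.fill_diagonal(S, 1.0)
    return SimilarityMatrix(record_ids=kept, scores=S, scheme=scheme)


def query_similar(
    matrix: SimilarityMatrix,
    record_id: str,
    k: int,
    corpus: Corpus | None = None,
) -> list[tuple[str, float, tuple[str, ...]]]:
    """Top-k most similar records to ``record_id``, with shared concepts.

    Results are sorted by descending score with ties broken by
    ascending record id.  ``shared_concepts`` is the sorted
    intersection of the two records' concept supports (empty when no
    corpus is supplied).
    """
    if record_id not in matrix:
        raise KeyError(f"record {record_id!r} not in matrix")
    if k < 1:
        raise ValueError("k must be >= 1")
    i = matrix._index[record_id]
    others = [
        (rid, float(matrix.scores[i, j]))
        for j, rid in enumerate(matrix.record_ids)
        if rid != record_id
    ]
    others.sort(key=lambda t: (-t[1], t[0]))
    out = []
    query_support = (
        corpus.vectors[record_id].support()
        if corpus is not None and record_id in corpus.vectors
        else frozenset()
    )
    for rid, score in others[:k]:
        shared: tuple[str, ...] = ()
        if corpus is not None and rid in corpus.vectors:
            shared = tuple(sorted(query_support & corpus.vectors[rid].support()))
        out.append((rid, score, shared))
    return out
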