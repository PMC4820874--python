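"""Ground-truth similar-disorder pair sets and ROC evaluation of similarity matrices.

Two benchmark constructions are supported.  A *phenotypic series*
groups the genetically heterogeneous subtypes of one disorder; every
unordered pair of records within a series counts as phenotypically
similar.  *Linked record pairs* arise when one phenotype record's text
references another; such a pair counts as similar when both records
carry a phenotype prefix (``#`` or ``%``).

Evaluation follows the labeling rule: every off-diagonal unordered
pair in the similarity matrix is an instance, positive iff it belongs
to the benchmark set, and the score is the matrix entry.  ROC curves
and trapezoid AUC come from scikit-learn; a decile-overlap analysis
bins scored pairs into equal-width score intervals and reports the
positive fraction per bin.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import roc_curve as _sk_roc_curve

from .corpus import RawRecord
from .similarity import SimilarityMatrix

logger = logging.getLogger(__name__)

Pair = tuple[str, str]


def _canonical(a: str, b: str) -> Pair:
    return (a, b) if a < b else (b, a)


@dataclass
class PhenotypicSeries:
    """Map series_id -> set of member record ids; a record may belong to several."""

    series: dict[str, set[str]]

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PhenotypicSeries":
        """Read ``series_id<TAB>record_id`` membership lines (no header)."""
        series: dict[str, set[str]] = {}
        for line in Path(path).read_text(encoding="utf-8").splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            sid, rid = line.split("\t")[:2]
            series.setdefault(sid, set()).add(rid)
        return cls(series=series)

    def to_tsv(self, path: str | Path) -> None:
        with Path(path).open("w", encoding="utf-8") as fh:
            for sid in sorted(self.series):
                for rid in sorted(self.series[sid]):
                    fh.write(f"{sid}\t{rid}\n")


@dataclass
class BenchmarkPairSet:
    """Unordered record-id pairs labeled phenotypically similar."""

    pairs: set[Pair]
    source: str = "synthetic"

    def __post_init__(self) -> None:
        canon = set()
        for a, b in self.pairs:
            if a == b:
                raise ValueError(f"self-pair {a!r} not allowed")
            canon.add(_canonical(a, b))
        self.pairs = canon

    def __len__(self) -> int:
        return len(self.pairs)

    def __contains__(self, pair: Pair) -> bool:
        return _canonical(*pair) in self.pairs


def pairs_from_series(series: PhenotypicSeries) -> BenchmarkPairSet:
    """All within-series unordered pairs, deduplicated across series."""
    pairs: set[Pair] = set()
    for members in series.series.values():
        for a, b in combinations(sorted(members), 2):
            pairs.add(_canonical(a, b))
    return BenchmarkPairSet(pairs=pairs, source="series")


def pairs_from_links(
    records: Sequence[RawRecord],
    references: Mapping[str, Iterable[str]] | None = None,
) -> BenchmarkPairSet:
    """Pairs where one phenotype record references the other.

    A pair is included iff either direction of reference exists and
    both records carry prefix ``#`` or ``%``.  References to unknown
    record ids are ignored with a logged warning.  ``references``
    defaults to the references embedded in the records themselves.
    """
    by_id = {r.record_id: r for r in records}
    if references is None:
        references = {r.record_id: r.references for r in records}
    eligible = {rid for rid, r in by_id.items() if r.prefix in ("#", "%")}
    pairs: set[Pair] = set()
    for src, targets in references.items():
        for dst in targets:
            if dst not in by_id:
                logger.warning("reference %s -> %s ignored: unknown record", src, dst)
                continue
            if src == dst:
                continue
            if src in eligible and dst in eligible:
                pairs.add(_canonical(src, dst))
    return BenchmarkPairSet(pairs=pairs, source="links")


@dataclass
class ROCResult:
    """ROC curve (descending thresholds) and trapezoid AUC."""

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    n_positive: int = 0
    n_negative: int = 0


def _roc_from_scores(scores: np.ndarray, labels: np.ndarray) -> ROCResult:
    n_pos = int(labels.sum())
    n_neg = int(len(labels) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError(
            f"ROC needs both classes, got {n_pos} positives and {n_neg} negatives"
        )
    fpr, tpr, thr = _sk_roc_curve(labels, scores, drop_intermediate=False)
    return ROCResult(
        thresholds=thr,
        fpr=fpr,
        tpr=tpr,
        auc=float(_sk_auc(fpr, tpr)),
        n_positive=n_pos,
        n_negative=n_neg,
    )


def _pair_instances(
    matrix: SimilarityMatrix, benchmark: BenchmarkPairSet
) -> tuple[np.ndarray, np.ndarray, int]:
    """Scores and labels for all off-diagonal unordered matrix pairs.

    Returns (scores, labels, n_dropped) where n_dropped counts
    benchmark pairs involving records absent from the matrix.
    """
    index = {rid: i for i, rid in enumerate(matrix.record_ids)}
    iu, ju = np.triu_indices(matrix.n, k=1)
    scores = matrix.scores[iu, ju]
    labels = np.zeros(len(scores), dtype=bool)
    # map upper-triangle (i, j) to flat position
    n = matrix.n
    offsets = np.concatenate(([0], np.cumsum(np.arange(n - 1, 0, -1))))
    dropped = 0
    for a, b in benchmark.pairs:
        if a not in index or b not in index:
            dropped += 1
            continue
        i, j = sorted((index[a], index[b]))
        labels[offsets[i] + (j - i - 1)] = True
    if dropped:
        logger.info("%d benchmark pairs outside the matrix were dropped", dropped)
    return scores, labels, dropped


def roc_evaluate(
    matrix: SimilarityMatrix,
    benchmark: BenchmarkPairSet,
    max_negatives: int | None = None,
    rng_seed: int = 0,
) -> ROCResult:
    """ROC/AUC of a similarity matrix against a benchmark pair set.

    Positives are matrix pairs present in the benchmark; all remaining
    off-diagonal pairs are negatives.  Equal scores share one
    threshold step and AUC is computed by the trapezoid rule.
    ``max_negatives`` uniformly subsamples the negative universe
    (reproducibly via ``rng_seed``) for very large matrices; the
    default keeps every pair.
    """
    scores, labels, _ = _pair_instances(matrix, benchmark)
    if max_negatives is not None and (~labels).sum() > max_negatives:
        neg_idx = np.flatnonzero(~labels)
        rng = np.random.default_rng(rng_seed)
        keep = np.concatenate(
            [
                np.flatnonzero(labels),
                rng.choice(neg_idx, size=max_negatives, replace=False),
            ]
        )
        scores, labels = scores[keep], labels[keep]
    return _roc_from_scores(scores, labels)


@dataclass
class ScoreBin:
    """One score interval of the decile-overlap analysis."""

    low: float
    high: float
    n_pairs: int
    n_positive: int

    @property
    def fraction(self) -> float | None:
        if self.n_pairs == 0:
            return None
        return self.n_positive / self.n_pairs


def decile_overlap(
    matrix: SimilarityMatrix,
    benchmark: BenchmarkPairSet,
    n_intervals: int = 10,
) -> list[ScoreBin]:
    """Positive fraction per equal-width score interval.

    Pairs with nonzero score are binned into ``n_intervals`` equal-width
    intervals over (0, max score]; each bin reports the fraction of its
    pairs that belong to the benchmark (``None`` for empty bins).  A
    rising fraction across bins indicates that higher similarity scores
    are more likely to reflect curated phenotypic overlap.
    """
    if n_intervals < 1:
        raise ValueError("n_intervals must be >= 1")
    scores, labels, _ = _pair_instances(matrix, benchmark)
    mask = scores > 0
    scores, labels = scores[mask], labels[mask]
    if len(scores) == 0:
        return [ScoreBin(0.0, 0.0, 0, 0) for _ in range(n_intervals)]
    top = float(scores.max())
    edges = np.linspace(0.0, top, n_intervals + 1)
    # interval i is (edges[i], edges[i+1]]
    idx = np.clip(np.searchsorted(edges, scores, side="left") - 1, 0, n_intervals - 1)
    bins = []
    for i in range(n_intervals):
        in_bin = idx == i
        bins.append(
            ScoreBin(
                low=float(edges[i]),
                high=float(edges[i + 1]),
                n_pairs=int(in_bin.sum()),
                n_positive=int((labels & in_bin).sum()),
            )
        )
    return bins
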