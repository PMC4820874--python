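"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive (exact integer combinatorics,
O(n^2 v) loops, exhaustive pair enumeration) and shares no code with
the package under test.
"""

from __future__ import annotations

import math
from fractions import Fraction
from itertools import combinations

import sympy


def global_weight_exact(N: int, n_concept: int, precision: int = 30):
    """log2(N / n_concept) evaluated with sympy at high precision."""
    return sympy.log(sympy.Rational(N, n_concept), 2).evalf(precision)


def local_weight_exact(r_concept: int, r_max: int) -> Fraction:
    return Fraction(1, 2) + Fraction(r_concept, 2 * r_max)


def cosine_exact(v1: dict[str, float], v2: dict[str, float]) -> float:
    dot = sum(w * v2[c] for c, w in v1.items() if c in v2)
    n1 = math.sqrt(sum(w * w for w in v1.values()))
    n2 = math.sqrt(sum(w * w for w in v2.values()))
    return dot / (n1 * n2)


def weighted_vectors(
    vectors: dict[str, dict[str, int]], scheme: str
) -> dict[str, dict[str, float]]:
    """Re-derive weighted vectors straight from the printed formulas."""
    N = len(vectors)
    doc_count: dict[str, int] = {}
    for vec in vectors.values():
        for c in vec:
            doc_count[c] = doc_count.get(c, 0) + 1
    out = {}
    for rid, vec in vectors.items():
        r_max = max(vec.values())
        w = {}
        for c, f in vec.items():
            if scheme == "unweighted":
                w[c] = float(f)
            elif scheme == "global":
                w[c] = math.log2(N / doc_count[c])
            elif scheme == "local":
                w[c] = 0.5 + f / (2 * r_max)
            elif scheme == "global_local":
                w[c] = (0.5 + f / (2 * r_max)) * math.log2(N / doc_count[c])
            else:
                raise ValueError(scheme)
        out[rid] = {c: x for c, x in w.items() if x != 0}
    return out


def similarity_matrix_bruteforce(
    vectors: dict[str, dict[str, int]], scheme: str
) -> dict[tuple[str, str], float]:
    """All pairwise cosines (including the diagonal) per the formulas."""
    weighted = {
        rid: v for rid, v in weighted_vectors(vectors, scheme).items() if v
    }
    out = {}
    ids = sorted(weighted)
    for a in ids:
        for b in ids:
            out[(a, b)] = 1.0 if a == b else cosine_exact(weighted[a], weighted[b])
    return out


def hypergeom_tail_fraction(k: int, M: int, K: int, n: int) -> Fraction:
    """Exact P(X >= k), X ~ Hypergeometric(M, K, n), by integer combinatorics."""
    if k <= max(0, K + n - M):
        return Fraction(1)
    hi = min(K, n)
    if k > hi:
        return Fraction(0)
    num = sum(math.comb(K, i) * math.comb(M - K, n - i) for i in range(k, hi + 1))
    return Fraction(num, math.comb(M, n))


def auc_rank_statistic(scores_pos, scores_neg) -> float:
    """AUC as P(pos > neg) + 0.5 * P(pos == neg), by exhaustive enumeration."""
    wins = ties = 0
    for p in scores_pos:
        for q in scores_neg:
            if p > q:
                wins += 1
            elif p == q:
                ties += 1
    return (wins + 0.5 * ties) / (len(scores_pos) * len(scores_neg))


def series_pair_count_bruteforce(series: dict[str, set[str]]) -> int:
    """Deduplicated within-series pair count by explicit enumeration."""
    seen = set()
    for members in series.values():
        for a, b in combinations(sorted(members), 2):
            seen.add((a, b))
    return len(seen)
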