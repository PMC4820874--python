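from __future__ import annotations

import random

import networkx as nx
import pytest
from hypothesis import HealthCheck, settings

import phenosim as ps

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_records(spec: list[tuple[str, str, dict[str, int]]]) -> list[ps.RawRecord]:
    """Build RawRecords from (record_id, prefix, text-concept-freqs) triples."""
    return [
        ps.RawRecord(
            record_id=rid,
            prefix=prefix,
            title=f"DISORDER {rid}",
            title_concepts=(),
            text_concepts=tuple((c, f) for c, f in sorted(concepts.items())),
        )
        for rid, prefix, concepts in spec
    ]


def random_corpus(
    n_records: int, vocab: int, rng: random.Random, max_freq: int = 5
) -> ps.Corpus:
    """A random corpus that satisfies the corpus invariants by construction."""
    while True:
        spec = []
        for i in range(n_records):
            n_concepts = rng.randint(1, max(1, vocab // 2))
            concepts = {
                f"C{rng.randrange(vocab):03d}": rng.randint(1, max_freq)
                for _ in range(n_concepts)
            }
            spec.append((f"{100000 + i}", "#", concepts))
        try:
            return ps.build_corpus(make_records(spec))
        except ps.CorpusError:
            continue


@pytest.fixture
def toy_corpus() -> ps.Corpus:
    """Five records over a small shared vocabulary."""
    return ps.build_corpus(
        make_records(
            [
                ("100001", "#", {"c1": 2, "c2": 1, "c3": 1}),
                ("100002", "#", {"c1": 1, "c2": 3}),
                ("100003", "%", {"c2": 1, "c3": 2, "c4": 1}),
                ("100004", "none", {"c3": 1, "c4": 4}),
                ("100005", "#", {"c1": 1, "c4": 2}),
            ]
        )
    )


@pytest.fixture
def toy_network() -> nx.Graph:
    """12-gene graph: a dense clique of 4 seeds + a well-connected candidate."""
    g = nx.Graph()
    seeds = ["S1", "S2", "S3", "S4"]
    for a, b in [(a, b) for i, a in enumerate(seeds) for b in seeds[i + 1 :]]:
        g.add_edge(a, b)
    g.add_edges_from(
        [
            ("CAND", "S1"),
            ("CAND", "S2"),
            ("CAND", "S3"),
            ("FAR", "B1"),
            ("B1", "B2"),
            ("B2", "B3"),
            ("B3", "B4"),
            ("B4", "B5"),
            ("B5", "S4"),
        ]
    )
    g.add_node("LONER")
    return g
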