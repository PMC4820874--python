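"""Synthetic fixtures with known ground truth for the whole pipeline.

Two generators are provided.

:func:`simulate_corpus` builds a concept-annotated disorder corpus with
planted clusters: each cluster owns a signature of concepts that its
member records carry with high probability, on top of noise concepts
drawn from a smaller shared pool.  Because the noise pool is small,
noise concepts recur across many records — the generic,
high-document-frequency vocabulary that inverse-document-frequency
weighting is designed to discount — while signature concepts stay
cluster-specific.  The planted clusters double as ground truth: a
phenotypic series per cluster and reference links between co-members.

:func:`simulate_disease_module` builds an Erdos-Renyi PPI network with
a densified planted disease module, plus gene-set collections each
containing one set enriched for module genes among random filler sets.
Module genes are split into observed seeds and held-out targets so
ranking performance can be measured against a known answer.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np

from .benchmark import PhenotypicSeries
from .corpus import RawRecord
from .enrichment import GeneSetCollection


@dataclass
class CorpusSimConfig:
    """Parameters of the planted-cluster corpus generator.

    Defaults give 200 records in 20 clusters of 10.  Each cluster's
    signature has 8 concepts carried by members with probability 0.8;
    every record additionally draws 8 noise concepts from the 40-concept
    non-signature pool, so noise concepts are common across clusters
    while signatures are rare.  Frequencies are uniform on 1..freq_max.
    """

    n_records: int = 200
    vocab_size: int = 200
    n_clusters: int = 20
    signature_size: int = 8
    signature_share: float = 0.8
    noise_concepts_per_record: int = 8
    freq_max: int = 5
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_records < 1 or self.vocab_size < 1 or self.n_clusters < 1:
            raise ValueError("n_records, vocab_size and n_clusters must be positive")
        if self.n_clusters * self.signature_size > self.vocab_size:
            raise ValueError("n_clusters * signature_size must not exceed vocab_size")
        if not 0 <= self.signature_share <= 1:
            raise ValueError("signature_share must be in [0, 1]")
        if self.noise_concepts_per_record < 0 or self.freq_max < 1:
            raise ValueError("invalid noise_concepts_per_record or freq_max")
        noise_pool = self.vocab_size - self.n_clusters * self.signature_size
        if self.noise_concepts_per_record > noise_pool:
            raise ValueError("noise_concepts_per_record exceeds the noise pool")


@dataclass
class ModuleSimConfig:
    """Parameters of the planted-disease-module generator.

    Defaults: a 200-gene network with background edge probability 0.02,
    a 20-gene module wired at 0.3, seven collections of 5 sets in which
    one planted set holds 70% of the module genes, and 10 of the 20
    module genes observed as seeds (the rest held out).
    """

    n_genes: int = 200
    module_size: int = 20
    p_in: float = 0.3
    p_out: float = 0.02
    n_collections: int = 7
    sets_per_collection: int = 5
    planted_set_overlap: float = 0.7
    n_seeds_observed: int = 10
    set_size_min: int = 10
    set_size_max: int = 30
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.module_size > self.n_genes:
            raise ValueError("module_size must not exceed n_genes")
        if not (0 <= self.p_out <= self.p_in <= 1):
            raise ValueError("require 0 <= p_out <= p_in <= 1")
        if not 0 <= self.planted_set_overlap <= 1:
            raise ValueError("planted_set_overlap must be in [0, 1]")
        if self.n_seeds_observed > self.module_size:
            raise ValueError("n_seeds_observed must not exceed module_size")
        if self.n_collections < 0 or self.sets_per_collection < 1:
            raise ValueError("invalid collection counts")
        if not 1 <= self.set_size_min <= self.set_size_max <= self.n_genes:
            raise ValueError("invalid set size range")


@dataclass
class CorpusFixture:
    records: list[RawRecord]
    truth_series: PhenotypicSeries
    truth_links: dict[str, set[str]]
    config: CorpusSimConfig


@dataclass
class ModuleFixture:
    network: nx.Graph
    collections: list[GeneSetCollection]
    seeds_observed: list[str]
    seeds_heldout: list[str]
    config: ModuleSimConfig


def simulate_corpus(config: CorpusSimConfig) -> CorpusFixture:
    """Generate a planted-cluster corpus with series and link ground truth.

    Records are assigned to clusters round-robin; each carries its
    cluster's signature concepts (independently with probability
    ``signature_share``) plus noise concepts sampled without
    replacement from the shared pool.  ``truth_series`` groups records
    by cluster; ``truth_links`` gives each record a reference to one
    random co-member.  Deterministic given ``rng_seed``.
    """
    rng = np.random.default_rng(config.rng_seed)
    concepts = [f"C{i:05d}" for i in range(config.vocab_size)]
    n_sig = config.n_clusters * config.signature_size
    signatures = [
        concepts[c * config.signature_size : (c + 1) * config.signature_size]
        for c in range(config.n_clusters)
    ]
    noise_pool = concepts[n_sig:]

    records: list[RawRecord] = []
    clusters: dict[int, list[str]] = {c: [] for c in range(config.n_clusters)}
    for i in range(config.n_records):
        cluster = i % config.n_clusters
        rid = f"{100000 + i}"
        clusters[cluster].append(rid)
        carried = [
            c for c in signatures[cluster] if rng.random() < config.signature_share
        ]
        noise = (
            [str(c) for c in rng.choice(noise_pool, size=config.noise_concepts_per_record, replace=False)]
            if config.noise_concepts_per_record and noise_pool
            else []
        )
        all_concepts = carried + [c for c in noise if c not in carried]
        freqs = rng.integers(1, config.freq_max + 1, size=len(all_concepts))
        pairs = [(c, int(f)) for c, f in zip(all_concepts, freqs)]
        # first carried signature concept doubles as the title concept
        title_part = tuple(pairs[:1]) if carried else ()
        text_part = tuple(pairs[1:]) if carried else tuple(pairs)
        records.append(
            RawRecord(
                record_id=rid,
                prefix="#",
                title=f"SYNTHETIC DISORDER {cluster}, TYPE {i // config.n_clusters + 1}",
                title_concepts=title_part,
                text_concepts=text_part,
            )
        )

    series = PhenotypicSeries(
        series={f"PS{c:03d}": set(members) for c, members in clusters.items() if members}
    )
    links: dict[str, set[str]] = {}
    for members in clusters.values():
        if len(members) < 2:
            continue
        for rid in members:
            co = [m for m in members if m != rid]
            links[rid] = {str(rng.choice(co))}
    records = [
        RawRecord(
            record_id=r.record_id,
            prefix=r.prefix,
            title=r.title,
            title_concepts=r.title_concepts,
            text_concepts=r.text_concepts,
            references=frozenset(links.get(r.record_id, ())),
        )
        for r in records
    ]
    return CorpusFixture(
        records=records, truth_series=series, truth_links=links, config=config
    )


def simulate_disease_module(config: ModuleSimConfig) -> ModuleFixture:
    """Generate a PPI network and collections with a planted disease module.

    Background edges appear with probability ``p_out``; pairs within
    the randomly chosen module are additionally wired at ``p_in``.
    Each collection holds one planted set containing a
    ``planted_set_overlap`` fraction of module genes (padded with
    random genes) plus random filler sets.  Deterministic given
    ``rng_seed``.
    """
    rng = np.random.default_rng(config.rng_seed)
    genes = [f"G{i:04d}" for i in range(config.n_genes)]
    module = sorted(
        str(g) for g in rng.choice(genes, size=config.module_size, replace=False)
    )
    module_set = set(module)

    network = nx.Graph()
    network.add_nodes_from(genes)
    n = config.n_genes
    for i in range(n):
        for j in range(i + 1, n):
            p = (
                config.p_in
                if genes[i] in module_set and genes[j] in module_set
                else config.p_out
            )
            if rng.random() < p:
                network.add_edge(genes[i], genes[j])

    collections: list[GeneSetCollection] = []
    n_planted = int(round(config.planted_set_overlap * config.module_size))
    for c in range(config.n_collections):
        sets: dict[str, frozenset[str]] = {}
        for s in range(config.sets_per_collection):
            size = int(rng.integers(config.set_size_min, config.set_size_max + 1))
            if s == 0 and n_planted > 0:
                core = [
                    str(g) for g in rng.choice(module, size=n_planted, replace=False)
                ]
                pad_pool = [g for g in genes if g not in module_set]
                n_pad = max(size - n_planted, 0)
                pad = [str(g) for g in rng.choice(pad_pool, size=n_pad, replace=False)]
                members = frozenset(core + pad)
                sets[f"SET{c:02d}_PLANTED"] = members
            else:
                members = frozenset(
                    str(g) for g in rng.choice(genes, size=size, replace=False)
                )
                sets[f"SET{c:02d}_{s:02d}"] = members
        collections.append(GeneSetCollection(name=f"collection_{c+1}", sets=sets))

    perm = [str(g) for g in rng.permutation(module)]
    seeds_observed = sorted(perm[: config.n_seeds_observed])
    seeds_heldout = sorted(perm[config.n_seeds_observed :])
    return ModuleFixture(
        network=network,
        collections=collections,
        seeds_observed=seeds_observed,
        seeds_heldout=seeds_heldout,
        config=config,
    )


def _write_records_tsv(records: Sequence[RawRecord], path: Path) -> None:
    def fmt(pairs: Sequence[tuple[str, int]]) -> str:
        return ";".join(f"{c}:{f}" for c, f in pairs)

    with path.open("w", encoding="utf-8") as fh:
        fh.write("record_id\tprefix\ttitle\ttitle_concepts\ttext_concepts\treferences\n")
        for r in records:
            fh.write(
                f"{r.record_id}\t{r.prefix}\t{r.title}\t{fmt(r.title_concepts)}"
                f"\t{fmt(r.text_concepts)}\t{';'.join(sorted(r.references))}\n"
            )


def write_fixture_bundle(
    fixture: CorpusFixture | ModuleFixture, directory: str | Path
) -> list[Path]:
    """Serialize a fixture in the file dialects the other modules read.

    A corpus fixture yields ``records.tsv`` and ``series.tsv``; a
    module fixture yields ``ppi_edges.tsv``, one GMT per collection,
    ``seeds_observed.txt`` and ``seeds_heldout.txt``.  Both include a
    ``manifest.json`` recording the generator config (and its rng
    seed).  Returns the written paths.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    if isinstance(fixture, CorpusFixture):
        p = directory / "records.tsv"
        _write_records_tsv(fixture.records, p)
        written.append(p)
        p = directory / "series.tsv"
        fixture.truth_series.to_tsv(p)
        written.append(p)
        kind = "corpus"
    elif isinstance(fixture, ModuleFixture):
        p = directory / "ppi_edges.tsv"
        with p.open("w", encoding="utf-8") as fh:
            fh.write("# synthetic planted-module PPI network\n")
            for a, b in sorted(tuple(sorted(e)) for e in fixture.network.edges):
                fh.write(f"{a}\t{b}\n")
            for node in sorted(nx.isolates(fixture.network)):
                fh.write(f"{node}\n")
        written.append(p)
        for coll in fixture.collections:
            p = directory / f"{coll.name}.gmt"
            with p.open("w", encoding="utf-8") as fh:
                for sid in sorted(coll.sets):
                    genes = "\t".join(sorted(coll.sets[sid]))
                    fh.write(f"{sid}\tsynthetic\t{genes}\n")
            written.append(p)
        for name, seeds in (
            ("seeds_observed.txt", fixture.seeds_observed),
            ("seeds_heldout.txt", fixture.seeds_heldout),
        ):
            p = directory / name
            p.write_text("\n".join(seeds) + "\n")
            written.append(p)
        kind = "module"
    else:
        raise TypeError(f"unsupported fixture type {type(fixture).__name__}")

    manifest = directory / "manifest.json"
    manifest.write_text(
        json.dumps(
            {"kind": kind, "config": asdict(fixture.config)},
            indent=1,
            sort_keys=True,
        )
    )
    written.append(manifest)
    return written
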