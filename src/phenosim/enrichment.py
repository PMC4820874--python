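"""Fisher's-exact enrichment features over PPI neighborhoods and gene-set collections.

The guilt-by-association signal for a candidate gene is summarized by
eight p-values.  The first treats the gene's protein-protein
interaction (PPI) neighbors as a gene set and asks, by a one-sided
Fisher's exact test, whether the known disease (seed) genes are
over-represented among them.  The remaining seven come from gene-set
collections (MSigDB-style GMT files): each set in a collection is
tested for seed over-representation, and a gene inherits the lowest
p-value among the sets it belongs to, one feature per collection.

The one-sided test is the hypergeometric upper tail: with a universe
of M genes, a set of K, n seeds, and k seeds inside the set,

    p = P(X >= k),  X ~ Hypergeometric(M, K, n).

k = 0 always gives p = 1 (the least extreme observation), and genes
absent from a resource receive the non-informative p = 1 so every
candidate stays rankable.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
from scipy.stats import hypergeom

logger = logging.getLogger(__name__)

#: Number of gene-set collections in a full feature vector (1 PPI + 7).
N_COLLECTION_FEATURES = 7

#: Cap applied to -log10(p) so vanishing p-values stay finite.
NEG_LOG10_CAP = 300.0

#: Smallest representable p, to keep p-values in (0, 1].
_P_FLOOR = 5e-324


@dataclass
class GeneSetCollection:
    """A named collection of gene sets (symbols uppercase-normalized)."""

    name: str
    sets: dict[str, frozenset[str]]

    def __post_init__(self) -> None:
        self.sets = {
            sid: frozenset(g.upper() for g in genes)
            for sid, genes in self.sets.items()
        }
        for sid, genes in self.sets.items():
            if not genes:
                raise ValueError(f"collection {self.name!r}: set {sid!r} is empty")

    def all_genes(self) -> frozenset[str]:
        out: set[str] = set()
        for genes in self.sets.values():
            out |= genes
        return frozenset(out)

    def sets_containing(self, gene: str) -> list[str]:
        g = gene.upper()
        return [sid for sid, genes in self.sets.items() if g in genes]


def read_gmt(path: str | Path, name: str | None = None) -> GeneSetCollection:
    """Read a GMT file: ``set_id<TAB>description<TAB>gene[<TAB>gene...]``.

    Duplicate genes within a set are collapsed; an empty file is an
    error.  ``name`` defaults to the file stem.
    """
    path = Path(path)
    sets: dict[str, frozenset[str]] = {}
    for line_no, line in enumerate(
        path.read_text(encoding="utf-8").splitlines(), start=1
    ):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(
                f"{path.name} line {line_no}: GMT lines need >= 3 fields"
            )
        sid = fields[0]
        genes = frozenset(g.strip().upper() for g in fields[2:] if g.strip())
        if not genes:
            raise ValueError(f"{path.name} line {line_no}: set {sid!r} has no genes")
        sets[sid] = genes
    if not sets:
        raise ValueError(f"{path}: empty gene-set collection")
    return GeneSetCollection(name=name or path.stem, sets=sets)


def read_ppi_edges(path: str | Path) -> nx.Graph:
    """Read an undirected PPI edge list: ``geneA<TAB>geneB``, ``#`` comments.

    Symbols are uppercased; self-loops and duplicate edges are dropped.
    A line with a single gene declares an isolated node.
    """
    g = nx.Graph()
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = [f.strip().upper() for f in line.split("\t") if f.strip()]
        if len(fields) == 1:
            g.add_node(fields[0])
        elif fields[0] != fields[1]:
            g.add_edge(fields[0], fields[1])
    return g


def read_gene_list(path: str | Path) -> list[str]:
    """Read a plain gene list, one symbol per line, uppercased."""
    out = []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            out.append(line.upper())
    return out


@dataclass
class EnrichmentResult:
    """One Fisher's-exact over-representation test.

    ``table`` is the 2x2 contingency (k, K-k, n-k, M-K-n+k): seeds in
    the set, non-seeds in the set, seeds outside, non-seeds outside.
    """

    set_id: str
    p_value: float
    table: tuple[int, int, int, int]


def hypergeometric_tail(k: int, M: int, K: int, n: int) -> float:
    """Upper-tail P(X >= k) for X ~ Hypergeometric(M, K, n), floored into (0, 1]."""
    p = float(hypergeom.sf(k - 1, M, K, n))
    return min(max(p, _P_FLOOR), 1.0)


def fisher_enrichment(
    gene_set: Iterable[str],
    seed_genes: Iterable[str],
    universe: Iterable[str],
    set_id: str = "",
) -> EnrichmentResult:
    """One-sided Fisher's exact test for seed over-representation in a set.

    Genes outside the universe are dropped (with a logged warning when
    any are).  Raises on an empty universe or when no seed survives the
    universe restriction.
    """
    uni = {g.upper() for g in universe}
    if len(uni) < 2:
        raise ValueError("universe must contain at least 2 genes")
    gset = {g.upper() for g in gene_set}
    seeds = {g.upper() for g in seed_genes}
    if not seeds:
        raise ValueError("seed gene list is empty")
    outside = (gset | seeds) - uni
    if outside:
        logger.warning(
            "%d genes outside the universe dropped (e.g. %s)",
            len(outside),
            sorted(outside)[0],
        )
    gset &= uni
    seeds &= uni
    if not seeds:
        raise ValueError("no seed gene belongs to the universe")
    M, K, n = len(uni), len(gset), len(seeds)
    k = len(gset & seeds)
    return EnrichmentResult(
        set_id=set_id,
        p_value=hypergeometric_tail(k, M, K, n),
        table=(k, K - k, n - k, M - K - n + k),
    )


def ppi_feature(
    network: nx.Graph, seed_genes: Iterable[str], gene: str
) -> float:
    """Seed over-representation p-value for a gene's PPI neighborhood.

    The neighbor set (excluding the gene itself) is tested against the
    seeds with the network's node set as universe.  A gene absent from
    the network, or isolated, gets the non-informative p = 1.
    """
    g = gene.upper()
    if g not in network:
        logger.info("gene %s absent from PPI network; feature p = 1", g)
        return 1.0
    neighbors = set(network[g]) - {g}
    if not neighbors:
        return 1.0
    return fisher_enrichment(
        neighbors, seed_genes, network.nodes, set_id=f"ppi:{g}"
    ).p_value


def collection_gsea(
    collection: GeneSetCollection,
    seed_genes: Iterable[str],
    universe: Iterable[str],
) -> list[EnrichmentResult]:
    """Test every set of a collection, sorted ascending by p then set id."""
    seeds = list(seed_genes)
    uni = list(universe)
    results = [
        fisher_enrichment(genes, seeds, uni, set_id=sid)
        for sid, genes in collection.sets.items()
    ]
    results.sort(key=lambda r: (r.p_value, r.set_id))
    return results


def gene_collection_feature(
    results: Sequence[EnrichmentResult],
    collection: GeneSetCollection,
    gene: str,
) -> float:
    """Lowest enrichment p among the collection's sets containing ``gene``.

    Returns 1.0 when the gene belongs to no set of the collection.
    """
    member = set(collection.sets_containing(gene))
    ps = [r.p_value for r in results if r.set_id in member]
    return min(ps) if ps else 1.0


@dataclass
class FeatureMatrix:
    """Gene x 8 matrix of enrichment-derived features.

    Raw p-values are always stored; :meth:`values` applies the
    configured transform (``neg_log10_p`` maps p to min(-log10 p, 300),
    which conditions the features for margin classifiers).
    """

    genes: list[str]
    pvalues: np.ndarray  # (n_genes, 8) raw p in (0, 1]
    transform: str = "neg_log10_p"
    columns: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.pvalues = np.asarray(self.pvalues, dtype=float)
        if self.pvalues.ndim != 2 or self.pvalues.shape[1] != 1 + N_COLLECTION_FEATURES:
            raise ValueError(
                f"feature matrix must have {1 + N_COLLECTION_FEATURES} columns"
            )
        if self.transform not in ("raw_p", "neg_log10_p"):
            raise ValueError(f"unknown transform {self.transform!r}")
        if not self.columns:
            self.columns = ("ppi",) + tuple(
                f"collection_{i+1}" for i in range(N_COLLECTION_FEATURES)
            )
        self._index = {g: i for i, g in enumerate(self.genes)}

    def __contains__(self, gene: str) -> bool:
        return gene.upper() in self._index

    def row(self, gene: str) -> np.ndarray:
        """Raw p-value row for one gene."""
        return self.pvalues[self._index[gene.upper()]]

    def values(self) -> np.ndarray:
        if self.transform == "raw_p":
            return self.pvalues.copy()
        return np.minimum(-np.log10(self.pvalues), NEG_LOG10_CAP)

    def subset(self, genes: Iterable[str]) -> np.ndarray:
        """Transformed feature rows for the given genes, in order."""
        idx = [self._index[g.upper()] for g in genes]
        return self.values()[idx]

    def to_tsv(self, path: str | Path) -> None:
        with Path(path).open("w", encoding="utf-8") as fh:
            fh.write("gene\t" + "\t".join(self.columns) + "\n")
            for g, row in zip(self.genes, self.pvalues):
                fh.write(g + "\t" + "\t".join(f"{p:.12g}" for p in row) + "\n")

    @classmethod
    def from_tsv(cls, path: str | Path, transform: str = "neg_log10_p") -> "FeatureMatrix":
        genes, rows = [], []
        with Path(path).open(encoding="utf-8") as fh:
            header = fh.readline().rstrip("\n").split("\t")
            for line in fh:
                fields = line.rstrip("\n").split("\t")
                genes.append(fields[0])
                rows.append([float(x) for x in fields[1:]])
        return cls(
            genes=genes,
            pvalues=np.asarray(rows),
            transform=transform,
            columns=tuple(header[1:]),
        )


def build_feature_matrix(
    network: nx.Graph,
    collections: Sequence[GeneSetCollection],
    seed_genes: Iterable[str],
    candidates: Sequence[str],
    transform: str = "neg_log10_p",
    allow_fewer_collections: bool = False,
) -> FeatureMatrix:
    """Assemble the 8-dimensional feature matrix for a list of genes.

    Column 1 is the PPI-neighborhood p-value; columns 2-8 are the
    per-collection lowest-set p-values.  The universe for the PPI test
    is the network node set; for each collection it is the union of the
    collection's genes and the seeds.  With fewer than 7 collections
    (requires ``allow_fewer_collections``) the missing features are
    padded at p = 1.
    """
    if len(collections) > N_COLLECTION_FEATURES:
        raise ValueError(f"at most {N_COLLECTION_FEATURES} collections supported")
    if len(collections) < N_COLLECTION_FEATURES and not allow_fewer_collections:
        raise ValueError(
            f"expected {N_COLLECTION_FEATURES} collections, got {len(collections)}; "
            "pass allow_fewer_collections=True to pad missing features at p = 1"
        )
    seeds = {g.upper() for g in seed_genes}
    genes: list[str] = []
    seen: set[str] = set()
    for g in candidates:
        gu = g.upper()
        if gu in seen:
            logger.warning("duplicate candidate %s ignored", gu)
            continue
        seen.add(gu)
        genes.append(gu)

    pvals = np.ones((len(genes), 1 + N_COLLECTION_FEATURES))
    for i, g in enumerate(genes):
        pvals[i, 0] = ppi_feature(network, seeds, g)
    columns = ["ppi"]
    for j in range(N_COLLECTION_FEATURES):
        if j < len(collections):
            coll = collections[j]
            columns.append(coll.name)
            universe = coll.all_genes() | seeds
            results = collection_gsea(coll, seeds, universe)
            by_set = {r.set_id: r.p_value for r in results}
            for i, g in enumerate(genes):
                ps = [by_set[sid] for sid in coll.sets_containing(g)]
                pvals[i, 1 + j] = min(ps) if ps else 1.0
        else:
            columns.append(f"pad_{j+1}")
    return FeatureMatrix(
        genes=genes, pvalues=pvals, transform=transform, columns=tuple(columns)
    )
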