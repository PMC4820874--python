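"""SVM ranking of candidate disease genes from enrichment features.

Known disease-associated genes (the seeds) are the positive training
class; an equal-sized random sample of non-seed genes is the negative
class.  Seeds whose entire feature row is non-significant carry no
guilt-by-association signal and are pruned from the core training set
before fitting.  A support vector machine is trained on the
standardized 8-dimensional features and every candidate gene is ranked
by its decision score.

A validation-set filter is provided for benchmarking: a putative
disease gene whose PPI neighborhood is more enriched for *non*-seed
genes than for seeds is a likely false positive and can be removed
before computing a validation ROC.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import yaml
from sklearn.svm import SVC

from .benchmark import ROCResult, _roc_from_scores
from .enrichment import FeatureMatrix, fisher_enrichment

logger = logging.getLogger(__name__)


@dataclass
class TrainingConfig:
    """Hyperparameters of the candidate-ranking SVM.

    negative_multiplier
        |negatives| = round(multiplier * |positives|); 1.0 keeps the
        classes balanced.
    kernel, regularization
        Passed to the SVM ("linear" or "rbf"; C > 0).
    rng_seed
        Seeds negative sampling and the learner.
    prune_alpha
        Significance level below which a raw feature p-value counts as
        informative when pruning seeds.
    """

    negative_multiplier: float = 1.0
    kernel: str = "linear"
    regularization: float = 1.0
    rng_seed: int = 0
    prune_alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.negative_multiplier <= 0:
            raise ValueError("negative_multiplier must be positive")
        if self.kernel not in ("linear", "rbf"):
            raise ValueError(f"kernel must be 'linear' or 'rbf', got {self.kernel!r}")
        if self.regularization <= 0:
            raise ValueError("regularization must be positive")
        if not 0 < self.prune_alpha <= 1:
            raise ValueError("prune_alpha must be in (0, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "TrainingConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)


@dataclass
class RankedGene:
    gene: str
    decision_score: float
    rank: int
    in_training: bool = False


@dataclass
class RankedGeneList:
    """Candidate genes ordered by descending SVM decision score.

    Ties are broken by ascending gene symbol; ranks are 1..n.
    """

    entries: list[RankedGene]

    def __len__(self) -> int:
        return len(self.entries)

    def genes(self) -> list[str]:
        return [e.gene for e in self.entries]

    def to_tsv(self, path: str | Path) -> None:
        with Path(path).open("w", encoding="utf-8") as fh:
            fh.write("rank\tgene\tdecision_score\tin_training\n")
            for e in self.entries:
                fh.write(
                    f"{e.rank}\t{e.gene}\t{e.decision_score:.12g}"
                    f"\t{str(e.in_training).lower()}\n"
                )


def prune_uninformative_seeds(
    features: FeatureMatrix, seeds: Iterable[str], alpha: float = 0.05
) -> tuple[set[str], set[str]]:
    """Split seeds into a core set and the uninformative remainder.

    A seed is retained iff at least one of its eight raw p-values is
    below ``alpha``; seeds with an all-non-significant row carry no
    signal for the learner.  Raises if every seed would be pruned.
    """
    core, removed = set(), set()
    for gene in {g.upper() for g in seeds}:
        if gene not in features:
            raise KeyError(f"seed {gene!r} has no feature row")
        # alpha = 1 is the keep-everything boundary: p-values never exceed 1
        if alpha >= 1.0 or float(features.row(gene).min()) < alpha:
            core.add(gene)
        else:
            removed.add(gene)
    if not core:
        raise ValueError(
            "all seed genes were pruned as uninformative; "
            "consider a larger disorder group"
        )
    return core, removed


def sample_negatives(
    universe: Iterable[str], seeds: Iterable[str], n: int, rng_seed: int
) -> set[str]:
    """Uniform sample of ``n`` non-seed genes, reproducible given the seed."""
    pool = sorted({g.upper() for g in universe} - {g.upper() for g in seeds})
    if n < 1:
        raise ValueError("n must be >= 1")
    if len(pool) < n:
        raise ValueError(f"only {len(pool)} non-seed genes available, need {n}")
    rng = np.random.default_rng(rng_seed)
    return {str(g) for g in rng.choice(pool, size=n, replace=False)}


def train_and_rank(
    features: FeatureMatrix,
    core_seeds: Iterable[str],
    negatives: Iterable[str],
    candidates: Sequence[str],
    config: TrainingConfig | None = None,
    score_train: bool = False,
) -> RankedGeneList:
    """Fit the SVM and rank candidates by decision score.

    Features are standardized per column with training-set mean and
    standard deviation.  Training genes found among the candidates are
    dropped (unless ``score_train``); output is deterministic given the
    inputs and config.
    """
    config = config or TrainingConfig()
    pos = sorted({g.upper() for g in core_seeds})
    neg = sorted({g.upper() for g in negatives})
    if not pos or not neg:
        raise ValueError("training requires both positive and negative genes")
    if set(pos) & set(neg):
        raise ValueError("core seeds and negatives overlap")
    training = set(pos) | set(neg)

    ranked_genes: list[str] = []
    seen: set[str] = set()
    for g in candidates:
        gu = g.upper()
        if gu in seen:
            continue
        if gu in training and not score_train:
            logger.info("candidate %s is a training gene; skipped", gu)
            continue
        seen.add(gu)
        ranked_genes.append(gu)

    X_train = np.vstack([features.subset(pos), features.subset(neg)])
    y_train = np.concatenate([np.ones(len(pos)), np.zeros(len(neg))])
    mu = X_train.mean(axis=0)
    sd = X_train.std(axis=0)
    sd[sd == 0] = 1.0

    clf = SVC(
        kernel=config.kernel,
        C=config.regularization,
        random_state=config.rng_seed,
    )
    clf.fit((X_train - mu) / sd, y_train)

    if not ranked_genes:
        return RankedGeneList(entries=[])
    X_cand = (features.subset(ranked_genes) - mu) / sd
    scores = clf.decision_function(X_cand)
    order = sorted(range(len(ranked_genes)), key=lambda i: (-scores[i], ranked_genes[i]))
    entries = [
        RankedGene(
            gene=ranked_genes[i],
            decision_score=float(scores[i]),
            rank=r + 1,
            in_training=ranked_genes[i] in training,
        )
        for r, i in enumerate(order)
    ]
    return RankedGeneList(entries=entries)


def run_prioritization(
    features: FeatureMatrix,
    seeds: Iterable[str],
    config: TrainingConfig | None = None,
    candidates: Sequence[str] | None = None,
    n_bags: int = 1,
) -> RankedGeneList:
    """End-to-end ranking: prune seeds, sample negatives, train, rank.

    Candidates default to every gene in the feature matrix outside the
    training set.  When pruning would remove every seed (no gene
    carries enrichment signal) the full seed set is used instead, with
    a warning — a ranking is still produced, it is just uninformative.
    ``n_bags > 1`` averages decision scores over that many independent
    negative resamples, damping negative-sampling noise.
    """
    config = config or TrainingConfig()
    seeds_u = {g.upper() for g in seeds}
    try:
        core, removed = prune_uninformative_seeds(features, seeds_u, config.prune_alpha)
    except ValueError:
        logger.warning(
            "all %d seeds are uninformative at alpha=%g; training on all of them",
            len(seeds_u),
            config.prune_alpha,
        )
        core, removed = set(seeds_u), set()
    if n_bags < 1:
        raise ValueError("n_bags must be >= 1")
    n_neg = max(1, round(config.negative_multiplier * len(core)))
    bag_negatives = [
        sample_negatives(features.genes, seeds_u, n_neg, config.rng_seed + b)
        for b in range(n_bags)
    ]
    if candidates is None:
        training = seeds_u.union(*bag_negatives)
        candidates = [g for g in features.genes if g not in training]
    rankings = [
        train_and_rank(features, core, negs, candidates, config)
        for negs in bag_negatives
    ]
    if n_bags == 1:
        return rankings[0]
    # average decision scores over bags; genes scored in every bag only
    common = set(rankings[0].genes())
    for r in rankings[1:]:
        common &= set(r.genes())
    mean_score = {
        g: sum(
            next(e.decision_score for e in r.entries if e.gene == g)
            for r in rankings
        )
        / n_bags
        for g in common
    }
    ordered = sorted(mean_score, key=lambda g: (-mean_score[g], g))
    return RankedGeneList(
        entries=[
            RankedGene(gene=g, decision_score=mean_score[g], rank=i + 1)
            for i, g in enumerate(ordered)
        ]
    )


def filter_validation_genes(
    network: nx.Graph,
    seeds: Iterable[str],
    validation: Iterable[str],
) -> tuple[set[str], set[str]]:
    """Drop validation genes more PPI-linked to non-seeds than to seeds.

    For each validation gene, its neighbor set is tested for
    over-representation of the seeds (p_in) and of all other genes
    (p_out); the gene is removed iff p_out < p_in — its interactions
    point away from the disease module, marking a probable false
    positive.  Genes absent from the network, or isolated, are kept
    with a warning.
    """
    seeds_u = {g.upper() for g in seeds}
    nodes = {str(g).upper() for g in network.nodes}
    kept, removed = set(), set()
    for gene in {g.upper() for g in validation}:
        if gene not in nodes:
            logger.warning("validation gene %s absent from network; kept", gene)
            kept.add(gene)
            continue
        neighbors = set(network[gene]) - {gene}
        if not neighbors:
            logger.warning("validation gene %s isolated; kept", gene)
            kept.add(gene)
            continue
        outsiders = nodes - seeds_u - {gene}
        p_in = fisher_enrichment(neighbors, seeds_u, nodes).p_value
        p_out = fisher_enrichment(neighbors, outsiders, nodes).p_value
        if p_out < p_in:
            removed.add(gene)
        else:
            kept.add(gene)
    return kept, removed


def evaluate_ranking(ranking: RankedGeneList, truth: Iterable[str]) -> ROCResult:
    """ROC/AUC of a ranked gene list against a truth set of positives."""
    truth_u = {g.upper() for g in truth}
    scores = np.array([e.decision_score for e in ranking.entries])
    labels = np.array([e.gene in truth_u for e in ranking.entries])
    return _roc_from_scores(scores, labels)
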