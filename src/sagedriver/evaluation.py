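"""Evaluation protocol: K-fold splits, top-K precision/recall/F1 against a
known-driver reference, randomized-network negative controls, and
cross-network top-K overlap analysis.

The negative controls probe whether performance depends on real biology:
``edge_shuffle`` rewires interactions while preserving every node's degree
(double-edge swaps), and ``node_shuffle`` permutes gene labels on an intact
topology, breaking the correspondence between genes and their network
neighborhoods.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .preprocess import PPINetwork

logger = logging.getLogger(__name__)

__all__ = [
    "FoldSplit",
    "TopKMetrics",
    "OverlapResult",
    "kfold_split",
    "topk_metrics",
    "edge_shuffle",
    "node_shuffle",
    "topk_overlap",
]


@dataclass
class FoldSplit:
    """Mutually exclusive, jointly exhaustive sample partitions."""

    folds: list[list[str]]

    def __post_init__(self) -> None:
        flat = [s for f in self.folds for s in f]
        if len(flat) != len(set(flat)):
            raise ValueError("folds must be mutually exclusive")
        sizes = [len(f) for f in self.folds]
        if max(sizes) - min(sizes) > 1:
            raise ValueError("fold sizes must differ by at most 1")

    def __len__(self) -> int:
        return len(self.folds)

    def __iter__(self):
        return iter(self.folds)


@dataclass
class TopKMetrics:
    K: int
    precision: float
    recall: float
    f1: float


def kfold_split(
    sample_ids: Sequence[str], k: int = 5, seed: int = 0
) -> FoldSplit:
    """Seeded shuffle followed by contiguous chunking into k folds.

    With n = qk + r samples, the first r folds get q + 1 samples each.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > len(sample_ids):
        raise ValueError("k exceeds the number of samples")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(sample_ids))
    shuffled = [sample_ids[i] for i in order]
    folds = [list(chunk) for chunk in np.array_split(np.array(shuffled, dtype=object), k)]
    return FoldSplit(folds=folds)


def topk_metrics(
    ranking: Sequence[str], truth: set[str] | frozenset[str], K: int
) -> TopKMetrics:
    """Precision/recall/F1 of the first K ranked genes against the truth set."""
    if K < 1:
        raise ValueError("K must be >= 1")
    if not truth:
        raise ValueError("truth set is empty")
    if K > len(ranking):
        warnings.warn(
            f"K={K} exceeds ranking length {len(ranking)}; evaluating the full list",
            stacklevel=2,
        )
        K = len(ranking)
    hits = len(set(ranking[:K]) & set(truth))
    precision = hits / K
    recall = hits / len(truth)
    f1 = 2 * precision * recall / (precision + recall) if precision + recall > 0 else 0.0
    return TopKMetrics(K=K, precision=precision, recall=recall, f1=f1)


def edge_shuffle(ppi: PPINetwork, n_swaps: int, seed: int = 0) -> PPINetwork:
    """Degree-preserving rewiring by double-edge swaps.

    Each swap replaces edges (a, b), (c, d) with (a, d), (c, b), carrying
    the confidences along; swaps that would create self-loops or duplicate
    edges are rejected. The degree of every individual node is unchanged.
    """
    edges = ppi.edges()
    if len(edges) < 2:
        raise ValueError("need at least 2 edges to swap")
    rng = np.random.default_rng(seed)
    edge_set = {frozenset((u, v)) for u, v, _ in edges}
    edges = [(u, v, c) for u, v, c in edges]
    performed, tries = 0, 0
    max_tries = 100 * max(n_swaps, 1)
    while performed < n_swaps and tries < max_tries:
        tries += 1
        i, j = rng.integers(0, len(edges), size=2)
        if i == j:
            continue
        a, b, c1 = edges[i]
        c, d, c2 = edges[j]
        if rng.random() < 0.5:
            a, b = b, a
        new1, new2 = frozenset((a, d)), frozenset((c, b))
        if len(new1) < 2 or len(new2) < 2 or new1 == new2:
            continue  # self-loop or coincident pair
        if new1 in edge_set or new2 in edge_set:
            continue
        edge_set.discard(frozenset((a, b)))
        edge_set.discard(frozenset((c, d)))
        edge_set.update((new1, new2))
        edges[i] = (a, d, c1)
        edges[j] = (c, b, c2)
        performed += 1
    if performed < n_swaps:
        logger.warning("edge_shuffle: performed %d of %d swaps", performed, n_swaps)
    return PPINetwork.from_edges(edges)


def node_shuffle(ppi: PPINetwork, seed: int = 0) -> PPINetwork:
    """Permute gene labels on the intact topology.

    The degree multiset (and the whole graph up to isomorphism) is
    preserved while each gene's own neighborhood is scrambled. For networks
    with more than one node the drawn permutation is redrawn until at least
    one label moves.
    """
    nodes = sorted(ppi.nodes())
    rng = np.random.default_rng(seed)
    perm = list(rng.permutation(len(nodes)))
    while len(nodes) > 1 and all(p == i for i, p in enumerate(perm)):
        perm = list(rng.permutation(len(nodes)))
    mapping = {nodes[i]: nodes[p] for i, p in enumerate(perm)}
    return PPINetwork.from_edges(
        (mapping[u], mapping[v], c) for u, v, c in ppi.edges()
    )


@dataclass
class OverlapResult:
    """Common top-K intersection plus Venn-region counts.

    ``region_counts`` maps each nonempty subset of ranking names (as a
    sorted tuple) to the number of genes whose top-K membership is exactly
    that subset.
    """

    intersection: set[str]
    region_counts: dict[tuple[str, ...], int]

    def subset_size(self, names: Sequence[str]) -> int:
        """Number of genes in the top-K of *all* the given rankings."""
        want = set(names)
        return sum(
            c for region, c in self.region_counts.items() if want <= set(region)
        )


def topk_overlap(
    rankings: Mapping[str, Sequence[str]], K: int = 100
) -> OverlapResult:
    """Venn analysis of the top-K genes of several rankings."""
    if len(rankings) < 2:
        raise ValueError("need at least two rankings to overlap")
    tops: dict[str, set[str]] = {}
    for name, ranking in rankings.items():
        if len(ranking) < K:
            warnings.warn(
                f"ranking {name!r} shorter than K={K}; using the full list",
                stacklevel=2,
            )
        tops[name] = set(ranking[:K])
    names = sorted(tops)
    all_genes = set().union(*tops.values())
    region_counts: dict[tuple[str, ...], int] = {}
    for gene in all_genes:
        region = tuple(n for n in names if gene in tops[n])
        region_counts[region] = region_counts.get(region, 0) + 1
    intersection = set.intersection(*tops.values())
    return OverlapResult(intersection=intersection, region_counts=region_counts)
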