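"""Rank aggregation: per-sample candidate driver lists and cohort-level
Exponential Pairwise Voting (EPV).

For each sample, genes mutated in that sample are ranked by their predicted
driver probability and the top half form the sample's candidate list. EPV
then runs pairwise contests over all ordered gene pairs: in each sample, a
listed gene beats every gene it outranks and every gene absent from that
sample's list, casting a vote whose strength decays exponentially with its
rank, w_s(g) = exp(-alpha (r_s(g) - 1)). A gene's final score is
P = win / (win + loss), the share of contest strength it wins. Classic
Condorcet aggregation (unit-strength votes, equivalent to alpha = 0) is
provided as the ablation baseline.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .decoder import ScoreMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "SampleRanking",
    "EPVResult",
    "build_sample_rankings",
    "rank_weight",
    "epv_scores",
    "condorcet_rank",
]

#: Cancer-type-specific exponential decay defaults from cohort calibration.
ALPHA_DEFAULTS = {"BRCA": 0.9, "LUAD": 0.3, "PRAD": 0.6}
ALPHA_FALLBACK = 0.5


@dataclass
class SampleRanking:
    """One sample's candidate driver list, best first (rank 1)."""

    sample: str
    genes: list[str]
    scores: list[float]

    def __post_init__(self) -> None:
        if len(self.genes) != len(set(self.genes)):
            raise ValueError(f"duplicate genes in ranking for sample {self.sample}")
        if len(self.scores) != len(self.genes):
            raise ValueError("scores must align with genes")

    def rank_of(self, gene: str) -> Optional[int]:
        try:
            return self.genes.index(gene) + 1
        except ValueError:
            return None


@dataclass
class EPVResult:
    """Cohort ranking with per-gene win/loss strengths and P scores."""

    table: pd.DataFrame  # columns: gene, p, win, loss; sorted best first

    @property
    def genes(self) -> list[str]:
        return list(self.table["gene"])

    def score_of(self, gene: str) -> float:
        row = self.table.loc[self.table["gene"] == gene, "p"]
        return float(row.iloc[0]) if len(row) else 0.0

    def write_tsv(self, path) -> None:
        out = self.table.copy()
        out.insert(0, "rank", np.arange(1, len(out) + 1))
        out.to_csv(path, sep="\t", index=False)


def build_sample_rankings(
    scores: ScoreMatrix,
    mutation: np.ndarray,
    keep_fraction: float = 0.5,
) -> list[SampleRanking]:
    """Per-sample candidate lists: mutated genes ranked by predicted score.

    Only genes mutated in the sample are eligible; they are sorted by score
    descending (ties broken by gene symbol ascending) and the top
    ``ceil(keep_fraction * m)`` survive, so a sample with a single mutated
    gene still contributes. Samples with no mutated genes yield an empty
    list (logged, not fatal).
    """
    if not 0 < keep_fraction <= 1:
        raise ValueError("keep_fraction must be in (0, 1]")
    mutation = np.asarray(mutation)
    if mutation.shape != scores.values.shape:
        raise ValueError("score and mutation matrices must share index maps")
    rankings: list[SampleRanking] = []
    for j, sample in enumerate(scores.samples):
        mutated = [
            (scores.genes[i], float(scores.values[i, j]))
            for i in np.flatnonzero(mutation[:, j])
        ]
        if not mutated:
            logger.info("sample %s has no mutated genes; empty candidate list", sample)
            rankings.append(SampleRanking(sample=sample, genes=[], scores=[]))
            continue
        mutated.sort(key=lambda gs: (-gs[1], gs[0]))
        keep = math.ceil(keep_fraction * len(mutated))
        kept = mutated[:keep]
        rankings.append(
            SampleRanking(
                sample=sample,
                genes=[g for g, _ in kept],
                scores=[s for _, s in kept],
            )
        )
    return rankings


def rank_weight(r: int, alpha: float) -> float:
    """Exponentially decaying vote strength of rank r: exp(-alpha (r - 1))."""
    if r < 1:
        raise ValueError("ranks count from 1")
    if alpha < 0:
        raise ValueError("alpha must be nonnegative")
    return math.exp(-alpha * (r - 1))


def _resolve_universe(
    rankings: Sequence[SampleRanking], universe: Optional[Iterable[str]]
) -> list[str]:
    seen: set[str] = set()
    for r in rankings:
        seen.update(r.genes)
    if universe is None:
        return sorted(seen)
    uni = set(universe)
    if not seen <= uni:
        raise ValueError("universe must contain every gene appearing in a ranking")
    return sorted(uni)


def epv_scores(
    rankings: Sequence[SampleRanking],
    alpha: float,
    universe: Optional[Iterable[str]] = None,
) -> EPVResult:
    """Exponential pairwise voting over all ordered gene pairs and samples.

    For every ordered pair (gi, gj) and sample s, gi earns w_s(gi) if gi is
    listed in s and either outranks gj or gj is unlisted. win/loss are the
    sums of strengths earned for/against each gene; P = win / (win + loss)
    with P = 0 for genes that never enter a contest. The default universe
    is every gene appearing in at least one candidate list; pass an
    explicit ``universe`` (e.g. all retained genes) to widen it.

    The implementation aggregates prefix sums per list rather than
    materializing the G^2 x N contests, but is exactly equivalent to the
    brute-force enumeration.
    """
    genes = _resolve_universe(rankings, universe)
    if not genes or all(len(r.genes) == 0 for r in rankings):
        raise ValueError("no candidate genes appear in any sample ranking")
    idx = {g: i for i, g in enumerate(genes)}
    U = len(genes)
    win = np.zeros(U)
    loss = np.zeros(U)
    for r in rankings:
        m = len(r.genes)
        if m == 0:
            continue
        w = np.array([rank_weight(k + 1, alpha) for k in range(m)])
        total = w.sum()
        # every gene (listed or not) provisionally loses to the whole list...
        loss += total
        prefix = np.concatenate(([0.0], np.cumsum(w)[:-1]))
        for k, g in enumerate(r.genes):
            gi = idx[g]
            # ...listed genes only lose to the genes ranked above them
            loss[gi] += prefix[k] - total
            # wins: lower-ranked listed genes plus all unlisted genes
            win[gi] += w[k] * ((m - 1 - k) + (U - m))
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(win + loss > 0, win / (win + loss), 0.0)
    table = pd.DataFrame({"gene": genes, "p": p, "win": win, "loss": loss})
    table = table.sort_values(
        by=["p", "win", "gene"], ascending=[False, False, True], kind="mergesort"
    ).reset_index(drop=True)
    return EPVResult(table=table)


def condorcet_rank(
    rankings: Sequence[SampleRanking],
    universe: Optional[Iterable[str]] = None,
) -> list[str]:
    """Classic pairwise voting baseline with unit vote strength.

    Every ordered pair of universe genes is contested in every sample: a
    listed gene scores one win against each gene it outranks and each
    unlisted gene. Genes are ordered by their Copeland-style win
    proportion win / (win + loss); ties break by win strength then symbol.
    Equivalent to :func:`epv_scores` at alpha = 0, but computed by direct
    pair enumeration (and therefore also serving as its cross-check).
    """
    genes = _resolve_universe(rankings, universe)
    if not genes or all(len(r.genes) == 0 for r in rankings):
        raise ValueError("no candidate genes appear in any sample ranking")
    idx = {g: i for i, g in enumerate(genes)}
    U = len(genes)
    win = np.zeros(U)
    loss = np.zeros(U)
    for r in rankings:
        ranks = {g: k + 1 for k, g in enumerate(r.genes)}
        for gi in genes:
            ri = ranks.get(gi)
            if ri is None:
                continue
            for gj in genes:
                if gj == gi:
                    continue
                rj = ranks.get(gj)
                if rj is None or ri < rj:
                    win[idx[gi]] += 1.0
                    loss[idx[gj]] += 1.0
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(win + loss > 0, win / (win + loss), 0.0)
    order = sorted(range(U), key=lambda i: (-p[i], -win[i], genes[i]))
    return [genes[i] for i in order]
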