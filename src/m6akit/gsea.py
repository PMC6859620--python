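"""Gene-set enrichment analysis with a built-in hypoxia metagene signature.

The statistic is the classic weighted Kolmogorov-Smirnov running sum:
walking down a ranked gene list, set members ("hits") increment the sum by
|score|^p normalised over the set's scores, non-members decrement it by
1/(N - N_hits); the enrichment score (ES) is the running-sum value of
largest magnitude.  Significance comes from a gene-label permutation null
(size-matched random sets), with NES the ES scaled by the mean magnitude
of same-sign null scores and a +1-corrected permutation p-value.

The built-in gene set is the 14-gene hypoxia metagene signature
(Winter et al. consensus hypoxia markers) used to score tumor-vs-paratumor
expression rankings.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

HYPOXIA_SIGNATURE_GENES = frozenset({
    "ALDOA", "MIF", "TUBB6", "P4HA1", "SLC2A1", "PGAM1", "ENO1",
    "LDHA", "CDKN3", "TPI1", "NDRG1", "VEGFA", "ACOT7", "ADM",
})


@dataclass(frozen=True)
class GeneSet:
    name: str
    members: frozenset

    def __post_init__(self):
        if not self.members:
            raise ValueError("gene set must be non-empty")


@dataclass(frozen=True)
class RankedGeneList:
    """Genes ordered by a ranking score, descending."""

    genes: tuple
    scores: np.ndarray

    def __post_init__(self):
        genes = tuple(self.genes)
        scores = np.asarray(self.scores, dtype=float)
        if len(genes) != scores.size:
            raise ValueError("genes and scores must align")
        if len(set(genes)) != len(genes):
            raise ValueError("ranked gene ids must be unique")
        if np.any(np.diff(scores) > 0):
            raise ValueError("scores must be sorted non-increasing")
        object.__setattr__(self, "genes", genes)
        object.__setattr__(self, "scores", scores)

    def __len__(self) -> int:
        return len(self.genes)

    @classmethod
    def from_scores(cls, scores: Mapping[str, float]) -> "RankedGeneList":
        """Build a ranked list from a gene -> score mapping (stable sort)."""
        items = sorted(scores.items(), key=lambda kv: -kv[1])
        return cls(genes=tuple(g for g, _ in items),
                   scores=np.array([v for _, v in items]))


@dataclass(frozen=True)
class EnrichmentResult:
    es: float
    nes: float
    p_value: float
    n_permutations: int
    seed: int
    n_hits: int


def load_hypoxia_signature() -> GeneSet:
    """The 14-gene hypoxia metagene signature as a built-in gene set."""
    return GeneSet(name="HYPOXIA_METAGENE_14", members=HYPOXIA_SIGNATURE_GENES)


def _es_from_hits(hit_idx: np.ndarray, hit_weights: np.ndarray, n: int) -> float:
    """ES from sorted hit positions without materialising the running sum.

    Between hits the sum decreases linearly, so extrema can only occur at
    a hit (just after the increment) or just before the next hit.
    """
    n_hits = hit_idx.size
    n_miss = n - n_hits
    if n_miss == 0:
        return 1.0
    miss_step = 1.0 / n_miss
    cum_hits = np.cumsum(hit_weights)
    # value right after processing hit j at position i: cum_hits[j] - (misses so far)*step
    misses_before = hit_idx + 1 - np.arange(1, n_hits + 1)
    at_hit = cum_hits - misses_before * miss_step
    # value just before each hit (all misses up to that position, previous hits)
    before_hit = np.concatenate(([0.0], cum_hits[:-1])) - misses_before * miss_step
    candidates = np.concatenate((at_hit, before_hit, [0.0]))
    return float(candidates[np.argmax(np.abs(candidates))])


def enrichment_score(
    ranked: RankedGeneList,
    gene_set: GeneSet,
    weight_p: float = 1.0,
) -> tuple[float, np.ndarray]:
    """Weighted running-sum enrichment score and the full running sum.

    Hits increment by |score|^p normalised over the set's hit scores;
    misses decrement by 1/(N - N_hits).  The ES is the running-sum value
    of maximum magnitude (first occurrence on ties).
    """
    n = len(ranked)
    hit_mask = np.fromiter((g in gene_set.members for g in ranked.genes),
                           dtype=bool, count=n)
    n_hits = int(hit_mask.sum())
    if n_hits == 0:
        raise ValueError("gene set has no overlap with the ranked list")
    if n_hits < len(gene_set.members):
        log.warning("gene set %s: only %d of %d members present in the ranking",
                    gene_set.name, n_hits, len(gene_set.members))
    w = np.abs(ranked.scores) ** weight_p
    denom = w[hit_mask].sum()
    if denom == 0:
        raise ValueError("all hit scores are zero; weighted ES undefined")
    steps = np.where(hit_mask, w / denom, 0.0)
    if n_hits < n:
        steps = steps - np.where(hit_mask, 0.0, 1.0 / (n - n_hits))
    running = np.cumsum(steps)
    es = float(running[np.argmax(np.abs(running))])
    return es, running


def nes_and_pvalue(
    ranked: RankedGeneList,
    gene_set: GeneSet,
    n_permutations: int = 1000,
    seed: int = 0,
    weight_p: float = 1.0,
) -> EnrichmentResult:
    """Permutation NES and p-value by size-matched gene-label resampling.

    Null ES values come from random gene sets of the same effective size
    drawn from the ranked list.  NES = ES / mean(|null ES|) over nulls of
    the same sign (sign preserved); p = (1 + #{same-sign nulls at least as
    extreme}) / (1 + #same-sign nulls), never exactly zero.
    """
    if n_permutations < 10:
        raise ValueError("need at least 10 permutations")
    es, _ = enrichment_score(ranked, gene_set, weight_p)
    n = len(ranked)
    k = sum(g in gene_set.members for g in ranked.genes)
    rng = np.random.default_rng(seed)
    w = np.abs(ranked.scores) ** weight_p
    order = np.arange(n)

    null = np.empty(n_permutations)
    for i in range(n_permutations):
        idx = np.sort(rng.choice(order, size=k, replace=False))
        hw = w[idx]
        denom = hw.sum()
        if denom == 0:  # degenerate permutation (all-zero scores in the draw)
            null[i] = 0.0
            continue
        null[i] = _es_from_hits(idx, hw / denom, n)

    if es == 0:
        return EnrichmentResult(es=0.0, nes=0.0, p_value=1.0,
                                n_permutations=n_permutations, seed=seed, n_hits=k)
    same = null[null > 0] if es > 0 else null[null < 0]
    if same.size == 0:
        log.warning("no same-sign null ES values; p floored at 1/(1+n_permutations)")
        return EnrichmentResult(
            es=es, nes=float("nan"), p_value=1.0 / (1.0 + n_permutations),
            n_permutations=n_permutations, seed=seed, n_hits=k,
        )
    nes = es / float(np.mean(np.abs(same)))
    p = (1.0 + float(np.sum(np.abs(same) >= abs(es)))) / (1.0 + same.size)
    return EnrichmentResult(es=es, nes=float(nes), p_value=float(p),
                            n_permutations=n_permutations, seed=seed, n_hits=k)


def rank_from_expression(
    expression: pd.DataFrame,
    conditions: Mapping[str, str],
) -> RankedGeneList:
    """Ranked list from a count matrix: log2FC (B over A) on mean CPM.

    Uses the same CPM + 0.5 pseudocount fold change as the expression
    integration; ties keep input order (stable sort).
    """
    from .integrate import expression_changes

    changes = expression_changes(expression, conditions, min_abs_log2fc=0.0)
    order = sorted(range(len(changes)), key=lambda i: -changes[i].log2_fc)
    return RankedGeneList(
        genes=tuple(changes[i].gene_id for i in order),
        scores=np.array([changes[i].log2_fc for i in order]),
    )
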