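"""Core-gene ranking, consensus order and pairwise synteny comparison.

Each genome's core genes receive a rank (1..N) following chromosomal start
coordinates.  The consensus order assigns every core group its modal rank
across a panel subset; collisions are resolved by majority pairwise
precedence (a Condorcet rule), then mean rank, then group id.  Pairwise
synteny comparisons pair the ranks of shared core groups; the sign of their
Spearman correlation gives the global orientation of one genome relative to
the other (the "diagonal from bottom-left to top-right" convention).
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd
from scipy import stats

from .genome_model import GenomeAnnotation

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CoreOrder:
    """Consensus core-gene order: group_ids listed by rank 1..N."""

    group_ids: tuple

    @property
    def rank_of(self) -> Mapping[str, int]:
        return {g: i + 1 for i, g in enumerate(self.group_ids)}

    def __len__(self):
        return len(self.group_ids)


@dataclass(frozen=True)
class SyntenyComparison:
    genome_a: str
    genome_b: str
    points: tuple  # (rank_in_A, rank_in_B) per shared core group
    orientation: str  # "same" | "inverted"


def rank_core_genes(genome: GenomeAnnotation, core_group_ids: Iterable[str]) -> dict:
    """group_id -> rank (1..N) by chromosomal start-coordinate order."""
    core = genome.core_genes(core_group_ids)
    core.sort(key=lambda g: g.start)
    return {g.orthogroup_id: i + 1 for i, g in enumerate(core)}


def _condorcet_order(groups, rank_maps, mean_rank):
    """Order colliding groups by majority pairwise precedence; fall back to
    mean rank, then lexicographic group id."""
    remaining = list(groups)
    ordered = []
    while remaining:
        winner = None
        for cand in remaining:
            beats_all = True
            for other in remaining:
                if other == cand:
                    continue
                before = sum(
                    1
                    for rm in rank_maps
                    if cand in rm and other in rm and rm[cand] < rm[other]
                )
                after = sum(
                    1
                    for rm in rank_maps
                    if cand in rm and other in rm and rm[cand] > rm[other]
                )
                if before <= after:
                    beats_all = False
                    break
            if beats_all:
                winner = cand
                break
        if winner is None:
            logger.warning(
                "unresolvable precedence cycle among %s; falling back to "
                "mean rank then group id",
                sorted(remaining),
            )
            remaining.sort(key=lambda g: (mean_rank[g], g))
            ordered.extend(remaining)
            break
        ordered.append(winner)
        remaining.remove(winner)
    return ordered


def consensus_order(genomes: Iterable[GenomeAnnotation], core_group_ids) -> CoreOrder:
    """Modal-rank consensus order over a panel subset.

    The subset is expected to share one global orientation (pre-flip with
    :func:`synteny_pairs` if needed).  Ranks are re-compacted to 1..N after
    collision resolution, so the result is always a permutation.
    """
    core_ids = sorted(set(core_group_ids))
    rank_maps = [rank_core_genes(g, core_ids) for g in genomes]
    if not rank_maps:
        raise ValueError("consensus requires at least one genome")
    modal = {}
    mean_rank = {}
    for gid in core_ids:
        ranks = [rm[gid] for rm in rank_maps if gid in rm]
        if not ranks:
            continue
        counts = Counter(ranks)
        top = max(counts.values())
        modal[gid] = min(r for r, c in counts.items() if c == top)
        mean_rank[gid] = sum(ranks) / len(ranks)
    by_modal: dict = {}
    for gid, r in modal.items():
        by_modal.setdefault(r, []).append(gid)
    ordered = []
    for r in sorted(by_modal):
        bucket = sorted(by_modal[r])
        if len(bucket) == 1:
            ordered.extend(bucket)
        else:
            ordered.extend(_condorcet_order(bucket, rank_maps, mean_rank))
    return CoreOrder(tuple(ordered))


def synteny_pairs(
    genome_a: GenomeAnnotation, genome_b: GenomeAnnotation, core_group_ids
) -> SyntenyComparison:
    """Rank-vs-rank points for shared core groups plus global orientation."""
    ra = rank_core_genes(genome_a, core_group_ids)
    rb = rank_core_genes(genome_b, core_group_ids)
    shared = sorted(set(ra) & set(rb))
    if len(shared) < 2:
        raise ValueError("fewer than 2 shared core groups")
    points = tuple((ra[g], rb[g]) for g in shared)
    rho = stats.spearmanr([p[0] for p in points], [p[1] for p in points]).statistic
    return SyntenyComparison(
        genome_a.genome_id,
        genome_b.genome_id,
        points,
        "same" if rho > 0 else "inverted",
    )


def core_order_table(order: CoreOrder) -> pd.DataFrame:
    return pd.DataFrame(
        {"rank": range(1, len(order) + 1), "group_id": list(order.group_ids)}
    )
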