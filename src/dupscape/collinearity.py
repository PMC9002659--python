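"""Intra-chromosomal collinear block detection by anchor chaining.

Homologous gene pairs on the same chromosome ("anchors") live in gene-rank
space.  A collinear block is a chain of anchors whose rank_a values are
strictly increasing while rank_b is strictly monotone (ascending or
descending orientation), with consecutive rank gaps bounded on both axes.
Chains are found by dynamic programming with unit anchor scores; blocks are
extracted greedily (best chain first, anchors removed, repeat) so each
anchor belongs to at most one block.
"""

from __future__ import annotations

import logging
import math
import statistics
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .model import Gene

logger = logging.getLogger(__name__)

DEFAULT_MIN_BLOCK_ANCHORS = 5
DEFAULT_MAX_GAP = 25


@dataclass(frozen=True)
class Anchor:
    """A same-chromosome homologous pair in canonical orientation (rank_a < rank_b)."""

    gene_a: str
    gene_b: str
    chrom: str
    rank_a: int
    rank_b: int
    ks: float = float("nan")

    @property
    def ks_defined(self) -> bool:
        return math.isfinite(self.ks)


@dataclass
class CollinearBlock:
    chrom: str
    anchors: list[Anchor]
    orientation: str  # ascending | descending

    @property
    def n_anchors(self) -> int:
        return len(self.anchors)

    @property
    def median_ks(self) -> float:
        defined = [a.ks for a in self.anchors if a.ks_defined]
        return statistics.median(defined) if defined else float("nan")

    @property
    def gene_ids(self) -> set[str]:
        return {g for a in self.anchors for g in (a.gene_a, a.gene_b)}

    def validate(self, max_gap: int = DEFAULT_MAX_GAP) -> None:
        sign = 1 if self.orientation == "ascending" else -1
        for prev, cur in zip(self.anchors, self.anchors[1:]):
            if cur.rank_a <= prev.rank_a:
                raise ValueError("rank_a not strictly increasing along chain")
            if sign * (cur.rank_b - prev.rank_b) <= 0:
                raise ValueError(f"rank_b not strictly {self.orientation}")
            if cur.rank_a - prev.rank_a > max_gap or abs(cur.rank_b - prev.rank_b) > max_gap:
                raise ValueError("anchor rank gap exceeds max_gap")


def build_anchors(pairs_with_ks: Iterable[tuple[str, str, float]],
                  genes: Sequence[Gene] | Mapping[str, Gene]) -> list[Anchor]:
    """Keep same-chromosome pairs, canonicalised so rank_a < rank_b."""
    by_id = genes if isinstance(genes, Mapping) else {g.gene_id: g for g in genes}
    anchors = []
    for gene_a, gene_b, ks in pairs_with_ks:
        for gid in (gene_a, gene_b):
            if gid not in by_id:
                raise ValueError(f"gene {gid} missing from annotation")
        ga, gb = by_id[gene_a], by_id[gene_b]
        if ga.chrom != gb.chrom or ga.rank == gb.rank:
            continue
        if ga.rank > gb.rank:
            ga, gb = gb, ga
        anchors.append(Anchor(ga.gene_id, gb.gene_id, ga.chrom, ga.rank, gb.rank, ks))
    return anchors


def _best_chain(anchors: list[Anchor], orientation: str, max_gap: int) -> list[int]:
    """Indices (into `anchors`) of the highest-scoring chain, by DP.

    Anchors must be pre-sorted by (rank_a, rank_b).  Unit scores; the first
    index attaining the maximum during the forward pass wins ties, which
    makes extraction deterministic.
    """
    sign = 1 if orientation == "ascending" else -1
    n = len(anchors)
    score = [1] * n
    parent = [-1] * n
    for j in range(n):
        aj = anchors[j]
        for i in range(j):
            ai = anchors[i]
            if ai.rank_a >= aj.rank_a:
                continue
            db = sign * (aj.rank_b - ai.rank_b)
            if db <= 0:
                continue
            if aj.rank_a - ai.rank_a > max_gap or db > max_gap:
                continue
            if score[i] + 1 > score[j]:
                score[j] = score[i] + 1
                parent[j] = i
    best_end = max(range(n), key=lambda j: (score[j], -j))
    chain = []
    j = best_end
    while j != -1:
        chain.append(j)
        j = parent[j]
    return chain[::-1]


def chain_anchors(anchors: Iterable[Anchor],
                  min_block_anchors: int = DEFAULT_MIN_BLOCK_ANCHORS,
                  max_gap: int = DEFAULT_MAX_GAP) -> list[CollinearBlock]:
    """Greedy extraction of non-overlapping maximal collinear chains.

    Per chromosome: repeatedly take the best DP chain over the remaining
    anchors (either orientation), remove its anchors, and stop when the best
    chain is shorter than ``min_block_anchors``.  Blocks are ordered by
    (score desc, leftmost rank_a, chromosome name) for determinism.
    """
    by_chrom: dict[str, list[Anchor]] = {}
    for anchor in anchors:
        by_chrom.setdefault(anchor.chrom, []).append(anchor)
    blocks: list[CollinearBlock] = []
    for chrom in sorted(by_chrom):
        remaining = sorted(by_chrom[chrom], key=lambda a: (a.rank_a, a.rank_b, a.gene_a))
        while remaining:
            candidates = []
            for orientation in ("ascending", "descending"):
                idx = _best_chain(remaining, orientation, max_gap)
                candidates.append((len(idx), -remaining[idx[0]].rank_a,
                                   orientation == "ascending", orientation, idx))
            candidates.sort(reverse=True)
            size, _, _, orientation, idx = candidates[0]
            if size < min_block_anchors:
                break
            chosen = [remaining[i] for i in idx]
            block = CollinearBlock(chrom=chrom, anchors=chosen, orientation=orientation)
            block.validate(max_gap)
            blocks.append(block)
            taken = set(idx)
            remaining = [a for i, a in enumerate(remaining) if i not in taken]
    blocks.sort(key=lambda b: (-b.n_anchors, b.anchors[0].rank_a, b.chrom))
    return blocks


def filter_blocks_by_ks(blocks: Iterable[CollinearBlock],
                        ks_max: float = 0.2) -> list[CollinearBlock]:
    """Keep blocks with median anchor Ks strictly below ks_max.

    Blocks whose anchors all lack a defined Ks are dropped and logged.
    """
    kept = []
    for block in blocks:
        median = block.median_ks
        if math.isnan(median):
            logger.info("dropping block on %s: no anchor has a defined Ks", block.chrom)
            continue
        if median < ks_max:
            kept.append(block)
    return kept
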