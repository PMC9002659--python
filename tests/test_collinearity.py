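import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dupscape.collinearity import (Anchor, CollinearBlock, build_anchors,
                                   chain_anchors, filter_blocks_by_ks)
from dupscape.model import assign_ranks
from oracles import best_chain_size_bruteforce


def make_anchor(rank_a, rank_b, ks=0.1, chrom="chr1"):
    return Anchor(f"a{rank_a}", f"b{rank_b}", chrom, rank_a, rank_b, ks)


def diagonal(n, offset=20, start=0):
    return [make_anchor(start + i, start + i + offset) for i in range(n)]


class TestBuildAnchors:
    GENES = assign_ranks([
        ("g1", "chr1", 100, 200, "+"), ("g2", "chr1", 300, 400, "+"),
        ("g5", "chr1", 900, 950, "+"), ("h1", "chr2", 100, 200, "+")])

    def test_interchromosomal_pair_dropped(self):
        assert build_anchors([("g1", "h1", 0.1)], self.GENES) == []

    def test_canonicalized_to_ascending_ranks(self):
        anchors = build_anchors([("g5", "g2", 0.1)], self.GENES)
        assert len(anchors) == 1
        assert (anchors[0].gene_a, anchors[0].gene_b) == ("g2", "g5")
        assert anchors[0].rank_a < anchors[0].rank_b

    def test_unknown_gene_is_error(self):
        with pytest.raises(ValueError, match="gX"):
            build_anchors([("g1", "gX", 0.1)], self.GENES)

    def test_planted_segmental_event_yields_block_anchors(self, canonical_result):
        truth_pairs = [(r["gene_id"], r["source_gene_id"], r["planted_ks"])
                       for r in canonical_result.truth_duplications
                       if r["event_type"] == "segmental"]
        anchors = build_anchors(truth_pairs, canonical_result.genome.genes)
        assert len(anchors) >= 6


class TestChainAnchors:
    def test_perfect_diagonal_forms_one_ascending_block(self):
        blocks = chain_anchors(diagonal(6))
        assert len(blocks) == 1
        assert blocks[0].orientation == "ascending"
        assert blocks[0].n_anchors == 6

    def test_below_min_anchor_threshold_gives_no_block(self):
        assert chain_anchors(diagonal(4), min_block_anchors=5) == []

    def test_descending_chain_detected(self):
        anchors = [make_anchor(i, 50 - i) for i in range(5)]
        blocks = chain_anchors(anchors)
        assert len(blocks) == 1
        assert blocks[0].orientation == "descending"

    def test_gap_constraint_splits_chains(self):
        anchors = diagonal(5) + diagonal(5, start=100)
        blocks = chain_anchors(anchors, max_gap=25)
        assert [b.n_anchors for b in blocks] == [5, 5]

    def test_anchor_used_in_at_most_one_block(self):
        anchors = diagonal(7) + diagonal(6, offset=40)
        blocks = chain_anchors(anchors)
        seen = []
        for block in blocks:
            seen.extend((a.rank_a, a.rank_b) for a in block.anchors)
        assert len(seen) == len(set(seen))

    def test_every_block_satisfies_its_invariants(self):
        rng = np.random.default_rng(5)
        anchors = [make_anchor(int(a), int(b))
                   for a, b in rng.integers(0, 40, size=(60, 2)) if a < b]
        for block in chain_anchors(anchors, min_block_anchors=2, max_gap=10):
            block.validate(max_gap=10)

    @given(st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=60, deadline=None)
    def test_dp_matches_exhaustive_search(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 9))
        max_gap = int(rng.integers(2, 12))
        pairs = set()
        while len(pairs) < n:
            a, b = sorted(rng.integers(0, 15, size=2))
            if a < b:
                pairs.add((int(a), int(b)))
        anchors = [make_anchor(a, b) for a, b in sorted(pairs)]
        blocks = chain_anchors(anchors, min_block_anchors=1, max_gap=max_gap)
        assert blocks[0].n_anchors == best_chain_size_bruteforce(sorted(pairs), max_gap)


class TestFilterBlocksByKs:
    def block(self, ks_values):
        anchors = [make_anchor(i, i + 20, ks=k) for i, k in enumerate(ks_values)]
        return CollinearBlock(chrom="chr1", anchors=anchors, orientation="ascending")

    def test_strict_inequality_at_threshold(self):
        kept = filter_blocks_by_ks([self.block([0.19] * 5), self.block([0.20] * 5)])
        assert len(kept) == 1
        assert kept[0].median_ks == pytest.approx(0.19)

    def test_all_undefined_anchors_dropped(self):
        nan = float("nan")
        assert filter_blocks_by_ks([self.block([nan] * 5)]) == []

    def test_median_ignores_undefined_anchors(self):
        block = self.block([0.1, 0.1, float("nan"), 0.1, 0.5])
        assert block.median_ks == pytest.approx(0.1)

    def test_planted_low_ks_block_kept_high_ks_dropped(self, canonical_result, tmp_path):
        # reuse canonical genome truth anchors but shift their Ks labels
        truth_pairs = [(r["gene_id"], r["source_gene_id"], 0.1)
                       for r in canonical_result.truth_duplications
                       if r["event_type"] == "segmental"]
        anchors = build_anchors(truth_pairs, canonical_result.genome.genes)
        low = chain_anchors(anchors)
        assert filter_blocks_by_ks(low, ks_max=0.2) == low
        high = chain_anchors([Anchor(a.gene_a, a.gene_b, a.chrom, a.rank_a, a.rank_b, 0.5)
                              for a in anchors])
        assert filter_blocks_by_ks(high, ks_max=0.2) == []
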