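import filecmp
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dupscape.homology import align_global
from dupscape.ks import codon_align, ng86
from dupscape.model import translate_cds
from dupscape.simulate import (SegmentalEvent, SimConfig, TandemEvent, build_genome,
                               canonical_config, plant_ks, random_cds, simulate_genome)


class TestSimConfigValidation:
    def test_target_ks_at_saturation_rejected(self):
        with pytest.raises(ValueError, match="1.0"):
            TandemEvent("chr1", 0, 1, 1.0)

    def test_overlapping_source_regions_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            SimConfig(segmental_events=[SegmentalEvent("chr1", 0, 6, 20, 0.1)],
                      tandem_events=[TandemEvent("chr1", 3, 1, 0.1)])

    def test_insert_inside_own_source_run_rejected(self):
        with pytest.raises(ValueError, match="inside"):
            SimConfig(segmental_events=[SegmentalEvent("chr1", 0, 6, 3, 0.1)])

    def test_short_segmental_block_rejected(self):
        with pytest.raises(ValueError, match=">= 5"):
            SegmentalEvent("chr1", 0, 4, 20, 0.1)


class TestPlantKs:
    def test_zero_target_leaves_sequence_unchanged(self):
        rng = np.random.default_rng(0)
        cds = random_cds(100, rng)
        assert plant_ks(cds, 0.0, rng) == cds

    @given(st.integers(min_value=0, max_value=9999),
           st.floats(min_value=0.0, max_value=0.9))
    @settings(max_examples=30, deadline=None)
    def test_translation_invariant_for_any_target(self, seed, target):
        rng = np.random.default_rng(seed)
        cds = random_cds(60, rng)
        assert translate_cds(plant_ks(cds, target, rng)) == translate_cds(cds)

    def test_observed_synonymous_proportion_matches_inverted_jc(self):
        # at target Ks 0.2 the planted per-site change probability is
        # p = 0.75 (1 - exp(-4*0.2/3)) ~ 0.1755
        rng = np.random.default_rng(3)
        cds = random_cds(6000, rng)
        mutated = plant_ks(cds, 0.2, rng)
        est = ng86(list(zip([cds[i:i + 3] for i in range(0, len(cds) - 3, 3)],
                            [mutated[i:i + 3] for i in range(0, len(mutated) - 3, 3)])))
        assert est.ps == pytest.approx(0.1755, abs=0.01)
        # doubly-hit codons can average a fractional nonsynonymous step over
        # pathways even though every applied change was synonymous
        assert est.pn < 0.002


class TestBuildGenome:
    def test_no_events_give_empty_truth_table(self):
        result = build_genome(SimConfig(n_chrom=1, genes_per_chrom=5, seed=4))
        assert result.truth_duplications == []
        assert len(result.genome.genes) == 5

    def test_single_tandem_copy_at_zero_ks_is_identical(self):
        config = SimConfig(n_chrom=1, genes_per_chrom=5,
                           tandem_events=[TandemEvent("chr1", 2, 1, 0.0)], seed=4)
        result = build_genome(config)
        (row,) = result.truth_duplications
        assert result.genome.cds[row["gene_id"]] == result.genome.cds[row["source_gene_id"]]

    def test_tandem_copies_sit_at_insertion_offsets(self):
        config = SimConfig(n_chrom=1, genes_per_chrom=10,
                           tandem_events=[TandemEvent("chr1", 4, 3, 0.05)], seed=4)
        result = build_genome(config)
        genome = result.genome
        source_rank = genome.gene("chr1g0004").rank
        offsets = sorted(genome.gene(r["gene_id"]).rank - source_rank
                         for r in result.truth_duplications)
        assert offsets == [1, 2, 3]

    def test_segmental_copies_form_perfect_ascending_chain(self, canonical_result):
        genome = canonical_result.genome
        for chrom in ("chr1", "chr3"):
            anchors = sorted(
                (genome.gene(r["source_gene_id"]).rank, genome.gene(r["gene_id"]).rank)
                for r in canonical_result.truth_duplications
                if r["event_type"] == "segmental" and r["gene_id"].startswith(chrom))
            ra = [a for a, _ in anchors]
            rb = [b for _, b in anchors]
            assert ra == sorted(ra) and rb == sorted(rb)
            assert len(set(ra)) == len(ra) and len(set(rb)) == len(rb)

    def test_rank_invariant_and_translation_invariant_hold(self, canonical_result):
        canonical_result.genome.validate()

    def test_domain_architectures_assigned(self, canonical_result):
        assert len(canonical_result.domains) == 12


class TestDeterminism:
    def test_same_seed_gives_byte_identical_files(self, tmp_path):
        paths_a = simulate_genome(canonical_config(seed=9), tmp_path / "a")
        paths_b = simulate_genome(canonical_config(seed=9), tmp_path / "b")
        for key in paths_a:
            assert filecmp.cmp(paths_a[key], paths_b[key], shallow=False), key

    def test_different_seeds_differ(self, tmp_path):
        paths_a = simulate_genome(canonical_config(seed=9), tmp_path / "a")
        paths_b = simulate_genome(canonical_config(seed=10), tmp_path / "b")
        assert not filecmp.cmp(paths_a["cds"], paths_b["cds"], shallow=False)


class TestParameterRecovery:
    @pytest.mark.parametrize("target", [0.05, 0.1, 0.2, 0.5])
    def test_estimated_ks_unbiased_within_sampling_tolerance(self, target):
        rng = np.random.default_rng(17)
        values = []
        for _ in range(60):
            cds = random_cds(300, rng)
            mutated = plant_ks(cds, target, rng)
            aln = align_global(translate_cds(cds), translate_cds(mutated))
            est = ng86(codon_align(cds, mutated, aln.aligned_query, aln.aligned_subject))
            values.append(est.ks)
        mean = sum(values) / len(values)
        # ~2 standard errors of the mean at this S and replicate count
        se = np.std(values, ddof=1) / math.sqrt(len(values))
        assert mean == pytest.approx(target, abs=max(2.5 * se, 0.01))
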