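import random

import pytest

from dupscape.classify import DuplicationCall
from dupscape.model import assign_ranks
from dupscape.rgenes import (CANONICAL_ARCHITECTURES, FAMILIES, RGeneCall,
                             classify_rgene, classify_rgenes,
                             family_duplication_table, rgene_summary, window_counts)


class TestClassifyRgene:
    @pytest.mark.parametrize("family", FAMILIES)
    def test_canonical_architecture_maps_to_family(self, family):
        assert classify_rgene(CANONICAL_ARCHITECTURES[family]) == family

    @pytest.mark.parametrize("domains,family", [
        (("TIR", "NBS", "LRR"), "TNL"),
        (("CC", "NBS"), "CN"),
        (("TM", "LRR"), "RLP"),
        (("TM", "KINASE", "LRR"), "RLK"),
        (("TIR", "CC", "NBS"), "OTHER"),
        (("TIR", "CC", "NBS", "LRR"), "OTHER"),
    ])
    def test_family_rules(self, domains, family):
        assert classify_rgene(domains) == family

    @pytest.mark.parametrize("domains", [(), ("OTHERDOM",), ("KINASE",), ("TM",),
                                         ("LRR",), ("CC",)])
    def test_non_r_architectures_get_no_call(self, domains):
        assert classify_rgene(domains) is None

    def test_unknown_label_is_error(self):
        with pytest.raises(ValueError, match="PKINASE"):
            classify_rgene(("NBS", "PKINASE"))

    @pytest.mark.parametrize("family", FAMILIES)
    def test_domain_order_never_matters(self, family):
        arch = list(CANONICAL_ARCHITECTURES[family])
        rng = random.Random(0)
        for _ in range(5):
            rng.shuffle(arch)
            assert classify_rgene(tuple(arch)) == family


class TestFamilyDuplicationTable:
    def calls(self, n_tnl=10, n_dup=7):
        rcalls = [RGeneCall(f"g{i:02d}", "TNL") for i in range(n_tnl)]
        dcalls = [DuplicationCall(f"g{i:02d}", "segmental" if i < n_dup else "none")
                  for i in range(n_tnl)]
        return rcalls, dcalls

    def test_partial_duplication_percentage(self):
        rcalls, dcalls = self.calls()
        table = {row["family"]: row for row in family_duplication_table(rcalls, dcalls)}
        assert table["TNL"]["n_total"] == 10
        assert table["TNL"]["pct_local"] == 70.0

    def test_undetected_family_has_zero_percent(self):
        rcalls = [RGeneCall("g0", "CNL")]
        dcalls = [DuplicationCall("g0", "none")]
        table = {row["family"]: row for row in family_duplication_table(rcalls, dcalls)}
        assert table["CNL"]["pct_local"] == 0.0

    def test_union_bound_per_family(self):
        rcalls = [RGeneCall(f"g{i}", "NL") for i in range(6)]
        labels = ["segmental", "tandem", "both", "none", "both", "segmental"]
        dcalls = [DuplicationCall(f"g{i}", label) for i, label in enumerate(labels)]
        for row in family_duplication_table(rcalls, dcalls):
            assert row["n_local"] <= row["n_segmental"] + row["n_tandem"]

    def test_all_r_genes_row_sums_families(self):
        rcalls = [RGeneCall("a", "TNL"), RGeneCall("b", "CN"), RGeneCall("c", "none")]
        dcalls = [DuplicationCall(g, "none") for g in "abc"]
        table = {row["family"]: row for row in family_duplication_table(rcalls, dcalls)}
        assert table["ALL_R_GENES"]["n_total"] == 2


class TestRgeneSummary:
    def test_zero_r_genes(self):
        summary = rgene_summary([RGeneCall("g0", "none")], 100)
        assert summary["n_rgenes"] == 0 and summary["pct_of_genome"] == 0.0

    def test_five_of_hundred(self):
        calls = [RGeneCall(f"g{i}", "NBS") for i in range(5)]
        assert rgene_summary(calls, 100)["pct_of_genome"] == 5.0

    def test_family_counts_sum_to_total(self, canonical_result):
        rcalls = classify_rgenes(canonical_result.domains)
        summary = rgene_summary(rcalls, len(canonical_result.genome.genes))
        assert sum(summary["per_family"].values()) == summary["n_rgenes"] == 12


class TestWindowCounts:
    def genes_at(self, starts, chrom="chr1"):
        return assign_ranks([(f"g{i}", chrom, s, s + 100, "+")
                             for i, s in enumerate(starts)])

    def test_boundary_start_at_window_end(self):
        genes = self.genes_at([100_000])
        rows = window_counts(genes, [RGeneCall("g0", "NL")])
        assert rows == [{"family": "NL", "chrom": "chr1", "window_start": 1,
                         "window_end": 100_000, "count": 1}]

    def test_next_position_opens_next_window(self):
        genes = self.genes_at([100_001])
        (row,) = window_counts(genes, [RGeneCall("g0", "NL")])
        assert row["window_start"] == 100_001

    def test_planted_cluster_counts_in_one_window(self):
        genes = self.genes_at([10_000 + 10_000 * i for i in range(5)])
        rows = window_counts(genes, [RGeneCall(f"g{i}", "NL") for i in range(5)])
        assert len(rows) == 1 and rows[0]["count"] == 5

    def test_per_family_totals_conserved(self, canonical_result):
        rcalls = classify_rgenes(canonical_result.domains)
        rows = window_counts(canonical_result.genome.genes, rcalls)
        totals = {}
        for row in rows:
            totals[row["family"]] = totals.get(row["family"], 0) + row["count"]
        expected = {}
        for call in rcalls:
            if call.family != "none":
                expected[call.family] = expected.get(call.family, 0) + 1
        assert totals == expected
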