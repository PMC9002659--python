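"""Segmental vs tandem duplicate classification.

Two definitions of local duplication, both intra-chromosomal and both gated
at Ks < 0.2:

* segmental — the gene sits in an anchor of a kept collinear block whose
  median Ks is below the threshold;
* tandem — the gene is in a homologous pair at gene-rank distance <= 10
  (adjacent genes have distance 1) whose own Ks is below the threshold.

A gene meeting both definitions is labelled ``both``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

from .collinearity import CollinearBlock
from .model import Gene

LABELS = ("segmental", "tandem", "both", "none")


@dataclass
class DupConfig:
    ks_max: float = 0.2
    tandem_max_gene_distance: int = 10

    def __post_init__(self) -> None:
        if self.ks_max <= 0:
            raise ValueError("ks_max must be positive")
        if self.tandem_max_gene_distance < 1:
            raise ValueError("tandem_max_gene_distance must be >= 1")


@dataclass
class DuplicationCall:
    gene_id: str
    label: str
    block_ids: list[int] = field(default_factory=list)
    tandem_partners: list[str] = field(default_factory=list)


def round1(x: float) -> float:
    """Round half-up to one decimal (reporting convention for percentages)."""
    return float(Decimal(repr(x)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def segmental_genes(kept_blocks: Sequence[CollinearBlock]) -> set[str]:
    """Union of the genes of every anchor of every (Ks-filtered) block."""
    return {g for block in kept_blocks for g in block.gene_ids}


def tandem_genes(pairs_with_ks: Iterable[tuple[str, str, float]],
                 genes: Sequence[Gene] | Mapping[str, Gene],
                 config: DupConfig | None = None) -> dict[str, set[str]]:
    """Genes in qualifying tandem pairs, with their partners as evidence.

    A pair qualifies iff same chromosome, |rank_a - rank_b| within the
    distance threshold (inclusive), and a defined Ks strictly below ks_max.
    """
    config = config or DupConfig()
    by_id = genes if isinstance(genes, Mapping) else {g.gene_id: g for g in genes}
    members: dict[str, set[str]] = {}
    for gene_a, gene_b, ks in pairs_with_ks:
        ga, gb = by_id[gene_a], by_id[gene_b]
        if ga.chrom != gb.chrom:
            continue
        if abs(ga.rank - gb.rank) > config.tandem_max_gene_distance:
            continue
        if not (isinstance(ks, (int, float)) and math.isfinite(ks) and ks < config.ks_max):
            continue
        members.setdefault(gene_a, set()).add(gene_b)
        members.setdefault(gene_b, set()).add(gene_a)
    return members


def classify(segmental_set: set[str], tandem_set: set[str],
             all_genes: Sequence[Gene] | Sequence[str],
             block_membership: Mapping[str, list[int]] | None = None,
             tandem_partners: Mapping[str, set[str]] | None = None,
             ) -> list[DuplicationCall]:
    """Label every gene segmental / tandem / both / none."""
    gene_ids = [g.gene_id if isinstance(g, Gene) else g for g in all_genes]
    universe = set(gene_ids)
    for name, subset in (("segmental", segmental_set), ("tandem", tandem_set)):
        stray = subset - universe
        if stray:
            raise ValueError(f"{name} set contains genes absent from the annotation: "
                             f"{sorted(stray)[:5]}")
    calls = []
    for gene_id in gene_ids:
        in_seg = gene_id in segmental_set
        in_tan = gene_id in tandem_set
        label = ("both" if in_seg and in_tan else
                 "segmental" if in_seg else
                 "tandem" if in_tan else "none")
        calls.append(DuplicationCall(
            gene_id=gene_id,
            label=label,
            block_ids=list(block_membership.get(gene_id, [])) if block_membership else [],
            tandem_partners=sorted(tandem_partners.get(gene_id, ())) if tandem_partners else [],
        ))
    return calls


def summarize_counts(n_segmental: int, n_tandem: int, n_both: int,
                     total_genes: int) -> dict:
    """Percentage summary from exclusive label counts.

    ``n_segmental``/``n_tandem`` count genes labelled only segmental/tandem;
    genes meeting both definitions are in ``n_both``.
    """
    seg_all = n_segmental + n_both
    tan_all = n_tandem + n_both
    local = n_segmental + n_tandem + n_both
    def pct(num: int, denom: int):
        return round1(100.0 * num / denom) if denom else None
    return {
        "total_genes": total_genes,
        "n_segmental": seg_all,
        "n_tandem": tan_all,
        "n_both": n_both,
        "n_local": local,
        "pct_segmental": pct(seg_all, total_genes),
        "pct_tandem": pct(tan_all, total_genes),
        "pct_overlap_of_tandem": pct(n_both, tan_all),
        "pct_local": pct(local, total_genes),
    }


def duplication_percentages(calls: Sequence[DuplicationCall], total_genes: int) -> dict:
    """Genome-level duplication summary (counts and 1-decimal percentages)."""
    if total_genes < 1:
        raise ValueError("total_genes must be >= 1")
    tally = {label: 0 for label in LABELS}
    for call in calls:
        tally[call.label] += 1
    return summarize_counts(tally["segmental"], tally["tandem"], tally["both"], total_genes)
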