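"""Resistance-gene (R-gene) family classification from domain architectures.

Plant R genes are built from a small set of domains: NBS (nucleotide-binding
site), LRR (leucine-rich repeat), TIR (Toll/interleukin-1 receptor), CC
(coiled-coil), transmembrane (TM) and kinase.  The 11 RGAugury families are
assigned from domain *presence* (order-independent):

NBS-containing: TIR+CC -> OTHER; TIR+LRR -> TNL; TIR -> TN; CC+LRR -> CNL;
CC -> CN; LRR -> NL; bare -> NBS.  Without NBS: TIR -> TX;
TM+KINASE+LRR -> RLK; TM+LRR -> RLP; TM+CC -> TM-CC; anything else -> no call.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .classify import DuplicationCall, round1
from .model import DOMAIN_VOCABULARY, Gene

FAMILIES = ("CN", "CNL", "NBS", "NL", "TN", "TNL", "TX", "OTHER", "RLK", "RLP", "TM-CC")

# One representative architecture per family (used by the simulator and docs).
CANONICAL_ARCHITECTURES: dict[str, tuple[str, ...]] = {
    "CN": ("CC", "NBS"),
    "CNL": ("CC", "NBS", "LRR"),
    "NBS": ("NBS",),
    "NL": ("NBS", "LRR"),
    "TN": ("TIR", "NBS"),
    "TNL": ("TIR", "NBS", "LRR"),
    "TX": ("TIR", "OTHERDOM"),
    "OTHER": ("TIR", "CC", "NBS"),
    "RLK": ("TM", "KINASE", "LRR"),
    "RLP": ("TM", "LRR"),
    "TM-CC": ("TM", "CC"),
}


@dataclass(frozen=True)
class RGeneCall:
    gene_id: str
    family: str  # one of FAMILIES, or "none"


def classify_rgene(domains: Iterable[str]) -> str | None:
    """Family label for one domain architecture, or None for non-R genes."""
    present = set(domains)
    unknown = present - DOMAIN_VOCABULARY
    if unknown:
        raise ValueError(f"unknown domain labels: {sorted(unknown)}")
    tir, cc, lrr = "TIR" in present, "CC" in present, "LRR" in present
    if "NBS" in present:
        if tir and cc:
            return "OTHER"
        if tir and lrr:
            return "TNL"
        if tir:
            return "TN"
        if cc and lrr:
            return "CNL"
        if cc:
            return "CN"
        if lrr:
            return "NL"
        return "NBS"
    if tir:
        return "TX"
    if "TM" in present and "KINASE" in present and lrr:
        return "RLK"
    if "TM" in present and lrr:
        return "RLP"
    if "TM" in present and cc:
        return "TM-CC"
    return None


def classify_rgenes(domains: Mapping[str, Sequence[str]]) -> list[RGeneCall]:
    calls = []
    for gene_id in sorted(domains):
        family = classify_rgene(domains[gene_id])
        calls.append(RGeneCall(gene_id=gene_id, family=family or "none"))
    return calls


def family_duplication_table(rgene_calls: Sequence[RGeneCall],
                             duplication_calls: Sequence[DuplicationCall]) -> list[dict]:
    """Per-family duplication cross-tabulation, plus an all-R-genes row.

    Columns: n_total, n_segmental and n_tandem (each including genes
    labelled both), n_local (any local duplication), pct_local.
    """
    label_of = {c.gene_id: c.label for c in duplication_calls}
    rows = []
    groups: dict[str, list[str]] = {fam: [] for fam in FAMILIES}
    for call in rgene_calls:
        if call.family != "none":
            groups[call.family].append(call.gene_id)
    all_r = [g for members in groups.values() for g in members]
    for family, members in [*groups.items(), ("ALL_R_GENES", all_r)]:
        n_seg = sum(label_of.get(g, "none") in ("segmental", "both") for g in members)
        n_tan = sum(label_of.get(g, "none") in ("tandem", "both") for g in members)
        n_local = sum(label_of.get(g, "none") != "none" for g in members)
        rows.append({
            "family": family,
            "n_total": len(members),
            "n_segmental": n_seg,
            "n_tandem": n_tan,
            "n_local": n_local,
            "pct_segmental": round1(100.0 * n_seg / len(members)) if members else 0.0,
            "pct_tandem": round1(100.0 * n_tan / len(members)) if members else 0.0,
            "pct_local": round1(100.0 * n_local / len(members)) if members else 0.0,
        })
    return rows


def rgene_summary(rgene_calls: Sequence[RGeneCall], total_genes: int) -> dict:
    """Total R-gene count, genome percentage, and per-family counts."""
    if total_genes < 1:
        raise ValueError("total_genes must be >= 1")
    per_family = {fam: 0 for fam in FAMILIES}
    for call in rgene_calls:
        if call.family != "none":
            per_family[call.family] += 1
    n_rgenes = sum(per_family.values())
    return {
        "n_rgenes": n_rgenes,
        "pct_of_genome": round1(100.0 * n_rgenes / total_genes),
        "per_family": per_family,
    }


def window_counts(genes: Sequence[Gene], rgene_calls: Sequence[RGeneCall],
                  window: int = 100_000, stride: int = 100_000) -> list[dict]:
    """Per-family R-gene counts in tiling windows along each chromosome.

    Windows start at position 1 and advance by ``stride``; a gene is counted
    in every window whose span contains its start coordinate (exactly one
    window when stride == window).  Only non-zero rows are returned, one per
    (family, chrom, window_start).
    """
    family_of = {c.gene_id: c.family for c in rgene_calls if c.family != "none"}
    counts: dict[tuple[str, str, int], int] = {}
    for gene in genes:
        family = family_of.get(gene.gene_id)
        if family is None:
            continue
        # window index range containing `start` (1-based spans [k*stride+1, k*stride+window])
        last = (gene.start - 1) // stride
        first = max(0, -(-(gene.start - window) // stride))
        for k in range(first, last + 1):
            key = (family, gene.chrom, k * stride + 1)
            counts[key] = counts.get(key, 0) + 1
    return [
        {"family": fam, "chrom": chrom, "window_start": ws,
         "window_end": ws + window - 1, "count": n}
        for (fam, chrom, ws), n in sorted(counts.items())
    ]
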