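"""Shared genome data model.

A :class:`Gene` is a point in two coordinate systems at once: base-pair
coordinates (1-based, inclusive, GFF3 convention) and gene-order *rank*
(0-based index among the genes of its chromosome, sorted by start).  All
collinearity and tandem-distance logic downstream operates in rank space;
window counting operates in base-pair space.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

from Bio.Seq import Seq

DOMAIN_VOCABULARY = frozenset({"TIR", "CC", "NBS", "LRR", "TM", "KINASE", "OTHERDOM"})


@dataclass(frozen=True)
class Gene:
    """A protein-coding gene locus.

    ``start``/``end`` are 1-based inclusive base-pair coordinates; ``rank``
    is the 0-based order index among genes on ``chrom`` sorted by start
    (ties broken by gene_id).
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    rank: int

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(f"gene {self.gene_id}: end {self.end} < start {self.start}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: bad strand {self.strand!r}")


def assign_ranks(records: Iterable[tuple[str, str, int, int, str]]) -> list[Gene]:
    """Build Gene objects from (gene_id, chrom, start, end, strand) tuples.

    Ranks are assigned per chromosome by ascending start coordinate with
    lexicographic gene_id as tie-break, yielding a contiguous 0..n-1
    permutation on every chromosome.
    """
    by_chrom: dict[str, list[tuple[str, str, int, int, str]]] = {}
    seen: set[str] = set()
    for rec in records:
        gene_id = rec[0]
        if gene_id in seen:
            raise ValueError(f"duplicate gene ID: {gene_id}")
        seen.add(gene_id)
        by_chrom.setdefault(rec[1], []).append(rec)
    genes: list[Gene] = []
    for chrom in sorted(by_chrom):
        ordered = sorted(by_chrom[chrom], key=lambda r: (r[2], r[0]))
        for rank, (gene_id, _, start, end, strand) in enumerate(ordered):
            genes.append(Gene(gene_id, chrom, start, end, strand, rank))
    return genes


def translate_cds(cds: str) -> str:
    """Translate a CDS with the standard code, dropping one trailing stop."""
    protein = str(Seq(cds).translate())
    if protein.endswith("*"):
        protein = protein[:-1]
    return protein


def strip_stop(cds: str) -> str:
    """Remove a single trailing stop codon if present."""
    if len(cds) >= 3 and len(cds) % 3 == 0 and cds[-3:].upper() in ("TAA", "TAG", "TGA"):
        return cds[:-3]
    return cds


@dataclass
class Genome:
    """Genes plus their coding and protein sequences.

    Invariant (checked by :meth:`validate`): for every gene_id present in
    both maps, the standard-code translation of the CDS (trailing stop
    removed) equals the stored protein.
    """

    genes: list[Gene]
    cds: dict[str, str] = field(default_factory=dict)
    proteins: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._by_id = {g.gene_id: g for g in self.genes}
        if len(self._by_id) != len(self.genes):
            raise ValueError("duplicate gene IDs in genome")

    def gene(self, gene_id: str) -> Gene:
        return self._by_id[gene_id]

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._by_id

    @property
    def chromosomes(self) -> list[str]:
        return sorted({g.chrom for g in self.genes})

    def genes_on(self, chrom: str) -> list[Gene]:
        return sorted((g for g in self.genes if g.chrom == chrom), key=lambda g: g.rank)

    def validate(self) -> None:
        for chrom in self.chromosomes:
            ranks = sorted(g.rank for g in self.genes_on(chrom))
            if ranks != list(range(len(ranks))):
                raise ValueError(f"ranks on {chrom} are not a 0..n-1 permutation")
        for mapping, what in ((self.cds, "CDS"), (self.proteins, "protein")):
            for gene_id in mapping:
                if gene_id not in self._by_id:
                    raise ValueError(f"{what} entry {gene_id} has no gene record")
        for gene_id in set(self.cds) & set(self.proteins):
            if translate_cds(self.cds[gene_id]) != self.proteins[gene_id]:
                raise ValueError(f"CDS/protein translation mismatch for {gene_id}")


def validate_domain_table(domains: Mapping[str, tuple[str, ...]], genome: Genome) -> None:
    """Check a gene_id -> ordered-domain-label table against the genome."""
    for gene_id, labels in domains.items():
        if gene_id not in genome:
            raise ValueError(f"domain table gene {gene_id} not in genome")
        bad = set(labels) - DOMAIN_VOCABULARY
        if bad:
            raise ValueError(f"unknown domain labels for {gene_id}: {sorted(bad)}")
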