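"""Synthetic genomes with planted duplications and known ground truth.

The generator emits a toy genome in the exact formats the pipeline reads:
chromosomes of ordered random genes (mutually non-homologous background),
with two kinds of planted intra-chromosomal duplication —

* **segmental**: a run of >= 5 consecutive genes copied and inserted, in
  order, elsewhere on the same chromosome;
* **tandem**: copies of a single gene inserted immediately adjacent to it
  (gene-rank distance 1..copies);

— plus R-gene domain architectures assigned to chosen genes, and a truth
table naming every planted copy, its source, event type and target Ks.

Divergence is planted only at synonymous positions, so protein sequences of
source and copy stay identical: homology detection and the Ks estimator are
then testable in isolation.  The per-position substitution probability is
``p * f_i`` where ``p = (3/4)(1 - exp(-4 Ks_target / 3))`` inverts the
Jukes-Cantor correction and ``f_i`` is the position's synonymous-change
fraction under NG86 counting, making the estimator's expected ps equal p and
the recovered Ks unbiased at the target.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from . import io_formats
from .ks import SENSE_CODONS, STOP_CODONS, synonymous_fractions, _amino_acid
from .model import Gene, Genome, assign_ranks, translate_cds
from .rgenes import CANONICAL_ARCHITECTURES, FAMILIES

_NUCS = "ACGT"
INTERGENIC_BP = 1000
STOP = "TAA"


@dataclass(frozen=True)
class SegmentalEvent:
    chrom: str
    source_start_rank: int
    block_len_genes: int
    insert_rank: int
    target_ks: float

    def __post_init__(self) -> None:
        if self.block_len_genes < 5:
            raise ValueError("segmental blocks must span >= 5 genes")
        _check_ks(self.target_ks)

    @property
    def source_ranks(self) -> range:
        return range(self.source_start_rank, self.source_start_rank + self.block_len_genes)


@dataclass(frozen=True)
class TandemEvent:
    chrom: str
    source_rank: int
    copies: int
    target_ks: float

    def __post_init__(self) -> None:
        if self.copies < 1:
            raise ValueError("tandem events need >= 1 copy")
        _check_ks(self.target_ks)


def _check_ks(target_ks: float) -> None:
    if target_ks < 0:
        raise ValueError("target_ks must be >= 0")
    if target_ks >= 1.0:
        raise ValueError("target_ks must be < 1.0 (JC saturation)")


@dataclass
class SimConfig:
    n_chrom: int = 3
    genes_per_chrom: int = 60
    codons_per_gene: int = 150
    segmental_events: list[SegmentalEvent] = field(default_factory=list)
    tandem_events: list[TandemEvent] = field(default_factory=list)
    # gene_id -> ordered domain labels
    rgene_assignments: dict[str, tuple[str, ...]] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_chrom < 1 or self.genes_per_chrom < 1:
            raise ValueError("need at least one chromosome and one gene")
        if self.codons_per_gene < 30:
            raise ValueError("codons_per_gene must be >= 30")
        self.segmental_events = [e if isinstance(e, SegmentalEvent) else SegmentalEvent(*e)
                                 for e in self.segmental_events]
        self.tandem_events = [e if isinstance(e, TandemEvent) else TandemEvent(*e)
                              for e in self.tandem_events]
        self._validate_events()

    def _validate_events(self) -> None:
        used: dict[str, set[int]] = {}
        inserts: dict[str, set[int]] = {}
        n = self.genes_per_chrom
        for event in self.segmental_events:
            ranks = set(event.source_ranks)
            if min(ranks) < 0 or max(ranks) >= n or not 0 <= event.insert_rank <= n:
                raise ValueError(f"segmental event out of range on {event.chrom}")
            if ranks & used.setdefault(event.chrom, set()):
                raise ValueError(f"overlapping event source regions on {event.chrom}")
            if ranks and min(ranks) < event.insert_rank <= max(ranks):
                raise ValueError("segmental insert position falls inside its source run")
            used[event.chrom] |= ranks
            if event.insert_rank in inserts.setdefault(event.chrom, set()):
                raise ValueError(f"two insertions at the same rank on {event.chrom}")
            inserts[event.chrom].add(event.insert_rank)
        for event in self.tandem_events:
            if not 0 <= event.source_rank < n:
                raise ValueError(f"tandem source rank out of range on {event.chrom}")
            if event.source_rank in used.setdefault(event.chrom, set()):
                raise ValueError(f"overlapping event source regions on {event.chrom}")
            used[event.chrom].add(event.source_rank)
            pos = event.source_rank + 1
            if pos in inserts.setdefault(event.chrom, set()):
                raise ValueError(f"two insertions at the same rank on {event.chrom}")
            inserts[event.chrom].add(pos)

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "SimConfig":
        with open(path) as handle:
            raw = yaml.safe_load(handle)
        raw["segmental_events"] = [SegmentalEvent(**e) for e in raw.get("segmental_events", [])]
        raw["tandem_events"] = [TandemEvent(**e) for e in raw.get("tandem_events", [])]
        raw["rgene_assignments"] = {k: tuple(v) for k, v in
                                    (raw.get("rgene_assignments") or {}).items()}
        return cls(**raw)


def random_cds(n_codons: int, rng: np.random.Generator) -> str:
    """ATG + uniform sense codons + fixed stop; n_codons counts coding codons."""
    body = rng.choice(len(SENSE_CODONS), size=n_codons - 1)
    return "ATG" + "".join(SENSE_CODONS[i] for i in body) + STOP


def plant_ks(cds: str, target_ks: float, rng: np.random.Generator) -> str:
    """Apply synonymous-only substitutions aiming at a JC-corrected Ks.

    Each codon position mutates with probability p*f_i (p inverts the JC
    correction at the target; f_i is the NG86 synonymous-change fraction),
    drawing uniformly among its synonymous non-stop alternatives.  Stop
    codons never arise and the translation is unchanged.
    """
    _check_ks(target_ks)
    if target_ks == 0:
        return cds
    p = 0.75 * (1.0 - math.exp(-4.0 * target_ks / 3.0))
    codons = [cds[i:i + 3] for i in range(0, len(cds), 3)]
    out = []
    for codon in codons:
        if codon in STOP_CODONS:
            out.append(codon)
            continue
        current = codon
        for pos in range(3):
            f = synonymous_fractions(current)[pos]
            if f == 0.0 or rng.random() >= p * f:
                continue
            alts = [current[:pos] + nuc + current[pos + 1:]
                    for nuc in _NUCS if nuc != current[pos]]
            alts = [c for c in alts
                    if c not in STOP_CODONS and _amino_acid(c) == _amino_acid(current)]
            current = alts[rng.integers(len(alts))]
        out.append(current)
    return "".join(out)


@dataclass
class SimResult:
    genome: Genome
    domains: dict[str, tuple[str, ...]]
    # rows: gene_id (copy), source_gene_id, event_type, planted_ks
    truth_duplications: list[dict]
    # rows: gene_id, domains
    truth_rgenes: list[dict]


def build_genome(config: SimConfig) -> SimResult:
    """Generate the genome in memory (deterministic in config.seed)."""
    rng = np.random.default_rng(config.seed)
    cds: dict[str, str] = {}
    chrom_gene_ids: dict[str, list[str]] = {}
    for c in range(1, config.n_chrom + 1):
        chrom = f"chr{c}"
        ids = [f"{chrom}g{r:04d}" for r in range(config.genes_per_chrom)]
        chrom_gene_ids[chrom] = ids
        for gid in ids:
            cds[gid] = random_cds(config.codons_per_gene, rng)

    truth: list[dict] = []
    # insertions[chrom]: original-rank position -> list of new gene ids
    insertions: dict[str, dict[int, list[str]]] = {}

    for event in config.segmental_events:
        copies = []
        for k, rank in enumerate(event.source_ranks):
            source_id = chrom_gene_ids[event.chrom][rank]
            copy_id = f"{source_id}.s"
            cds[copy_id] = plant_ks(cds[source_id], event.target_ks, rng)
            copies.append(copy_id)
            truth.append({"gene_id": copy_id, "source_gene_id": source_id,
                          "event_type": "segmental", "planted_ks": event.target_ks})
        insertions.setdefault(event.chrom, {})[event.insert_rank] = copies

    for event in config.tandem_events:
        source_id = chrom_gene_ids[event.chrom][event.source_rank]
        copies = []
        for k in range(1, event.copies + 1):
            copy_id = f"{source_id}.t{k}"
            cds[copy_id] = plant_ks(cds[source_id], event.target_ks, rng)
            copies.append(copy_id)
            truth.append({"gene_id": copy_id, "source_gene_id": source_id,
                          "event_type": "tandem", "planted_ks": event.target_ks})
        insertions.setdefault(event.chrom, {})[event.source_rank + 1] = copies

    # splice insertions (descending position so earlier indices stay valid),
    # then lay out coordinates left to right with fixed intergenic spacing
    gene_len = 3 * (config.codons_per_gene + 1)
    records = []
    strands = {}
    for chrom in sorted(chrom_gene_ids):
        ids = list(chrom_gene_ids[chrom])
        for pos in sorted(insertions.get(chrom, {}), reverse=True):
            ids[pos:pos] = insertions[chrom][pos]
        for rank, gid in enumerate(ids):
            start = 1 + rank * (gene_len + INTERGENIC_BP)
            strands[gid] = "+" if rng.random() < 0.5 else "-"
            records.append((gid, chrom, start, start + gene_len - 1, strands[gid]))

    genes = assign_ranks(records)
    proteins = {gid: translate_cds(cds[gid]) for gid in cds}
    genome = Genome(genes=genes, cds=cds, proteins=proteins)
    genome.validate()

    domains: dict[str, tuple[str, ...]] = {}
    for gene_id, architecture in config.rgene_assignments.items():
        if gene_id not in genome:
            raise ValueError(f"rgene assignment to unknown gene {gene_id}")
        domains[gene_id] = tuple(architecture)
    truth_rgenes = [{"gene_id": gid, "domains": ",".join(arch)}
                    for gid, arch in sorted(domains.items())]
    return SimResult(genome=genome, domains=domains,
                     truth_duplications=truth, truth_rgenes=truth_rgenes)


def simulate_genome(config: SimConfig, outdir: str | os.PathLike) -> dict[str, Path]:
    """Generate a genome and write GFF3/FASTA/TSV files plus the truth table."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result = build_genome(config)
    paths = {
        "gff3": outdir / "genes.gff3",
        "cds": outdir / "cds.fasta",
        "proteins": outdir / "proteins.fasta",
        "domains": outdir / "domains.tsv",
        "truth_duplications": outdir / "truth_duplications.tsv",
        "truth_rgenes": outdir / "truth_rgenes.tsv",
    }
    io_formats.write_gff3(result.genome.genes, paths["gff3"])
    ordered = sorted(result.genome.cds)
    io_formats.write_fasta({g: result.genome.cds[g] for g in ordered}, paths["cds"])
    io_formats.write_fasta({g: result.genome.proteins[g] for g in ordered}, paths["proteins"])
    io_formats.write_domain_table(result.domains, paths["domains"])
    io_formats.write_tsv(result.truth_duplications, paths["truth_duplications"],
                         ["gene_id", "source_gene_id", "event_type", "planted_ks"])
    io_formats.write_tsv(result.truth_rgenes, paths["truth_rgenes"],
                         ["gene_id", "domains"])
    return paths


def canonical_config(seed: int = 0) -> SimConfig:
    """The reference test genome: one distant segmental block (Ks 0.1), one
    3-copy tandem array (Ks 0.05), one near-source segmental block whose
    genes qualify as both segmental and tandem, and 12 R genes covering all
    11 families."""
    rgenes = {}
    for i, fam in enumerate(FAMILIES):
        rgenes[f"chr2g{30 + i:04d}"] = CANONICAL_ARCHITECTURES[fam]
    rgenes["chr1g0010"] = CANONICAL_ARCHITECTURES["TNL"]  # inside the segmental source run
    return SimConfig(
        n_chrom=3,
        genes_per_chrom=60,
        codons_per_gene=150,
        segmental_events=[
            SegmentalEvent("chr1", 10, 6, 40, 0.10),
            SegmentalEvent("chr3", 5, 6, 12, 0.10),  # copies land 7 ranks away -> "both"
        ],
        tandem_events=[TandemEvent("chr2", 20, 3, 0.05)],
        rgene_assignments=rgenes,
        seed=seed,
    )
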