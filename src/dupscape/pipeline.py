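"""End-to-end orchestration: homology -> Ks -> synteny -> classification ->
R genes -> report, with provenance-stamped TSV outputs and an output
validator that re-checks every invariant from the emitted files alone."""

from __future__ import annotations

import hashlib
import json
import logging
import math
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import __version__, io_formats
from .classify import DupConfig, classify, duplication_percentages, round1, \
    segmental_genes, tandem_genes
from .collinearity import DEFAULT_MAX_GAP, DEFAULT_MIN_BLOCK_ANCHORS, build_anchors, \
    chain_anchors, filter_blocks_by_ks
from .homology import all_vs_all, rbh_pairs, read_hits_tsv
from .ks import OK, ks_distribution, ks_for_pairs
from .model import Genome, validate_domain_table
from .rgenes import classify_rgenes, family_duplication_table, rgene_summary, window_counts

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    gff3: str
    cds: str
    proteins: str
    domains: str
    outdir: str
    hits_tsv: str | None = None          # precomputed hits bypass the aligner
    ks_max: float = 0.2
    tandem_max_gene_distance: int = 10
    min_block_anchors: int = DEFAULT_MIN_BLOCK_ANCHORS
    max_gap: int = DEFAULT_MAX_GAP
    ks_mode: str = "median"              # median | all_anchors block Ks filter
    min_score: int = 50
    prefilter_k: int = 6
    window: int = 100_000
    stride: int = 100_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ks_mode not in ("median", "all_anchors"):
            raise ValueError("ks_mode must be 'median' or 'all_anchors'")
        for name in ("ks_max", "min_block_anchors", "max_gap", "window", "stride"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def config_hash(self) -> str:
        """Hash of the analysis parameters (file locations excluded, so runs
        on the same inputs into different directories stamp identically)."""
        params = {k: v for k, v in vars(self).items()
                  if k not in ("gff3", "cds", "proteins", "domains", "hits_tsv", "outdir")}
        payload = yaml.safe_dump(params, sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class RunReport:
    config_hash: str
    seed: int
    version: str
    counts: dict = field(default_factory=dict)
    duplication_summary: dict = field(default_factory=dict)
    rgene_summary: dict = field(default_factory=dict)
    family_table: list = field(default_factory=list)


def run_pipeline(config: PipelineConfig, genome: Genome | None = None,
                 domains: Mapping[str, tuple[str, ...]] | None = None) -> RunReport:
    """Run all stages in order and write the stage TSVs under config.outdir."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stamp = [f"dupscape {__version__}", f"config_hash {config.config_hash()}",
             f"seed {config.seed}"]

    t0 = time.perf_counter()
    if genome is None:
        genome = io_formats.load_genome(config.gff3, config.cds, config.proteins)
    if domains is None:
        domains = io_formats.read_domain_table(config.domains)
    validate_domain_table(domains, genome)
    logger.info("loaded %d genes on %d chromosomes (%.1fs)", len(genome.genes),
                len(genome.chromosomes), time.perf_counter() - t0)
    io_formats.write_tsv(
        [{"gene_id": g.gene_id, "chrom": g.chrom, "start": g.start, "end": g.end,
          "strand": g.strand, "rank": g.rank} for g in genome.genes],
        outdir / "genes.tsv",
        ["gene_id", "chrom", "start", "end", "strand", "rank"], stamp)

    # --- homology ---
    t0 = time.perf_counter()
    if config.hits_tsv:
        hits = read_hits_tsv(config.hits_tsv)
        hit_rows = [{"query": q, "subject": s, "score": sc} for q, s, sc in hits]
    else:
        results = all_vs_all(genome, k=config.prefilter_k, min_score=config.min_score)
        hits = results
        hit_rows = [{"query": r.query_id, "subject": r.subject_id, "score": r.score}
                    for r in results]
    rbh = rbh_pairs(hits)
    logger.info("homology: %d hits, %d RBH pairs (%.1fs)", len(hit_rows), len(rbh),
                time.perf_counter() - t0)
    io_formats.write_tsv(hit_rows, outdir / "hits.tsv", ["query", "subject", "score"], stamp)
    io_formats.write_tsv([{"gene_a": a, "gene_b": b, "score": s} for a, b, s in rbh],
                         outdir / "rbh_pairs.tsv", ["gene_a", "gene_b", "score"], stamp)

    # --- Ks for all hit pairs (RBH subset feeds the distribution) ---
    t0 = time.perf_counter()
    all_pairs = sorted({(min(r["query"], r["subject"]), max(r["query"], r["subject"]))
                        for r in hit_rows})
    estimates = ks_for_pairs(all_pairs, genome)
    est_by_pair = {(e.gene_a, e.gene_b): e for e in estimates}
    io_formats.write_tsv(
        [{"gene_a": e.gene_a, "gene_b": e.gene_b, "n_codons": e.n_codons,
          "S": round(e.S, 4), "N": round(e.N, 4), "Sd": round(e.Sd, 4),
          "Nd": round(e.Nd, 4),
          "ks": round(e.ks, 6) if e.ks_flag == OK else "NA",
          "ka": round(e.ka, 6) if e.ka_flag == OK else "NA",
          "ks_flag": e.ks_flag, "ka_flag": e.ka_flag} for e in estimates],
        outdir / "ks.tsv",
        ["gene_a", "gene_b", "n_codons", "S", "N", "Sd", "Nd", "ks", "ka",
         "ks_flag", "ka_flag"], stamp)
    rbh_estimates = [est_by_pair[(a, b)] for a, b, _ in rbh if (a, b) in est_by_pair]
    defined_rbh = [e for e in rbh_estimates if e.ks_defined]
    if defined_rbh:
        dist = ks_distribution(defined_rbh)
        io_formats.write_tsv(
            [{"bin_start": round(float(dist.bin_edges[i]), 3),
              "bin_end": round(float(dist.bin_edges[i + 1]), 3),
              "count": int(dist.counts[i])} for i in range(len(dist.counts))],
            outdir / "ks_histogram.tsv", ["bin_start", "bin_end", "count"], stamp)
        io_formats.write_tsv([{"peak_ks": round(p, 4)} for p in dist.peaks],
                             outdir / "ks_peaks.tsv", ["peak_ks"], stamp)
    logger.info("ks: %d estimates (%.1fs)", len(estimates), time.perf_counter() - t0)

    # --- collinearity ---
    t0 = time.perf_counter()
    pairs_with_ks = [(e.gene_a, e.gene_b, e.ks if e.ks_defined else float("nan"))
                     for e in estimates]
    anchors = build_anchors(pairs_with_ks, genome.genes)
    blocks = chain_anchors(anchors, config.min_block_anchors, config.max_gap)
    if config.ks_mode == "median":
        kept = filter_blocks_by_ks(blocks, config.ks_max)
    else:
        kept = [b for b in blocks
                if all(a.ks_defined and a.ks < config.ks_max for a in b.anchors)]
    block_rows = []
    block_membership: dict[str, list[int]] = {}
    for i, block in enumerate(blocks):
        kept_flag = block in kept
        block_rows.append({
            "block_id": i, "chrom": block.chrom, "orientation": block.orientation,
            "n_anchors": block.n_anchors,
            "median_ks": round(block.median_ks, 6) if not math.isnan(block.median_ks) else "NA",
            "kept": int(kept_flag),
            "anchors": ";".join(f"{a.gene_a}|{a.gene_b}" for a in block.anchors)})
        if kept_flag:
            for g in block.gene_ids:
                block_membership.setdefault(g, []).append(i)
    io_formats.write_tsv(block_rows, outdir / "blocks.tsv",
                         ["block_id", "chrom", "orientation", "n_anchors", "median_ks",
                          "kept", "anchors"], stamp)
    _write_collinearity_text(blocks, kept, outdir / "collinearity.txt", stamp)
    io_formats.write_tsv(
        [{"gene_a": a.gene_a, "gene_b": a.gene_b, "chrom": a.chrom,
          "rank_a": a.rank_a, "rank_b": a.rank_b,
          "ks": round(a.ks, 6) if a.ks_defined else "NA"} for a in anchors],
        outdir / "anchors.tsv", ["gene_a", "gene_b", "chrom", "rank_a", "rank_b", "ks"],
        stamp)
    logger.info("synteny: %d anchors, %d blocks (%d kept) (%.1fs)", len(anchors),
                len(blocks), len(kept), time.perf_counter() - t0)

    # --- duplication classification ---
    dup_config = DupConfig(config.ks_max, config.tandem_max_gene_distance)
    seg_set = segmental_genes(kept)
    tandem_map = tandem_genes(pairs_with_ks, genome.genes, dup_config)
    calls = classify(seg_set, set(tandem_map), genome.genes,
                     block_membership=block_membership, tandem_partners=tandem_map)
    io_formats.write_tsv(
        [{"gene_id": c.gene_id, "label": c.label,
          "block_ids": ";".join(map(str, c.block_ids)),
          "tandem_partners": ";".join(c.tandem_partners)} for c in calls],
        outdir / "duplication_calls.tsv",
        ["gene_id", "label", "block_ids", "tandem_partners"], stamp)
    dup_summary = duplication_percentages(calls, len(genome.genes))

    # --- R genes ---
    rcalls = classify_rgenes(domains)
    io_formats.write_tsv([{"gene_id": c.gene_id, "family": c.family} for c in rcalls],
                         outdir / "rgene_calls.tsv", ["gene_id", "family"], stamp)
    family_table = family_duplication_table(rcalls, calls)
    io_formats.write_tsv(family_table, outdir / "rgene_family_duplication.tsv",
                         ["family", "n_total", "n_segmental", "n_tandem", "n_local",
                          "pct_segmental", "pct_tandem", "pct_local"], stamp)
    r_summary = rgene_summary(rcalls, len(genome.genes))
    windows = window_counts(genome.genes, rcalls, config.window, config.stride)
    io_formats.write_tsv(windows, outdir / "rgene_windows.tsv",
                         ["family", "chrom", "window_start", "window_end", "count"], stamp)
    with open(outdir / "rgene_windows.bed", "w") as bed:
        for row in sorted(windows, key=lambda r: (r["chrom"], r["window_start"], r["family"])):
            bed.write(f"{row['chrom']}\t{row['window_start'] - 1}\t{row['window_end']}\t"
                      f"{row['family']}\t{row['count']}\n")

    # --- report ---
    report = RunReport(
        config_hash=config.config_hash(), seed=config.seed, version=__version__,
        counts={
            "total_genes": len(genome.genes), "n_hits": len(hit_rows),
            "n_rbh_pairs": len(rbh), "n_ks_defined": sum(e.ks_defined for e in estimates),
            "n_anchors": len(anchors), "n_blocks": len(blocks),
            "n_blocks_kept": len(kept),
            "n_anchor_pairs_kept": sum(b.n_anchors for b in kept),
        },
        duplication_summary=dup_summary,
        rgene_summary=r_summary,
        family_table=family_table,
    )
    with open(outdir / "report.json", "w") as handle:
        json.dump(report.__dict__, handle, indent=2, sort_keys=True)
        handle.write("\n")
    _write_summary_text(report, outdir / "summary.txt")
    return report


def _write_collinearity_text(blocks, kept, path, stamp) -> None:
    """MCScanX-like human-readable block listing."""
    with open(path, "w") as handle:
        for line in stamp:
            handle.write(f"## {line}\n")
        for i, block in enumerate(blocks):
            median = block.median_ks
            handle.write(f"## Alignment {i}: score={block.n_anchors} chrom={block.chrom} "
                         f"orientation={block.orientation} "
                         f"median_ks={'NA' if math.isnan(median) else round(median, 4)} "
                         f"kept={int(block in kept)}\n")
            for j, a in enumerate(block.anchors):
                ks_str = "NA" if not a.ks_defined else f"{a.ks:.4f}"
                handle.write(f"{i}-{j:>4}:\t{a.gene_a}\t{a.gene_b}\t{ks_str}\n")


def _write_summary_text(report: RunReport, path) -> None:
    d = report.duplication_summary
    r = report.rgene_summary
    with open(path, "w") as handle:
        handle.write(f"# dupscape {report.version} run summary "
                     f"(config {report.config_hash}, seed {report.seed})\n")
        for key, value in sorted(report.counts.items()):
            handle.write(f"{key}\t{value}\n")
        handle.write(f"segmental_genes\t{d['n_segmental']}\t{d['pct_segmental']}%\n")
        handle.write(f"tandem_genes\t{d['n_tandem']}\t{d['pct_tandem']}%\n")
        handle.write(f"tandem_also_segmental\t{d['n_both']}\t{d['pct_overlap_of_tandem']}%\n")
        handle.write(f"locally_duplicated\t{d['n_local']}\t{d['pct_local']}%\n")
        handle.write(f"r_genes\t{r['n_rgenes']}\t{r['pct_of_genome']}%\n")


def validate_outputs(output_dir: str | Path) -> list[str]:
    """Re-check module invariants from a completed run directory.

    Returns a list of violation messages (empty = pass).
    """
    outdir = Path(output_dir)
    violations: list[str] = []

    def load(name: str) -> pd.DataFrame:
        return io_formats.read_tsv(outdir / name)

    genes = load("genes.tsv")
    for chrom, group in genes.groupby("chrom"):
        ranks = sorted(group["rank"])
        if ranks != list(range(len(group))):
            violations.append(f"ranks on {chrom} are not a contiguous 0..n-1 permutation")
        by_start = group.sort_values(["start", "gene_id"])["rank"].tolist()
        if by_start != sorted(by_start):
            violations.append(f"rank order on {chrom} disagrees with start coordinates")
    if genes["gene_id"].duplicated().any():
        violations.append("duplicate gene_id in genes.tsv")

    rank_of = dict(zip(genes["gene_id"], genes["rank"]))
    blocks = load("blocks.tsv")
    for row in blocks.itertuples(index=False):
        pairs = [tuple(p.split("|")) for p in str(row.anchors).split(";") if p]
        ra = [rank_of.get(a) for a, _ in pairs]
        rb = [rank_of.get(b) for _, b in pairs]
        if any(r is None for r in ra + rb):
            violations.append(f"block {row.block_id}: anchor gene missing from genes.tsv")
            continue
        if ra != sorted(ra) or len(set(ra)) != len(ra):
            violations.append(f"block {row.block_id}: rank_a not strictly increasing")
        ordered = sorted(rb) if row.orientation == "ascending" else sorted(rb, reverse=True)
        if rb != ordered or len(set(rb)) != len(rb):
            violations.append(f"block {row.block_id}: rank_b not {row.orientation}")

    calls = load("duplication_calls.tsv")
    if len(calls) != len(genes):
        violations.append("duplication_calls.tsv row count differs from genes.tsv")
    if not set(calls["label"]) <= {"segmental", "tandem", "both", "none"}:
        violations.append("unexpected duplication label")

    with open(outdir / "report.json") as handle:
        report = json.load(handle)
    d = report["duplication_summary"]
    tally = calls["label"].value_counts().to_dict()
    expected = {
        "n_segmental": tally.get("segmental", 0) + tally.get("both", 0),
        "n_tandem": tally.get("tandem", 0) + tally.get("both", 0),
        "n_both": tally.get("both", 0),
        "n_local": len(calls) - tally.get("none", 0),
    }
    for key, value in expected.items():
        if d.get(key) != value:
            violations.append(f"report {key}={d.get(key)} but calls give {value}")
    total = d["total_genes"]
    for num_key, pct_key, denom in (
            ("n_segmental", "pct_segmental", total),
            ("n_tandem", "pct_tandem", total),
            ("n_both", "pct_overlap_of_tandem", d["n_tandem"]),
            ("n_local", "pct_local", total)):
        if denom:
            recomputed = round1(100.0 * d[num_key] / denom)
            if d[pct_key] != recomputed:
                violations.append(f"report {pct_key}={d[pct_key]} but recomputes to {recomputed}")

    rcalls = load("rgene_calls.tsv")
    n_rgenes = int((rcalls["family"] != "none").sum())
    if report["rgene_summary"]["n_rgenes"] != n_rgenes:
        violations.append("R-gene total in report disagrees with rgene_calls.tsv")
    windows = load("rgene_windows.tsv")
    if len(windows):
        per_family_windows = windows.groupby("family")["count"].sum().to_dict()
        per_family_calls = rcalls[rcalls["family"] != "none"].groupby("family").size().to_dict()
        if per_family_windows != per_family_calls:
            violations.append("window counts do not conserve per-family totals")
    return violations
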