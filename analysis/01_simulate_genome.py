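"""Generate the study genome: a synthetic multi-chromosome genome with
planted duplications and R genes, standing in for a real assembly.

Writes results/data/ (GFF3, CDS and protein FASTA, domain table, truth
tables) and prints what was planted.
"""

from pathlib import Path

from dupscape.simulate import canonical_config, simulate_genome

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    config = canonical_config(seed=1)
    paths = simulate_genome(config, ROOT / "results" / "data")
    print(f"simulated {config.n_chrom} chromosomes x {config.genes_per_chrom} genes "
          f"({config.codons_per_gene} codons each), seed {config.seed}")
    for event in config.segmental_events:
        print(f"  planted segmental block: {event.block_len_genes} genes on "
              f"{event.chrom}, source rank {event.source_start_rank}, inserted at "
              f"rank {event.insert_rank}, target Ks {event.target_ks}")
    for event in config.tandem_events:
        print(f"  planted tandem array: {event.copies} copies of rank "
              f"{event.source_rank} on {event.chrom}, target Ks {event.target_ks}")
    print(f"  planted R genes: {len(config.rgene_assignments)}")
    for key, path in paths.items():
        print(f"  wrote {key}: {path.relative_to(ROOT)}")


if __name__ == "__main__":
    main()
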