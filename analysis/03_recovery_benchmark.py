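"""Benchmark the estimator and the classifier against planted truth.

Sweeps target Ks values and reports bias of the NG86 + Jukes-Cantor
estimate over 200 planted 300-codon gene pairs per target, plus the
duplication-class recovery on the study genome.  Writes
results/ks_recovery.tsv and results/duplication_recovery.tsv.
"""

from pathlib import Path

import numpy as np

from dupscape import io_formats
from dupscape.ks import ks_for_pairs
from dupscape.simulate import SimConfig, TandemEvent, build_genome

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    rows = []
    for i, target in enumerate((0.05, 0.1, 0.2, 0.5)):
        events = [TandemEvent(f"chr{c}", r, 1, target)
                  for c in range(1, 5) for r in range(50)]
        config = SimConfig(n_chrom=4, genes_per_chrom=50, codons_per_gene=300,
                           tandem_events=events, seed=1000 + i)
        result = build_genome(config)
        pairs = [(r["source_gene_id"], r["gene_id"]) for r in result.truth_duplications]
        values = [e.ks for e in ks_for_pairs(pairs, result.genome) if e.ks_defined]
        rows.append({"target_ks": target, "n_pairs": len(values),
                     "mean_ks": round(float(np.mean(values)), 4),
                     "sd_ks": round(float(np.std(values, ddof=1)), 4),
                     "bias": round(float(np.mean(values)) - target, 4)})
        print(f"target {target}: mean {rows[-1]['mean_ks']} "
              f"(sd {rows[-1]['sd_ks']}, bias {rows[-1]['bias']:+})")
    io_formats.write_tsv(rows, ROOT / "results" / "ks_recovery.tsv",
                         ["target_ks", "n_pairs", "mean_ks", "sd_ks", "bias"])

    # duplication recovery on the study genome (needs 02 outputs)
    calls_path = ROOT / "results" / "pipeline" / "duplication_calls.tsv"
    truth_path = ROOT / "results" / "data" / "truth_duplications.tsv"
    if calls_path.exists() and truth_path.exists():
        calls = io_formats.read_tsv(calls_path)
        truth = io_formats.read_tsv(truth_path)
        called = set(calls.loc[calls["label"] != "none", "gene_id"])
        planted = set(truth["gene_id"]) | set(truth["source_gene_id"])
        tp = len(called & planted)
        rows = [{"metric": "precision", "value": round(tp / len(called), 4) if called else 0.0},
                {"metric": "recall", "value": round(tp / len(planted), 4) if planted else 0.0}]
        io_formats.write_tsv(rows, ROOT / "results" / "duplication_recovery.tsv",
                             ["metric", "value"])
        print(f"locally-duplicated gene recovery: precision {rows[0]['value']}, "
              f"recall {rows[1]['value']}")
    else:
        print("run 02_run_pipeline.py first for the duplication-recovery table")


if __name__ == "__main__":
    main()
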