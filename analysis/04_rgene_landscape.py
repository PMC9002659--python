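"""Summarise the R-gene landscape of the simulated genome.

Reads the pipeline outputs and prints which families were recovered, how
many of each are locally duplicated, and where R genes cluster along the
chromosomes (100-kb windows).
"""

from pathlib import Path

from dupscape import io_formats

ROOT = Path(__file__).resolve().parents[1]
PIPELINE = ROOT / "results" / "pipeline"


def main() -> None:
    table = io_formats.read_tsv(PIPELINE / "rgene_family_duplication.tsv")
    print("family  total  segmental  tandem  local  pct_local")
    for row in table.itertuples(index=False):
        if row.n_total:
            print(f"{row.family:<10}{row.n_total:>4}{row.n_segmental:>9}"
                  f"{row.n_tandem:>8}{row.n_local:>7}{row.pct_local:>10}")
    windows = io_formats.read_tsv(PIPELINE / "rgene_windows.tsv")
    print(f"\n{len(windows)} non-empty (family, 100-kb window) cells; "
          f"densest window:")
    top = windows.sort_values("count", ascending=False).iloc[0]
    print(f"  {top['chrom']}:{top['window_start']}-{top['window_end']} "
          f"{top['family']} x{top['count']}")


if __name__ == "__main__":
    main()
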