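"""Readers/writers for GFF3 gene models, FASTA sequences, and TSV tables."""

from __future__ import annotations

import os
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from gffutils.feature import feature_from_line

from .model import DOMAIN_VOCABULARY, Gene, Genome, assign_ranks

# IUPAC nucleotide + amino-acid one-letter codes (selenocysteine/pyrrolysine
# included) plus the stop symbol.
_IUPAC_CHARS = frozenset("ABCDEFGHIKLMNPQRSTUVWXYZ*")


def read_gff3(path: str | os.PathLike) -> list[Gene]:
    """Load gene-type features from a GFF3 file.

    Only ``gene`` features are read (the analysis is gene-level); ranks are
    assigned per chromosome by start coordinate, ties by gene_id.  A feature
    without an ID attribute or a repeated ID is a hard error.
    """
    records: list[tuple[str, str, int, int, str]] = []
    seen: set[str] = set()
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            feature = feature_from_line(line)
            if feature.featuretype != "gene":
                continue
            ids = feature.attributes.get("ID", [])
            if not ids:
                raise ValueError(f"{path}: line {lineno}: gene feature without ID attribute")
            gene_id = ids[0]
            if gene_id in seen:
                raise ValueError(f"{path}: duplicate gene ID {gene_id}")
            seen.add(gene_id)
            strand = feature.strand if feature.strand in ("+", "-") else "+"
            records.append((gene_id, feature.seqid, feature.start, feature.end, strand))
    return assign_ranks(records)


def write_gff3(genes: Iterable[Gene], path: str | os.PathLike,
               header_comments: Sequence[str] = ()) -> None:
    with open(path, "w") as handle:
        handle.write("##gff-version 3\n")
        for comment in header_comments:
            handle.write(f"# {comment}\n")
        ordered = sorted(genes, key=lambda g: (g.chrom, g.rank))
        for g in ordered:
            handle.write(
                f"{g.chrom}\tdupscape\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\tID={g.gene_id}\n"
            )


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    """Read FASTA into an id -> uppercase-sequence map.

    The id is the first whitespace-delimited header token.  Duplicate ids,
    an empty file, or non-IUPAC sequence characters are errors.
    """
    sequences: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in sequences:
            raise ValueError(f"{path}: duplicate FASTA ID {record.id}")
        seq = str(record.seq).upper()
        bad = set(seq) - _IUPAC_CHARS
        if bad:
            raise ValueError(f"{path}: record {record.id} has non-IUPAC characters {sorted(bad)}")
        sequences[record.id] = seq
    if not sequences:
        raise ValueError(f"{path}: no FASTA records found")
    return sequences


def write_fasta(sequences: Mapping[str, str], path: str | os.PathLike, width: int = 60) -> None:
    with open(path, "w") as handle:
        for name in sequences:
            handle.write(f">{name}\n")
            seq = sequences[name]
            for i in range(0, len(seq), width):
                handle.write(seq[i:i + width] + "\n")


def write_tsv(records: Iterable[Mapping], path: str | os.PathLike, schema: Sequence[str],
              header_comments: Sequence[str] = ()) -> None:
    """Write records as a TSV with a header row, sorted by the first column.

    ``header_comments`` become leading ``#`` lines (provenance stamping).
    """
    frame = pd.DataFrame(list(records), columns=list(schema))
    frame = frame.sort_values(by=schema[0], kind="mergesort").reset_index(drop=True)
    with open(path, "w") as handle:
        for comment in header_comments:
            handle.write(f"# {comment}\n")
        frame.to_csv(handle, sep="\t", index=False)


def read_tsv(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def read_domain_table(path: str | os.PathLike) -> dict[str, tuple[str, ...]]:
    """Read a domain-architecture TSV (columns: gene_id, domains)."""
    frame = read_tsv(path)
    table: dict[str, tuple[str, ...]] = {}
    for row in frame.itertuples(index=False):
        labels = tuple(d for d in str(row.domains).split(",") if d)
        bad = set(labels) - DOMAIN_VOCABULARY
        if bad:
            raise ValueError(f"{path}: unknown domain labels for {row.gene_id}: {sorted(bad)}")
        table[str(row.gene_id)] = labels
    return table


def write_domain_table(domains: Mapping[str, Sequence[str]], path: str | os.PathLike,
                       header_comments: Sequence[str] = ()) -> None:
    records = [{"gene_id": gid, "domains": ",".join(labels)} for gid, labels in domains.items()]
    write_tsv(records, path, ["gene_id", "domains"], header_comments)


def load_genome(gff3_path, cds_path, protein_path) -> Genome:
    """Assemble and validate a Genome from its three input files."""
    genome = Genome(
        genes=read_gff3(gff3_path),
        cds=read_fasta(cds_path),
        proteins=read_fasta(protein_path),
    )
    genome.validate()
    return genome
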