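"""All-vs-all protein comparison and reciprocal-best-hit paralog pairing.

Global (end-to-end) affine-gap alignment under BLOSUM62 with gap open 11 /
extend 1 (a single-residue gap costs 12, BLAST convention).  An exact-6-mer
prefilter keeps all-vs-all tractable, and a score floor discards the rare
chance 6-mer collisions between unrelated sequences; reciprocal best hits
over the surviving scores define paralog pairs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

from Bio.Align import PairwiseAligner, substitution_matrices

from .model import Genome

DEFAULT_GAP_OPEN = 11
DEFAULT_GAP_EXTEND = 1
DEFAULT_PREFILTER_K = 6
DEFAULT_MIN_SCORE = 50


def _blosum62_x_neutral():
    """BLOSUM62 with X scored 0 against everything."""
    matrix = substitution_matrices.load("BLOSUM62").copy()
    alphabet = matrix.alphabet
    for ch in alphabet:
        matrix["X", ch] = 0.0
        matrix[ch, "X"] = 0.0
    return matrix


def make_aligner(gap_open: int = DEFAULT_GAP_OPEN,
                 gap_extend: int = DEFAULT_GAP_EXTEND) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = _blosum62_x_neutral()
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


@dataclass(frozen=True)
class AlignmentResult:
    query_id: str
    subject_id: str
    score: int
    aligned_query: str
    aligned_subject: str
    identity_fraction: float


def align_global(a: str, b: str, aligner: PairwiseAligner | None = None,
                 query_id: str = "query", subject_id: str = "subject") -> AlignmentResult:
    """Optimal global alignment of two protein sequences."""
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    if aligner is None:
        aligner = make_aligner()
    alignment = aligner.align(a.upper(), b.upper())[0]
    aligned_a, aligned_b = alignment[0], alignment[1]
    matches = sum(x == y and x != "-" for x, y in zip(aligned_a, aligned_b))
    return AlignmentResult(
        query_id=query_id,
        subject_id=subject_id,
        score=int(round(alignment.score)),
        aligned_query=aligned_a,
        aligned_subject=aligned_b,
        identity_fraction=matches / len(aligned_a),
    )


def _kmer_candidate_pairs(proteins: Mapping[str, str], k: int) -> set[tuple[str, str]]:
    index: dict[str, list[str]] = {}
    for name in sorted(proteins):
        seq = proteins[name]
        for i in range(len(seq) - k + 1):
            index.setdefault(seq[i:i + k], []).append(name)
    pairs: set[tuple[str, str]] = set()
    for members in index.values():
        unique = sorted(set(members))
        for i, a in enumerate(unique):
            for b in unique[i + 1:]:
                pairs.add((a, b))
    return pairs


def all_vs_all(genome: Genome | Mapping[str, str], k: int = DEFAULT_PREFILTER_K,
               min_score: int = DEFAULT_MIN_SCORE,
               aligner: PairwiseAligner | None = None) -> list[AlignmentResult]:
    """Align every unordered protein pair sharing an exact k-mer.

    Hits scoring below ``min_score`` are discarded; self-pairs excluded.
    """
    proteins = genome.proteins if isinstance(genome, Genome) else dict(genome)
    if len(proteins) < 2:
        raise ValueError("all-vs-all needs at least two proteins")
    if aligner is None:
        aligner = make_aligner()
    hits: list[AlignmentResult] = []
    for a, b in sorted(_kmer_candidate_pairs(proteins, k)):
        result = align_global(proteins[a], proteins[b], aligner=aligner,
                              query_id=a, subject_id=b)
        if result.score >= min_score:
            hits.append(result)
    return hits


def rbh_pairs(hits: Iterable[AlignmentResult | tuple[str, str, float]]
              ) -> list[tuple[str, str, int]]:
    """Reciprocal best hits: pairs that are mutually top-scoring.

    Score ties are broken toward the lexicographically smaller partner.
    Returns (gene_a, gene_b, score) with gene_a < gene_b, sorted.
    """
    best: dict[str, tuple[float, str]] = {}
    scores: dict[tuple[str, str], float] = {}
    for hit in hits:
        if isinstance(hit, AlignmentResult):
            a, b, score = hit.query_id, hit.subject_id, hit.score
        else:
            a, b, score = hit
        if a == b:
            continue
        key = (min(a, b), max(a, b))
        scores[key] = max(score, scores.get(key, float("-inf")))
        for gene, partner in ((a, b), (b, a)):
            incumbent = best.get(gene)
            # higher score wins; on a tie the smaller partner id wins
            if incumbent is None or (-score, partner) < (-incumbent[0], incumbent[1]):
                best[gene] = (score, partner)
    pairs = []
    for (a, b), score in scores.items():
        if best[a][1] == b and best[b][1] == a:
            pairs.append((a, b, int(score)))
    return sorted(pairs)


def read_hits_tsv(path) -> list[tuple[str, str, float]]:
    """Load externally computed hits (query, subject, score) from TSV."""
    import pandas as pd

    frame = pd.read_csv(path, sep="\t", comment="#")
    cols = list(frame.columns[:3])
    return [(str(q), str(s), float(sc)) for q, s, sc in frame[cols].itertuples(index=False)]
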