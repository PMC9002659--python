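"""Independent brute-force oracles used by the test suite.

Deliberately naive: Biopython translation per call, explicit enumeration of
codon neighbours, mutational pathways, alignments and anchor-chain subsets.
Nothing here shares code with the package implementation.
"""

from __future__ import annotations

import itertools

from Bio.Seq import Seq

BASES = "ACGT"
_AA = {"".join(c): str(Seq("".join(c)).translate()) for c in itertools.product(BASES, repeat=3)}


def naive_synonymous_sites(codon: str) -> float:
    """NG86 site count by explicit enumeration of the 9 single-base neighbours."""
    total = 0.0
    for pos in range(3):
        outcomes = []
        for base in BASES:
            if base == codon[pos]:
                continue
            neighbour = codon[:pos] + base + codon[pos + 1:]
            if _AA[neighbour] == "*":
                continue
            outcomes.append(_AA[neighbour] == _AA[codon])
        if outcomes:
            total += sum(outcomes) / len(outcomes)
    return total


def naive_pathway_differences(codon_a: str, codon_b: str):
    """Average (sd, nd) over all difference pathways; None if all hit stops."""
    positions = [i for i in range(3) if codon_a[i] != codon_b[i]]
    outcomes = []
    for order in itertools.permutations(positions):
        current = codon_a
        sd = nd = 0
        blocked = False
        for pos in order:
            following = current[:pos] + codon_b[pos] + current[pos + 1:]
            if _AA[following] == "*":
                blocked = True
                break
            if _AA[following] == _AA[current]:
                sd += 1
            else:
                nd += 1
            current = following
        if not blocked:
            outcomes.append((sd, nd))
    if not positions:
        return 0.0, 0.0
    if not outcomes:
        return None
    return (sum(o[0] for o in outcomes) / len(outcomes),
            sum(o[1] for o in outcomes) / len(outcomes))


def enumerate_global_alignments(a: str, b: str):
    """Yield every global alignment of a and b as (aligned_a, aligned_b)."""
    if not a and not b:
        yield "", ""
        return
    if a:
        for rest_a, rest_b in enumerate_global_alignments(a[1:], b):
            yield a[0] + rest_a, "-" + rest_b
    if b:
        for rest_a, rest_b in enumerate_global_alignments(a, b[1:]):
            yield "-" + rest_a, b[0] + rest_b
    if a and b:
        for rest_a, rest_b in enumerate_global_alignments(a[1:], b[1:]):
            yield a[0] + rest_a, b[0] + rest_b


def score_alignment(aligned_a: str, aligned_b: str, matrix, gap_open: int,
                    gap_extend: int) -> float:
    """Score one explicit alignment with affine gaps (first gap residue costs
    gap_open + gap_extend)."""
    score = 0.0
    in_gap_a = in_gap_b = False
    for x, y in zip(aligned_a, aligned_b):
        if x == "-":
            score -= gap_extend + (0 if in_gap_a else gap_open)
            in_gap_a, in_gap_b = True, False
        elif y == "-":
            score -= gap_extend + (0 if in_gap_b else gap_open)
            in_gap_a, in_gap_b = False, True
        else:
            score += matrix[x, y]
            in_gap_a = in_gap_b = False
    return score


def best_alignment_score_bruteforce(a: str, b: str, matrix, gap_open: int,
                                    gap_extend: int) -> float:
    return max(score_alignment(x, y, matrix, gap_open, gap_extend)
               for x, y in enumerate_global_alignments(a, b))


def best_chain_size_bruteforce(anchors, max_gap: int) -> int:
    """Largest valid collinear chain over (rank_a, rank_b) anchors, by trying
    every subset in every order-preserving arrangement."""
    best = 0
    n = len(anchors)
    for r in range(1, n + 1):
        for subset in itertools.combinations(range(n), r):
            chain = sorted((anchors[i] for i in subset), key=lambda a: a)
            ra = [a[0] for a in chain]
            rb = [a[1] for a in chain]
            if any(x >= y for x, y in zip(ra, ra[1:])):
                continue
            ascending = all(x < y for x, y in zip(rb, rb[1:]))
            descending = all(x > y for x, y in zip(rb, rb[1:]))
            if not (ascending or descending):
                continue
            if any(y - x > max_gap for x, y in zip(ra, ra[1:])):
                continue
            if any(abs(y - x) > max_gap for x, y in zip(rb, rb[1:])):
                continue
            best = max(best, r)
    return best


def rbh_bruteforce(scores: dict) -> set:
    """Mutual-best pairs from a {(a, b): score} table (a < b), ties toward
    the lexicographically smaller partner."""
    genes = sorted({g for pair in scores for g in pair})
    best = {}
    for gene in genes:
        partners = []
        for (a, b), score in scores.items():
            if gene == a:
                partners.append((-score, b))
            elif gene == b:
                partners.append((-score, a))
        if partners:
            best[gene] = min(partners)[1]
    return {(a, b) for (a, b) in scores
            if best.get(a) == b and best.get(b) == a}
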