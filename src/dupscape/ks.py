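"""Synonymous-rate (Ks) estimation for coding gene pairs.

Pipeline per pair: protein global alignment -> codon back-translation ->
Nei-Gojobori (1986) site/difference counting -> Jukes-Cantor correction.

NG86 counting, in brief: each codon position contributes a fractional
synonymous-site count equal to the fraction of its possible single-nucleotide
changes (stop-codon changes excluded from the possible set) that preserve the
amino acid; sites are averaged between the two sequences.  Codons differing
at d positions are resolved by averaging synonymous/nonsynonymous step counts
over all d! mutational pathways, excluding pathways that pass through a stop
codon.  The observed proportion ps = Sd/S is corrected for multiple hits with
the one-parameter Jukes-Cantor formula Ks = -(3/4)ln(1 - 4 ps/3), undefined
(saturated) at ps >= 3/4.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Sequence

import numpy as np
from scipy.signal import find_peaks
from scipy.stats import gaussian_kde
from Bio.Data import CodonTable

from .model import Genome, strip_stop, translate_cds

logger = logging.getLogger(__name__)

OK = "OK"
SATURATED = "SATURATED"
UNDEFINED = "UNDEFINED"

_NUCS = "ACGT"
_TABLE = CodonTable.unambiguous_dna_by_id[1]
STOP_CODONS = frozenset(_TABLE.stop_codons)
SENSE_CODONS = tuple(sorted(_TABLE.forward_table))
_AA = dict(_TABLE.forward_table)


def _amino_acid(codon: str) -> str | None:
    return _AA.get(codon)


@lru_cache(maxsize=None)
def synonymous_fractions(codon: str) -> tuple[float, float, float]:
    """Per-position fraction of possible (non-stop) changes that are synonymous."""
    if codon in STOP_CODONS:
        raise ValueError(f"stop codon {codon} has no site counts")
    fractions = []
    for pos in range(3):
        n_valid = 0
        n_syn = 0
        for nuc in _NUCS:
            if nuc == codon[pos]:
                continue
            alt = codon[:pos] + nuc + codon[pos + 1:]
            if alt in STOP_CODONS:
                continue
            n_valid += 1
            if _amino_acid(alt) == _amino_acid(codon):
                n_syn += 1
        fractions.append(n_syn / n_valid if n_valid else 0.0)
    return tuple(fractions)


def synonymous_sites(codon: str) -> float:
    """NG86 synonymous-site count of one codon (0..3)."""
    return sum(synonymous_fractions(codon))


@lru_cache(maxsize=None)
def pathway_differences(codon_a: str, codon_b: str) -> tuple[float, float, bool]:
    """Average (synonymous, nonsynonymous) step counts over mutational pathways.

    Pathways passing through a stop codon are excluded.  Returns
    (sd, nd, ok); ok is False when every pathway hits a stop, in which case
    the codon pair must be skipped.
    """
    if codon_a in STOP_CODONS or codon_b in STOP_CODONS:
        raise ValueError("stop codons are not compared")
    diff_positions = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff_positions:
        return 0.0, 0.0, True
    sd_total = 0.0
    nd_total = 0.0
    n_valid = 0
    for order in itertools.permutations(diff_positions):
        current = codon_a
        sd = nd = 0
        valid = True
        for pos in order:
            nxt = current[:pos] + codon_b[pos] + current[pos + 1:]
            if nxt in STOP_CODONS:
                valid = False
                break
            if _amino_acid(nxt) == _amino_acid(current):
                sd += 1
            else:
                nd += 1
            current = nxt
        if valid:
            sd_total += sd
            nd_total += nd
            n_valid += 1
    if n_valid == 0:
        return 0.0, 0.0, False
    return sd_total / n_valid, nd_total / n_valid, True


def jukes_cantor(p: float) -> float:
    """JC69 distance for an observed difference proportion p < 3/4."""
    if p >= 0.75:
        raise ValueError("Jukes-Cantor correction undefined at p >= 3/4")
    return -0.75 * math.log1p(-4.0 * p / 3.0)


@dataclass
class KsEstimate:
    gene_a: str
    gene_b: str
    n_codons: int = 0
    S: float = 0.0
    N: float = 0.0
    Sd: float = 0.0
    Nd: float = 0.0
    ps: float = float("nan")
    pn: float = float("nan")
    ks: float = float("nan")
    ka: float = float("nan")
    ks_flag: str = UNDEFINED
    ka_flag: str = UNDEFINED

    @property
    def ks_defined(self) -> bool:
        return self.ks_flag == OK


def codon_align(cds_a: str, cds_b: str, aligned_a: str, aligned_b: str,
                name_a: str = "a", name_b: str = "b") -> list[tuple[str, str]]:
    """Expand a protein alignment to aligned codon pairs.

    Columns where either side is a gap, or where a codon contains a
    non-ACGT base, are dropped.  The CDSs must translate to the
    gap-stripped aligned proteins (trailing stop codons are ignored).
    """
    cds_a = strip_stop(cds_a.upper())
    cds_b = strip_stop(cds_b.upper())
    for name, cds, aligned in ((name_a, cds_a, aligned_a), (name_b, cds_b, aligned_b)):
        protein = aligned.replace("-", "")
        if len(cds) != 3 * len(protein):
            raise ValueError(f"{name}: CDS length {len(cds)} does not match "
                             f"{len(protein)} aligned residues")
        if translate_cds(cds) != protein:
            raise ValueError(f"{name}: CDS does not translate to the aligned protein")
    pairs: list[tuple[str, str]] = []
    i = j = 0
    for col_a, col_b in zip(aligned_a, aligned_b):
        codon_a = codon_b = None
        if col_a != "-":
            codon_a = cds_a[3 * i:3 * i + 3]
            i += 1
        if col_b != "-":
            codon_b = cds_b[3 * j:3 * j + 3]
            j += 1
        if codon_a is None or codon_b is None:
            continue
        if set(codon_a) <= set(_NUCS) and set(codon_b) <= set(_NUCS):
            pairs.append((codon_a, codon_b))
    return pairs


def ng86(codon_pairs: Sequence[tuple[str, str]], gene_a: str = "a",
         gene_b: str = "b") -> KsEstimate:
    """Nei-Gojobori (1986) Ks/Ka estimate from aligned codon pairs."""
    est = KsEstimate(gene_a=gene_a, gene_b=gene_b)
    s_a = s_b = sd = nd = 0.0
    n_codons = 0
    for codon_x, codon_y in codon_pairs:
        step_sd, step_nd, ok = pathway_differences(codon_x, codon_y)
        if not ok:
            logger.debug("skipping codon pair %s/%s: all pathways hit stops",
                         codon_x, codon_y)
            continue
        s_a += synonymous_sites(codon_x)
        s_b += synonymous_sites(codon_y)
        sd += step_sd
        nd += step_nd
        n_codons += 1
    if n_codons == 0:
        return est
    est.n_codons = n_codons
    est.S = (s_a + s_b) / 2.0
    est.N = 3.0 * n_codons - est.S
    est.Sd = sd
    est.Nd = nd
    # 0/0 -> 0: no sites and no differences means no divergence to measure
    est.ps = sd / est.S if est.S > 0 else (0.0 if sd == 0 else float("nan"))
    est.pn = nd / est.N if est.N > 0 else (0.0 if nd == 0 else float("nan"))
    for p, value_attr, flag_attr in ((est.ps, "ks", "ks_flag"), (est.pn, "ka", "ka_flag")):
        if math.isnan(p):
            continue
        if p >= 0.75:
            setattr(est, flag_attr, SATURATED)
        else:
            setattr(est, value_attr, jukes_cantor(p))
            setattr(est, flag_attr, OK)
    return est


def ks_for_pairs(pairs: Iterable[tuple[str, str]], genome: Genome,
                 aligner=None) -> list[KsEstimate]:
    """Estimate Ks for gene pairs: align proteins, back-translate, count.

    Pairs whose CDS or protein is missing are flagged UNDEFINED and logged.
    """
    from .homology import align_global  # deferred: avoid import cycle

    estimates: list[KsEstimate] = []
    for gene_a, gene_b in pairs:
        missing = [g for g in (gene_a, gene_b)
                   if g not in genome.cds or g not in genome.proteins]
        if missing:
            logger.warning("missing CDS/protein for %s; Ks undefined", missing)
            estimates.append(KsEstimate(gene_a=gene_a, gene_b=gene_b))
            continue
        result = align_global(genome.proteins[gene_a], genome.proteins[gene_b],
                              aligner=aligner)
        codon_pairs = codon_align(genome.cds[gene_a], genome.cds[gene_b],
                                  result.aligned_query, result.aligned_subject,
                                  name_a=gene_a, name_b=gene_b)
        estimates.append(ng86(codon_pairs, gene_a=gene_a, gene_b=gene_b))
    return estimates


@dataclass
class KsDistribution:
    values: list[float]
    bin_edges: np.ndarray
    counts: np.ndarray
    peaks: list[float] = field(default_factory=list)


def ks_distribution(estimates: Sequence[KsEstimate | float], bin_width: float = 0.05,
                    max_ks: float = 3.0) -> KsDistribution:
    """Histogram (width 0.05 on [0, max_ks]) and KDE mode locations.

    Peaks are local maxima of a Gaussian kernel density with absolute
    bandwidth ``bin_width``, separated by at least two bandwidths, in
    ascending Ks order.
    """
    values = []
    for est in estimates:
        if isinstance(est, KsEstimate):
            if est.ks_defined:
                values.append(est.ks)
        elif math.isfinite(est):
            values.append(float(est))
    if not values:
        raise ValueError("no defined Ks estimates to build a distribution from")
    edges = np.arange(0.0, max_ks + bin_width / 2, bin_width)
    in_range = [v for v in values if 0.0 <= v <= max_ks]
    counts, _ = np.histogram(in_range, bins=edges)
    arr = np.asarray(values)
    if np.std(arr) < 1e-12:
        peaks = [float(arr[0])]
    else:
        kde = gaussian_kde(arr, bw_method=bin_width / np.std(arr, ddof=1))
        grid = np.arange(0.0, max_ks + bin_width / 10, bin_width / 10)
        density = kde(grid)
        step = grid[1] - grid[0]
        idx, _ = find_peaks(density, distance=max(1, int(round(2 * bin_width / step))))
        peaks = [float(grid[i]) for i in idx]
    return KsDistribution(values=values, bin_edges=edges, counts=counts, peaks=sorted(peaks))
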