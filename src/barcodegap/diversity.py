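"""Per-locus nucleotide diversity, variable-site counts and Tajima's D.

Tajima's D contrasts two estimators of the population mutation rate:
mean pairwise differences (Π) and the normalized segregating-site count
(S/a1).  Negative D means rare alleles are in excess relative to the
neutral expectation — the pattern reported for fast-evolving spacer
barcodes under weak constraint.  Indel columns never count toward S or Π;
only substitutions among {A,C,G,T} are scored, and ambiguous or missing
characters are excluded pairwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .io import LocusAlignment, NUCLEOTIDES

__all__ = [
    "DiversityResult",
    "segregating_sites",
    "nucleotide_diversity",
    "mean_pairwise_differences",
    "tajimas_d",
]


@dataclass
class DiversityResult:
    """Summary of within-alignment variation for one barcode region."""

    n: int  # sequences used
    L: int  # alignment columns
    S: int  # segregating (variable) sites, substitutions only
    pi: float  # nucleotide diversity per site
    tajima_D: float  # nan when undefined
    undefined_reason: str | None = None
    n_indel_columns: int = 0  # columns containing a gap, reported separately


def segregating_sites(aln: LocusAlignment) -> int:
    """Count columns with >=2 distinct nucleotides among {A,C,G,T}.

    Gap, N and ambiguity characters are ignored within a column; a column
    where all non-missing characters agree is invariant.
    """
    if aln.n < 2:
        raise ValueError("segregating_sites needs >=2 sequences")
    s = 0
    for col in range(aln.length):
        observed = {seq[col] for seq in aln.seqs if seq[col] in NUCLEOTIDES}
        if len(observed) >= 2:
            s += 1
    return s


def _indel_columns(aln: LocusAlignment) -> int:
    return sum(
        any(seq[col] == "-" for seq in aln.seqs) for col in range(aln.length)
    )


def _pair_diffs(seq_a: str, seq_b: str) -> tuple[int, int]:
    """(differences, comparable sites) over plain-nucleotide positions."""
    diffs = comp = 0
    for a, b in zip(seq_a, seq_b):
        if a in NUCLEOTIDES and b in NUCLEOTIDES:
            comp += 1
            if a != b:
                diffs += 1
    return diffs, comp


def nucleotide_diversity(aln: LocusAlignment) -> float:
    """π: mean per-site p-distance over all sequence pairs.

    Each pair is compared over its own comparable sites (pairwise
    deletion); pairs with zero comparable sites are skipped.
    """
    if aln.n < 2:
        raise ValueError("nucleotide_diversity needs >=2 sequences")
    total = 0.0
    used = 0
    for i in range(aln.n):
        for j in range(i + 1, aln.n):
            diffs, comp = _pair_diffs(aln.seqs[i], aln.seqs[j])
            if comp > 0:
                total += diffs / comp
                used += 1
    return total / used if used else math.nan


def mean_pairwise_differences(aln: LocusAlignment) -> float:
    """Π: mean pairwise difference count (not per site).

    Computed as the mean per-site pairwise p-distance rescaled by the
    alignment length, so sequences with scattered missing data contribute
    on the same footing as complete ones.
    """
    return nucleotide_diversity(aln) * aln.length


def tajimas_d(aln: LocusAlignment) -> DiversityResult:
    """Tajima's D with the standard (1989) constants.

    With n sequences, S segregating sites and Π mean pairwise differences:

        a1 = sum_{i=1}^{n-1} 1/i        a2 = sum 1/i^2
        b1 = (n+1)/(3(n-1))             b2 = 2(n^2+n+3)/(9n(n-1))
        c1 = b1 - 1/a1                  c2 = b2 - (n+2)/(a1 n) + a2/a1^2
        e1 = c1/a1                      e2 = c2/(a1^2 + a2)
        D  = (Π - S/a1) / sqrt(e1 S + e2 S (S-1))

    Undefined (nan, with a reason) when S = 0 or n < 4.
    """
    n = aln.n
    S = segregating_sites(aln)
    pi = nucleotide_diversity(aln)
    result = DiversityResult(
        n=n, L=aln.length, S=S, pi=pi, tajima_D=math.nan,
        n_indel_columns=_indel_columns(aln),
    )
    if n < 4:
        result.undefined_reason = f"need >=4 sequences, have {n}"
        return result
    if S == 0:
        result.undefined_reason = "no segregating sites"
        return result
    big_pi = pi * aln.length
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    var = e1 * S + e2 * S * (S - 1)
    result.tajima_D = (big_pi - S / a1) / math.sqrt(var)
    return result
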