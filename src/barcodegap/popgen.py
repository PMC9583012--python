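"""Pairwise Fst between species from a genotype matrix.

Calls are treated as haploid alleles: the accessions are inbred selfing
lines, so homozygous single-letter calls carry the allelic state directly.
Heterozygous (IUPAC) calls are excluded at that locus for that accession;
missing calls likewise.  Two estimators are provided: Nei's Gst
(heterozygosity partition) and the Weir–Cockerham variance-components
theta for haploid data.  By convention Fst in (0.05, 0.15) indicates
moderate-to-small differentiation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .io import GenotypeMatrix, NUCLEOTIDES

__all__ = ["FstResult", "pairwise_fst", "pairwise_fst_matrix", "fst_migration_consistency"]


@dataclass
class FstResult:
    """Per-locus and multi-locus Fst for one species pair."""

    species_pair: tuple[str, str]
    estimator: str
    per_locus: list[float]  # nan for loci where the estimator is undefined
    fst: float  # multi-locus, ratio of sums; may be slightly negative
    fst_clamped: float  # max(fst, 0), bounded to [0, 1]
    fst_mean_of_ratios: float  # mean of defined per-locus values, for comparison
    loci_used: int
    loci_undefined: int

    @property
    def interpretation(self) -> str:
        v = self.fst_clamped
        if math.isnan(v):
            return "undefined"
        if v < 0.05:
            return "little differentiation"
        if v < 0.15:
            return "moderate/small differentiation"
        if v < 0.25:
            return "moderately great differentiation"
        return "great differentiation"


def _haploid_counts(gm: GenotypeMatrix, accessions: Sequence[str]) -> list[dict[str, int]]:
    """Per-site allele counts over unambiguous homozygous calls."""
    rows = [gm.accessions.index(a) for a in accessions]
    out: list[dict[str, int]] = []
    for s in range(gm.n_sites):
        counts: dict[str, int] = {}
        for r in rows:
            c = gm.calls[r, s]
            if c in NUCLEOTIDES:
                counts[c] = counts.get(c, 0) + 1
        out.append(counts)
    return out


def _expected_het(counts: dict[str, int]) -> float:
    n = sum(counts.values())
    if n == 0:
        return math.nan
    return 1.0 - sum((c / n) ** 2 for c in counts.values())


def pairwise_fst(
    gm: GenotypeMatrix,
    species_a: str,
    species_b: str,
    estimator: str = "nei_gst",
) -> FstResult:
    """Fst between two species over all shared informative loci.

    ``nei_gst``: per locus ``(Ht - Hs)/Ht`` with Ht the expected
    heterozygosity of the pooled allele frequencies and Hs the mean
    within-species expected heterozygosity; multi-locus value is the
    ratio of sums ``sum(Ht - Hs)/sum(Ht)``.

    ``weir_cockerham``: haploid variance-components theta; per allele u,
    with r=2 populations of sizes n_i and allele frequencies p_iu,
    MSP = sum_i n_i (p_iu - pbar_u)^2 / (r-1) and
    MSG = sum_i n_i p_iu (1 - p_iu) / sum_i (n_i - 1); the
    between-population component is a = (MSP - MSG)/n_c with
    n_c = (sum n_i - sum n_i^2 / sum n_i)/(r-1), and
    theta = sum_u a / sum_u (a + MSG), summed over alleles and (for the
    multi-locus value) over loci.

    Loci where the denominator is zero (e.g. both species fixed for the
    same allele) are undefined and excluded; their count is reported.
    """
    if estimator not in ("nei_gst", "weir_cockerham"):
        raise ValueError(f"unknown estimator {estimator!r}")
    acc_a = gm.accessions_of(species_a)
    acc_b = gm.accessions_of(species_b)
    if len(acc_a) < 2 or len(acc_b) < 2:
        raise ValueError("each species needs >=2 accessions")
    counts_a = _haploid_counts(gm, acc_a)
    counts_b = _haploid_counts(gm, acc_b)

    per_locus: list[float] = []
    num_sum = 0.0
    den_sum = 0.0
    used = undefined = 0
    for ca, cb in zip(counts_a, counts_b):
        na, nb = sum(ca.values()), sum(cb.values())
        if na < 1 or nb < 1:
            per_locus.append(math.nan)
            undefined += 1
            continue
        if estimator == "nei_gst":
            pooled: dict[str, int] = dict(ca)
            for k, v in cb.items():
                pooled[k] = pooled.get(k, 0) + v
            ht = _expected_het(pooled)
            hs = 0.5 * (_expected_het(ca) + _expected_het(cb))
            num, den = ht - hs, ht
        else:
            num, den = _wc_components(ca, cb, na, nb)
        if den <= 0 or math.isnan(den):
            per_locus.append(math.nan)
            undefined += 1
            continue
        per_locus.append(num / den)
        num_sum += num
        den_sum += den
        used += 1
    if used == 0 or den_sum <= 0:
        fst = math.nan
    else:
        fst = num_sum / den_sum
    defined = [v for v in per_locus if not math.isnan(v)]
    return FstResult(
        species_pair=(species_a, species_b),
        estimator=estimator,
        per_locus=per_locus,
        fst=fst,
        fst_clamped=min(max(fst, 0.0), 1.0) if not math.isnan(fst) else math.nan,
        fst_mean_of_ratios=float(np.mean(defined)) if defined else math.nan,
        loci_used=used,
        loci_undefined=undefined,
    )


def _wc_components(ca: dict[str, int], cb: dict[str, int], na: int, nb: int) -> tuple[float, float]:
    """Summed (a, a+b) Weir–Cockerham haploid components over alleles."""
    if na < 2 or nb < 2:
        return math.nan, math.nan
    r = 2
    n_tot = na + nb
    n_c = (n_tot - (na**2 + nb**2) / n_tot) / (r - 1)
    alleles = set(ca) | set(cb)
    a_sum = ab_sum = 0.0
    for u in alleles:
        pa, pb = ca.get(u, 0) / na, cb.get(u, 0) / nb
        pbar = (na * pa + nb * pb) / n_tot
        msp = (na * (pa - pbar) ** 2 + nb * (pb - pbar) ** 2) / (r - 1)
        msg = (na * pa * (1 - pa) + nb * pb * (1 - pb)) / ((na - 1) + (nb - 1))
        a = (msp - msg) / n_c
        a_sum += a
        ab_sum += a + msg
    return a_sum, ab_sum


def pairwise_fst_matrix(
    gm: GenotypeMatrix, estimator: str = "nei_gst"
) -> pd.DataFrame:
    """All species-pair multi-locus Fst values as a tidy table."""
    species = gm.species_list()
    rows = []
    for i, sa in enumerate(species):
        for sb in species[i + 1 :]:
            res = pairwise_fst(gm, sa, sb, estimator=estimator)
            rows.append(
                {
                    "species_a": sa,
                    "species_b": sb,
                    "fst": res.fst,
                    "fst_clamped": res.fst_clamped,
                    "loci_used": res.loci_used,
                    "interpretation": res.interpretation,
                }
            )
    return pd.DataFrame(rows)


def fst_migration_consistency(fst: float) -> float:
    """Island-model migration estimate Nm = (1 - Fst)/(4 Fst).

    A naive equilibrium identity useful as an order-of-magnitude
    consistency check against dedicated gene-flow estimators; it is not a
    coalescent-based migration analysis.  Undefined for Fst outside the
    open interval (0, 1).
    """
    if not 0.0 < fst < 1.0 or math.isnan(fst):
        return math.nan
    return (1.0 - fst) / (4.0 * fst)
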