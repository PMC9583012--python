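"""Kimura two-parameter distances and barcoding-gap summaries.

The barcoding gap is the separation between the distribution of
within-species (intraspecific) and between-species (interspecific) pairwise
distances; distance-based identification works when the two distributions
barely overlap.  Distances here use the K2P model with pairwise deletion:
for each sequence pair only sites where both characters are plain
nucleotides are compared, so gaps, N and ambiguity codes act as missing
data rather than differences.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from .io import LocusAlignment, NUCLEOTIDES

__all__ = [
    "k2p_distance",
    "DistanceMatrix",
    "distance_matrix",
    "DistanceSummary",
    "distance_summary",
    "barcoding_gap_histogram",
]

_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")


def k2p_distance(seq_a: str, seq_b: str) -> tuple[float, int]:
    """K2P distance between two aligned sequences, with pairwise deletion.

    Returns ``(distance, comparable_sites)``.  Comparable sites are those
    where both characters are in ``{A,C,G,T}``.  With transition proportion
    P and transversion proportion Q over comparable sites,

        d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q)

    The distance is ``nan`` (undefined, e.g. saturated) when a log argument
    is non-positive or no sites are comparable; it is never silently zero.
    """
    if len(seq_a) != len(seq_b):
        raise ValueError(
            f"aligned sequences differ in length ({len(seq_a)} vs {len(seq_b)})"
        )
    n = transitions = transversions = 0
    for a, b in zip(seq_a, seq_b):
        if a not in NUCLEOTIDES or b not in NUCLEOTIDES:
            continue
        n += 1
        if a == b:
            continue
        if (a in _PURINES) == (b in _PURINES):
            transitions += 1
        else:
            transversions += 1
    if n == 0:
        return math.nan, 0
    p = transitions / n
    q = transversions / n
    w1 = 1.0 - 2.0 * p - q
    w2 = 1.0 - 2.0 * q
    if w1 <= 0.0 or w2 <= 0.0:
        return math.nan, n
    return -0.5 * math.log(w1) - 0.25 * math.log(w2) + 0.0, n


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix with per-pair site counts.

    Undefined (saturated or zero-overlap) pairs are stored as ``nan``.
    """

    accessions: list[str]
    d: np.ndarray
    comparable_sites: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        self.comparable_sites = np.asarray(self.comparable_sites, dtype=int)
        n = len(self.accessions)
        if self.d.shape != (n, n) or self.comparable_sites.shape != (n, n):
            raise ValueError("matrix shapes do not match accession count")

    @property
    def n(self) -> int:
        return len(self.accessions)

    def get(self, acc_a: str, acc_b: str) -> float:
        i, j = self.accessions.index(acc_a), self.accessions.index(acc_b)
        return float(self.d[i, j])

    def n_undefined_pairs(self) -> int:
        iu = np.triu_indices(self.n, k=1)
        return int(np.isnan(self.d[iu]).sum())

    def write_square_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("accession\t" + "\t".join(self.accessions) + "\n")
            for acc, row in zip(self.accessions, self.d):
                cells = ["nan" if np.isnan(v) else f"{v:.8f}" for v in row]
                fh.write(acc + "\t" + "\t".join(cells) + "\n")

    def write_phylip(self, path: str | Path) -> None:
        """Square PHYLIP distance format (names truncated/padded to 10)."""
        with open(path, "w") as fh:
            fh.write(f"{self.n}\n")
            for acc, row in zip(self.accessions, self.d):
                name = acc[:10].ljust(10)
                cells = " ".join("nan" if np.isnan(v) else f"{v:.8f}" for v in row)
                fh.write(f"{name} {cells}\n")


def distance_matrix(aln: LocusAlignment) -> DistanceMatrix:
    """All-pairs K2P distances for one alignment (pairwise deletion)."""
    if aln.n < 2:
        raise ValueError("distance matrix needs at least 2 accessions")
    n = aln.n
    d = np.zeros((n, n), dtype=float)
    sites = np.zeros((n, n), dtype=int)
    for i in range(n):
        sites[i, i] = sum(c in NUCLEOTIDES for c in aln.seqs[i])
        for j in range(i + 1, n):
            dist, ns = k2p_distance(aln.seqs[i], aln.seqs[j])
            d[i, j] = d[j, i] = dist
            sites[i, j] = sites[j, i] = ns
    return DistanceMatrix(list(aln.accessions), d, sites)


@dataclass
class DistanceSummary:
    """Intra-/interspecific distance distributions and the gap ratio.

    ``ratio = mean_intra / mean_inter`` is computed from the unrounded
    means; rounding (4 decimals for means, 3 significant figures for the
    ratio) is applied only at reporting time by :meth:`formatted`.
    Undefined pairwise distances are excluded and counted in
    ``n_undefined``.
    """

    intra: list[float]
    inter: list[float]
    mean_intra: float
    mean_inter: float
    ratio: float
    n_undefined: int = 0
    intra_pairs: list[tuple[str, str]] = field(default_factory=list)
    inter_pairs: list[tuple[str, str]] = field(default_factory=list)

    def formatted(self) -> dict[str, str]:
        def r4(x: float) -> str:
            return "NA" if math.isnan(x) else f"{x:.4f}"

        def sig3(x: float) -> str:
            if math.isnan(x):
                return "NA"
            if x == 0:
                return "0.000"
            return f"{x:.3g}"

        return {
            "mean_intraspecific_distance": r4(self.mean_intra),
            "mean_interspecific_distance": r4(self.mean_inter),
            "intra_inter_ratio": sig3(self.ratio),
        }


def distance_summary(dm: DistanceMatrix, species_of: Mapping[str, str]) -> DistanceSummary:
    """Partition defined pairwise distances into intra- and interspecific.

    Species represented by a single accession contribute no intraspecific
    pairs (they are not treated as zero).  With no conspecific pairs the
    intraspecific mean and the ratio are undefined (``nan``).
    """
    intra: list[float] = []
    inter: list[float] = []
    intra_pairs: list[tuple[str, str]] = []
    inter_pairs: list[tuple[str, str]] = []
    undefined = 0
    for i in range(dm.n):
        for j in range(i + 1, dm.n):
            acc_i, acc_j = dm.accessions[i], dm.accessions[j]
            v = dm.d[i, j]
            if math.isnan(v):
                undefined += 1
                continue
            if species_of[acc_i] == species_of[acc_j]:
                intra.append(float(v))
                intra_pairs.append((acc_i, acc_j))
            else:
                inter.append(float(v))
                inter_pairs.append((acc_i, acc_j))
    mean_intra = float(np.mean(intra)) if intra else math.nan
    mean_inter = float(np.mean(inter)) if inter else math.nan
    if intra and inter and mean_inter > 0:
        ratio = mean_intra / mean_inter
    else:
        ratio = math.nan
    return DistanceSummary(
        intra, inter, mean_intra, mean_inter, ratio, undefined, intra_pairs, inter_pairs
    )


def barcoding_gap_histogram(
    ds: DistanceSummary, bin_width: float
) -> dict[str, object]:
    """Bin the intra- and interspecific distance distributions.

    Returns bin edges over ``[0, max_distance]``, counts for each
    distribution, and an ``overlap`` flag that is true when some
    intraspecific distance is >= some interspecific distance — i.e. the
    barcoding gap is imperfect.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    values = ds.intra + ds.inter
    if not values:
        return {
            "bin_edges": np.array([0.0]),
            "intra_counts": np.array([], dtype=int),
            "inter_counts": np.array([], dtype=int),
            "overlap": False,
        }
    top = max(values)
    n_bins = max(1, math.ceil(top / bin_width + 1e-12))
    edges = np.arange(0.0, (n_bins + 1) * bin_width, bin_width)[: n_bins + 1]
    if edges[-1] < top:  # guard against float accumulation
        edges = np.append(edges, edges[-1] + bin_width)
    intra_counts, _ = np.histogram(ds.intra, bins=edges)
    inter_counts, _ = np.histogram(ds.inter, bins=edges)
    overlap = bool(ds.intra and ds.inter and max(ds.intra) >= min(ds.inter))
    return {
        "bin_edges": edges,
        "intra_counts": intra_counts,
        "inter_counts": inter_counts,
        "overlap": overlap,
    }
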