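"""Distance-based species identification: best match and best close match.

Every accession is treated in turn as a query against all remaining
barcodes.  Under *best match* the query is assigned the species of its
nearest neighbour(s); under *best close match* the assignment is attempted
only when the nearest distance is within a threshold derived from the
intraspecific distance distribution (conventionally its 95th percentile),
otherwise the query is unidentified.  Queries from singleton species are
excluded from the rates: no conspecific match exists for them, so they
cannot be identified correctly by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .distance import DistanceMatrix, DistanceSummary

__all__ = [
    "MatchOutcome",
    "MatchReport",
    "best_match",
    "intraspecific_threshold",
    "best_close_match",
    "bba_summary",
]

VERDICTS = ("correct", "incorrect", "ambiguous", "no_match")


@dataclass
class MatchOutcome:
    """Identification outcome for one query accession."""

    query: str
    species: str
    nearest: list[str]  # full tied set at minimal distance
    nearest_distance: float
    verdict: str  # correct | incorrect | ambiguous | no_match
    excluded: bool = False  # singleton species or all-undefined distances
    exclusion_reason: str | None = None


@dataclass
class MatchReport:
    """Per-query outcomes plus aggregate identification rates (percent)."""

    outcomes: list[MatchOutcome]
    threshold: float | None = None  # None for plain best match
    label: str = ""

    @property
    def queried(self) -> list[MatchOutcome]:
        return [o for o in self.outcomes if not o.excluded]

    @property
    def n_queries(self) -> int:
        return len(self.queried)

    def rate(self, verdict: str) -> float:
        n = self.n_queries
        if n == 0:
            return math.nan
        return 100.0 * sum(o.verdict == verdict for o in self.queried) / n

    @property
    def rates(self) -> dict[str, float]:
        return {v: self.rate(v) for v in VERDICTS}

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "accession": [o.query for o in self.outcomes],
                "species": [o.species for o in self.outcomes],
                "nearest": [",".join(o.nearest) for o in self.outcomes],
                "distance": [o.nearest_distance for o in self.outcomes],
                "verdict": [
                    (o.exclusion_reason or "excluded") if o.excluded else o.verdict
                    for o in self.outcomes
                ],
            }
        )


def _classify_query(
    i: int,
    dm: DistanceMatrix,
    species_of: Mapping[str, str],
    threshold: float | None,
) -> MatchOutcome:
    query = dm.accessions[i]
    sp = species_of[query]
    row = dm.d[i].copy()
    row[i] = math.nan
    defined = ~np.isnan(row)
    if not defined.any():
        return MatchOutcome(
            query, sp, [], math.nan, "no_match",
            excluded=True, exclusion_reason="all distances undefined",
        )
    dmin = float(np.nanmin(row))
    tied = [dm.accessions[j] for j in np.flatnonzero(defined & (row == dmin))]
    if threshold is not None and dmin > threshold:
        return MatchOutcome(query, sp, tied, dmin, "no_match")
    tied_species = {species_of[a] for a in tied}
    if tied_species == {sp}:
        verdict = "correct"
    elif sp in tied_species:
        verdict = "ambiguous"  # conspecific tied with heterospecific
    elif len(tied_species) > 1:
        verdict = "ambiguous"
    else:
        verdict = "incorrect"
    return MatchOutcome(query, sp, tied, dmin, verdict)


def _species_counts(dm: DistanceMatrix, species_of: Mapping[str, str]) -> dict[str, int]:
    counts: dict[str, int] = {}
    for acc in dm.accessions:
        counts[species_of[acc]] = counts.get(species_of[acc], 0) + 1
    return counts


def best_match(
    dm: DistanceMatrix,
    species_of: Mapping[str, str],
    label: str = "",
) -> MatchReport:
    """Nearest-neighbour identification of every accession.

    A query is *correct* when every nearest neighbour (the full tied set at
    minimal distance) is conspecific, *incorrect* when all are
    heterospecific, and *ambiguous* when the tied set spans more than one
    species.  Queries whose species has a single accession are excluded
    from the denominator.
    """
    return _run(dm, species_of, threshold=None, label=label)


def _run(dm, species_of, threshold, label) -> MatchReport:
    if dm.n < 2:
        raise ValueError("best match needs >=2 accessions")
    counts = _species_counts(dm, species_of)
    outcomes = []
    for i, acc in enumerate(dm.accessions):
        if counts[species_of[acc]] < 2:
            outcomes.append(
                MatchOutcome(
                    acc, species_of[acc], [], math.nan, "no_match",
                    excluded=True, exclusion_reason="singleton species",
                )
            )
            continue
        outcomes.append(_classify_query(i, dm, species_of, threshold))
    return MatchReport(outcomes, threshold=threshold, label=label)


def intraspecific_threshold(ds: DistanceSummary, percentile: float = 95.0) -> float:
    """Percentile of all intraspecific pairwise distances.

    Linear interpolation between order statistics (the same convention as
    ``numpy.percentile``).  Undefined (nan) when there are no intraspecific
    pairs.
    """
    if not ds.intra:
        return math.nan
    return float(np.percentile(ds.intra, percentile, method="linear"))


def best_close_match(
    dm: DistanceMatrix,
    species_of: Mapping[str, str],
    threshold: float,
    label: str = "",
) -> MatchReport:
    """Best match with a distance cutoff.

    Queries whose nearest defined distance exceeds *threshold* are
    ``no_match``; the rest are classified exactly as in :func:`best_match`.
    With ``threshold = inf`` the two procedures coincide.
    """
    if threshold is None or math.isnan(threshold):
        raise ValueError("best_close_match requires a defined threshold")
    return _run(dm, species_of, threshold=threshold, label=label)


def bba_summary(reports: Sequence[MatchReport]) -> pd.DataFrame:
    """Aggregate identification-rate table across markers and combinations.

    One row per report (marker or marker combination × method), with the
    four verdict percentages and the query count; this is the combined
    best-match / best-close-match comparison table.
    """
    if not reports:
        raise ValueError("bba_summary needs at least one report")
    rows = []
    for rep in reports:
        row: dict[str, object] = {
            "dataset": rep.label,
            "method": "best_match" if rep.threshold is None else "best_close_match",
            "threshold": rep.threshold,
            "n_queries": rep.n_queries,
        }
        row.update({f"{v}_pct": rep.rates[v] for v in VERDICTS})
        rows.append(row)
    return pd.DataFrame(rows)
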