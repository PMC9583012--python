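"""GBS site statistics, filtering, and species-diagnostic SNP keys.

A site is *diagnostic* for a species when the allele set observed in that
species is disjoint from the union of the alleles observed in every other
species — the weakest rule under which a single call at the site can
separate the species from the rest.  A key of such sites supports
molecular classification of accessions that standard barcodes cannot
separate; the packaged Aegilops panel (30 SNPs × 14 accessions of
Ae. biuncialis, Ae. juvenalis and Ae. columnaris) is the published example
of such a key.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import (
    GenotypeMatrix,
    HET_TO_ALLELES,
    IUPAC_HET,
    MISSING,
    NUCLEOTIDES,
)

__all__ = [
    "SiteStats",
    "site_stats",
    "filter_sites",
    "DiagnosticSite",
    "DiagnosticKey",
    "screen_diagnostic",
    "classify_sample",
    "load_aegilops_panel",
]


@dataclass
class SiteStats:
    """Allele tally for one SNP site across all accessions.

    Major allele frequency is computed over non-missing calls, with
    heterozygous IUPAC calls contributing half a count to each of their
    two alleles; ``major_af_printed`` applies half-up rounding to five
    decimals, the convention used in published genotype reports.
    """

    site_id: str
    alleles: list[str]  # distinct non-missing alleles, most frequent first
    major_allele: str | None
    major_af: float
    missing_fraction: float
    het_fraction: float

    @property
    def major_af_printed(self) -> float:
        if math.isnan(self.major_af):
            return math.nan
        return float(Decimal(repr(self.major_af)).quantize(Decimal("0.00001"), ROUND_HALF_UP))


def _call_alleles(call: str) -> tuple[str, ...]:
    """Expand a single-character call to its constituent alleles."""
    if call in NUCLEOTIDES:
        return (call,)
    if call in IUPAC_HET:
        return tuple(sorted(HET_TO_ALLELES[call]))
    return ()


def site_stats(gm: GenotypeMatrix) -> list[SiteStats]:
    """Per-site allele counts, major allele frequency, missing and het rates."""
    if gm.n_accessions < 1:
        raise ValueError("site_stats needs >=1 accession")
    out: list[SiteStats] = []
    n = gm.n_accessions
    for s, (_, _, site_id) in enumerate(gm.sites):
        col = gm.column(s)
        n_missing = int(np.sum(col == MISSING))
        n_het = int(sum(c in IUPAC_HET for c in col))
        counts: dict[str, float] = {}
        for call in col:
            expanded = _call_alleles(call)
            w = 1.0 / len(expanded) if expanded else 0.0
            for a in expanded:
                counts[a] = counts.get(a, 0.0) + w
        non_missing = n - n_missing
        if non_missing == 0:
            out.append(
                SiteStats(site_id, [], None, math.nan, 1.0, 0.0)
            )
            continue
        # most frequent first; alphabetical among equals for determinism
        alleles = sorted(counts, key=lambda a: (-counts[a], a))
        major = alleles[0]
        out.append(
            SiteStats(
                site_id=site_id,
                alleles=alleles,
                major_allele=major,
                major_af=counts[major] / non_missing,
                missing_fraction=n_missing / n,
                het_fraction=n_het / n,
            )
        )
    return out


def filter_sites(
    gm: GenotypeMatrix,
    max_major_af: float = 0.95,
    max_missing: float = 0.05,
    max_het: float = 0.20,
) -> GenotypeMatrix:
    """Quality filter for genotype sites (the GBS screening step).

    Retains sites with major allele frequency <= *max_major_af* (removes
    near-monomorphic sites), missing fraction <= *max_missing* and
    heterozygous fraction <= *max_het*.  Sites whose stats are undefined
    (all calls missing) are removed.  The accession set is unchanged, and
    the operation is idempotent.
    """
    for name, v in (("max_major_af", max_major_af), ("max_missing", max_missing), ("max_het", max_het)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {v}")
    keep = [
        i
        for i, st in enumerate(site_stats(gm))
        if not math.isnan(st.major_af)
        and st.major_af <= max_major_af
        and st.missing_fraction <= max_missing
        and st.het_fraction <= max_het
    ]
    return gm.subset_sites(keep)


@dataclass
class DiagnosticSite:
    """One key entry: where the site is and which species it separates."""

    chromosome: str
    position: int
    site_id: str
    species_alleles: dict[str, frozenset[str]]  # observed per-species allele sets
    diagnosed_species: list[str]  # species whose allele set is private
    major_af: float


@dataclass
class DiagnosticKey:
    """Ordered collection of diagnostic sites over a fixed species list."""

    species: list[str]
    sites: list[DiagnosticSite] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.sites)

    def site_ids(self) -> list[str]:
        return [s.site_id for s in self.sites]

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for i, s in enumerate(self.sites, start=1):
            alleles = sorted(set().union(*s.species_alleles.values()))
            rows.append(
                {
                    "no": i,
                    "major_allele_frequency": s.major_af,
                    "alleles": "/".join(alleles),
                    "chromosome": s.chromosome,
                    "position": s.position,
                    "diagnoses": ",".join(s.diagnosed_species),
                    **{
                        f"alleles[{sp}]": "/".join(sorted(s.species_alleles[sp]))
                        for sp in self.species
                    },
                }
            )
        return pd.DataFrame(rows)


def _species_allele_sets(
    gm: GenotypeMatrix, site_index: int, species: Sequence[str]
) -> dict[str, frozenset[str]]:
    col = gm.column(site_index)
    sets: dict[str, set[str]] = {sp: set() for sp in species}
    for acc, call in zip(gm.accessions, col):
        sp = gm.species_of[acc]
        if sp in sets:
            sets[sp].update(_call_alleles(call))
    return {sp: frozenset(v) for sp, v in sets.items()}


def screen_diagnostic(
    gm: GenotypeMatrix, species_list: Sequence[str] | None = None
) -> DiagnosticKey:
    """Screen sites for species-diagnostic allele patterns.

    A site is retained iff at least one species' observed allele set
    (missing calls ignored, heterozygous calls expanded to both alleles)
    is non-empty and disjoint from the union of all other species' allele
    sets.  The result is invariant to accession and species order.
    """
    species = sorted(species_list) if species_list else sorted(set(gm.species_of[a] for a in gm.accessions))
    if len(species) < 2:
        raise ValueError("diagnostic screening needs >=2 species")
    stats = site_stats(gm)
    key = DiagnosticKey(species=list(species))
    for s, (chrom, pos, site_id) in enumerate(gm.sites):
        sets = _species_allele_sets(gm, s, species)
        diagnosed = []
        for sp in species:
            own = sets[sp]
            if not own:
                continue
            others = set().union(*(sets[o] for o in species if o != sp))
            if own.isdisjoint(others):
                diagnosed.append(sp)
        if diagnosed:
            key.sites.append(
                DiagnosticSite(
                    chromosome=chrom,
                    position=pos,
                    site_id=site_id,
                    species_alleles=sets,
                    diagnosed_species=diagnosed,
                    major_af=stats[s].major_af_printed,
                )
            )
    return key


def classify_sample(
    key: DiagnosticKey, calls: Mapping[str, str]
) -> dict[str, object]:
    """Assign a sample to a species by voting over the key's sites.

    *calls* maps site ids to single-character calls.  At each key site,
    every species diagnosed there whose private allele set intersects the
    call's alleles receives one vote.  The verdict is the species with a
    plurality of votes; ties and zero votes give ``None`` (unclassified).
    Calls at site ids not in the key are ignored (reported in
    ``ignored_sites``).
    """
    known = set(key.site_ids())
    votes: dict[str, int] = {sp: 0 for sp in key.species}
    per_site: list[dict[str, object]] = []
    n_used = 0
    for site in key.sites:
        call = calls.get(site.site_id, MISSING)
        alleles = set(_call_alleles(call))
        if not alleles:
            continue
        n_used += 1
        voted = [
            sp
            for sp in site.diagnosed_species
            if alleles & site.species_alleles[sp]
        ]
        for sp in voted:
            votes[sp] += 1
        per_site.append({"site_id": site.site_id, "call": call, "votes": voted})
    verdict: str | None = None
    if n_used and any(votes.values()):
        ranked = sorted(votes.items(), key=lambda kv: -kv[1])
        if len(ranked) == 1 or ranked[0][1] > ranked[1][1]:
            verdict = ranked[0][0]
    return {
        "verdict": verdict,
        "votes": votes,
        "sites_used": n_used,
        "per_site": per_site,
        "ignored_sites": sorted(set(calls) - known),
    }


def load_aegilops_panel() -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Load the packaged 30-SNP Aegilops diagnostic panel.

    Returns the genotype matrix (14 accessions of Ae. biuncialis,
    Ae. juvenalis and Ae. columnaris × 30 published diagnostic SNPs) and
    the panel metadata table (printed major allele frequencies, allele
    lists, chromosome and 1-based position per site).
    """
    data = resources.files("barcodegap.data")
    panel = pd.read_csv(data / "aegilops_diagnostic_panel.tsv", sep="\t", dtype=str)
    species = pd.read_csv(data / "aegilops_accessions.tsv", sep="\t", dtype=str)
    species_of = dict(zip(species["accession"], species["species"]))
    accessions = [c for c in panel.columns if c in species_of]
    sites = [
        (row["chromosome"], int(row["position"]), f"{row['chromosome']}:{row['position']}")
        for _, row in panel.iterrows()
    ]
    calls = panel[accessions].to_numpy(dtype="<U1").T
    gm = GenotypeMatrix(sites, accessions, species_of, calls)
    meta = panel.drop(columns=accessions).copy()
    meta["major_allele_frequency"] = meta["major_allele_frequency"].astype(float)
    meta["position"] = meta["position"].astype(int)
    return gm, meta
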