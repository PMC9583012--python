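"""Synthetic barcode alignments and GBS-like genotype matrices.

The generator emulates the statistical shape of a multi-species barcoding
study: deep interspecific divergence with shallow intraspecific diversity
across several loci, and a genotype matrix mixing species-diagnostic,
shared-polymorphism and monomorphic SNP sites, with optional gene flow.

Sequences evolve along a star-of-stars phylogeny (a species star whose
tips carry within-species stars) under the Kimura two-parameter
substitution process.  Star trees keep the expected intra- and
interspecific distances analytically simple: conspecific tips are
``intraspecific_diversity`` apart in expectation, heterospecific tips
``2*interspecific_divergence + intraspecific_diversity``.  Gene flow is
modelled as whole-locus lineage replacement — with probability ``m`` an
accession's copy of a locus descends from another species' ancestor —
mirroring horizontal transfer of a barcode region between hybridizing
species.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .io import GenotypeMatrix, LocusAlignment, MISSING, _ALLELES_TO_HET

__all__ = [
    "SpeciesSimConfig",
    "BarcodeTruth",
    "GenotypeTruth",
    "simulate_barcode_alignments",
    "simulate_genotype_matrix",
    "aegilops_barcode_config",
    "aegilops_gbs_config",
]

_BASES = np.array(list("ACGT"))


@dataclass
class SpeciesSimConfig:
    """Study-design parameters for the synthetic generator.

    ``interspecific_divergence`` is the per-site branch length (expected
    substitutions) from the root to each species ancestor;
    ``intraspecific_diversity`` is the expected per-site divergence between
    two conspecific accessions (each tip branch is half of it).  ``kappa``
    is the transition/transversion *rate* ratio (alpha/beta) of the K2P
    process.  ``admixture`` is the per-accession, per-locus probability of
    a lineage-replacement (gene-flow) event.  A seed is mandatory: every
    run is reproducible.
    """

    n_species: int = 17
    accessions_per_species: int | Sequence[int] = 5
    locus_lengths: dict[str, int] = field(
        default_factory=lambda: {"ITS2": 437, "matK": 712, "rbcL": 582, "psbM-petN": 688}
    )
    interspecific_divergence: float = 0.004
    intraspecific_diversity: float = 0.002
    kappa: float = 2.0
    admixture: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 1:
            raise ValueError("need >=1 species")
        if self.interspecific_divergence < 0 or self.intraspecific_diversity < 0:
            raise ValueError("divergences must be >=0")
        if not 0.0 <= self.admixture <= 1.0:
            raise ValueError("admixture must be in [0, 1]")
        if self.seed is None:
            raise ValueError("a seed is mandatory")

    def sizes(self) -> list[int]:
        if isinstance(self.accessions_per_species, int):
            return [self.accessions_per_species] * self.n_species
        sizes = list(self.accessions_per_species)
        if len(sizes) != self.n_species:
            raise ValueError("accessions_per_species length != n_species")
        return sizes

    def species_names(self) -> list[str]:
        return [f"species_{i+1:02d}" for i in range(self.n_species)]


def aegilops_barcode_config(**overrides) -> SpeciesSimConfig:
    """17 species / 84 accessions / 4 loci, shaped like the Aegilops panel."""
    defaults = dict(
        n_species=17,
        accessions_per_species=[9, 2, 3] + [5] * 14,  # 84 accessions, 2-9 each
    )
    defaults.update(overrides)
    return SpeciesSimConfig(**defaults)


def aegilops_gbs_config(**overrides) -> SpeciesSimConfig:
    """3 species with 5/3/6 accessions, shaped like the GBS panel."""
    defaults = dict(n_species=3, accessions_per_species=[5, 3, 6])
    defaults.update(overrides)
    return SpeciesSimConfig(**defaults)


def _k2p_probs(d: float, kappa: float) -> tuple[float, float, float]:
    """(P(no change), P(transition), P(each transversion)) after branch d."""
    if d == 0:
        return 1.0, 0.0, 0.0
    bt = d / (kappa + 2.0)  # beta * t, with alpha = kappa * beta
    at = kappa * bt
    e1 = math.exp(-4.0 * bt)
    e2 = math.exp(-2.0 * (at + bt))
    p_ts = 0.25 + 0.25 * e1 - 0.5 * e2
    p_tv = 0.25 - 0.25 * e1
    return 1.0 - p_ts - 2.0 * p_tv, p_ts, p_tv


def _evolve(seq: np.ndarray, d: float, kappa: float, rng: np.random.Generator) -> np.ndarray:
    """Evolve an integer-coded (A=0,C=1,G=2,T=3) sequence along branch d."""
    p_same, p_ts, p_tv = _k2p_probs(d, kappa)
    u = rng.random(seq.shape)
    out = seq.copy()
    ts = u < p_ts
    tv1 = (u >= p_ts) & (u < p_ts + p_tv)
    tv2 = (u >= p_ts + p_tv) & (u < p_ts + 2 * p_tv)
    # transition partner is +2 mod 4 in ACGT coding; transversions are +/-1
    out[ts] = (seq[ts] + 2) % 4
    out[tv1] = (seq[tv1] + 1) % 4
    out[tv2] = (seq[tv2] + 3) % 4
    return out


@dataclass
class BarcodeTruth:
    """Ground truth for a simulated barcode dataset."""

    species_of: dict[str, str]
    admixture_events: list[tuple[str, str, str]]  # (locus, accession, source species)


def simulate_barcode_alignments(cfg: SpeciesSimConfig) -> tuple[list[LocusAlignment], BarcodeTruth]:
    """Simulate one aligned FASTA-style dataset per configured locus.

    Per locus: a random root sequence evolves to each species ancestor
    (branch ``interspecific_divergence``), then to each accession (branch
    ``intraspecific_diversity / 2``).  With probability ``admixture`` an
    accession's lineage at that locus is replaced by a uniformly chosen
    other species' ancestor before the tip branch; events are recorded in
    the returned truth.
    """
    rng = np.random.default_rng(cfg.seed)
    sizes = cfg.sizes()
    species = cfg.species_names()
    accessions: list[str] = []
    species_of: dict[str, str] = {}
    for sp, size in zip(species, sizes):
        for a in range(size):
            acc = f"{sp}_acc{a+1}"
            accessions.append(acc)
            species_of[acc] = sp

    alignments: list[LocusAlignment] = []
    events: list[tuple[str, str, str]] = []
    tip_branch = cfg.intraspecific_diversity / 2.0
    for locus, length in cfg.locus_lengths.items():
        root = rng.integers(0, 4, size=length)
        ancestors = {
            sp: _evolve(root, cfg.interspecific_divergence, cfg.kappa, rng)
            for sp in species
        }
        seqs: list[str] = []
        for acc in accessions:
            sp = species_of[acc]
            source = sp
            if cfg.n_species > 1 and cfg.admixture > 0 and rng.random() < cfg.admixture:
                others = [s for s in species if s != sp]
                source = others[rng.integers(0, len(others))]
                events.append((locus, acc, source))
            tip = _evolve(ancestors[source], tip_branch, cfg.kappa, rng)
            seqs.append("".join(_BASES[tip]))
        alignments.append(LocusAlignment(locus, list(accessions), dict(species_of), seqs))
    return alignments, BarcodeTruth(species_of=species_of, admixture_events=events)


@dataclass
class GenotypeTruth:
    """Ground truth for a simulated genotype matrix."""

    diagnostic_sites: list[str]  # site ids of planted diagnostic SNPs
    target_species: dict[str, str]  # site id -> species it diagnoses
    background_sites: list[str]
    monomorphic_sites: list[str]


def simulate_genotype_matrix(
    cfg: SpeciesSimConfig,
    n_diagnostic: int = 30,
    n_background: int = 2378,
    n_monomorphic: int = 3930,
    missing_rate: float = 0.02,
    het_rate: float = 0.02,
    exception_rate: float = 0.0,
) -> tuple[GenotypeMatrix, GenotypeTruth]:
    """Simulate a GBS-like SNP matrix with planted diagnostic sites.

    Diagnostic sites give one (cycling) target species a private allele
    while every other species shares a second allele; with probability
    ``exception_rate`` one non-target accession carries a third allele
    (within-species polymorphism that leaves the target's allele private).
    Background sites carry a shared polymorphism whose per-species
    frequencies are drawn independently and then pulled toward the pooled
    mean by the admixture proportion ``m`` (allele-frequency
    homogenization under gene flow).  Monomorphic sites are uniform.
    Missing and heterozygous calls are injected at the given per-cell
    rates after the alleles are drawn.
    """
    rng = np.random.default_rng(cfg.seed)
    sizes = cfg.sizes()
    species = cfg.species_names()
    accessions: list[str] = []
    species_of: dict[str, str] = {}
    sp_index: list[int] = []
    for k, (sp, size) in enumerate(zip(species, sizes)):
        for a in range(size):
            acc = f"{sp}_acc{a+1}"
            accessions.append(acc)
            species_of[acc] = sp
            sp_index.append(k)
    n_acc = len(accessions)
    m = cfg.admixture

    sites: list[tuple[str, int, str]] = []
    columns: list[np.ndarray] = []
    truth = GenotypeTruth([], {}, [], [])
    chroms = [f"{i}D" for i in range(1, 8)]
    pos_counter = 0

    def new_site() -> tuple[str, int, str]:
        nonlocal pos_counter
        pos_counter += 1
        chrom = chroms[pos_counter % len(chroms)]
        pos = 1_000_000 + pos_counter * 1357
        return chrom, pos, f"{chrom}:{pos}"

    for i in range(n_diagnostic):
        chrom, pos, sid = new_site()
        target = i % cfg.n_species
        private, shared, third = rng.choice(4, size=3, replace=False)
        col = np.where(np.array(sp_index) == target, private, shared)
        if exception_rate > 0 and rng.random() < exception_rate:
            non_target = [j for j in range(n_acc) if sp_index[j] != target]
            col[non_target[rng.integers(0, len(non_target))]] = third
        # gene flow: a non-target accession may carry the target allele and
        # vice versa, eroding diagnosticity
        if m > 0:
            flip = rng.random(n_acc) < m
            col = np.where(flip, np.where(col == private, shared, private), col)
        sites.append((chrom, pos, sid))
        columns.append(col)
        truth.diagnostic_sites.append(sid)
        truth.target_species[sid] = species[target]

    for _ in range(n_background):
        chrom, pos, sid = new_site()
        a1, a2 = rng.choice(4, size=2, replace=False)
        p_sp = rng.uniform(0.05, 0.95, size=cfg.n_species)
        p_bar = float(np.mean(p_sp))
        p_eff = (1.0 - m) * p_sp + m * p_bar
        draws = rng.random(n_acc)
        col = np.where(draws < p_eff[sp_index], a1, a2)
        sites.append((chrom, pos, sid))
        columns.append(col)
        truth.background_sites.append(sid)

    for _ in range(n_monomorphic):
        chrom, pos, sid = new_site()
        allele = rng.integers(0, 4)
        sites.append((chrom, pos, sid))
        columns.append(np.full(n_acc, allele))
        truth.monomorphic_sites.append(sid)

    n_sites = len(sites)
    calls = np.empty((n_acc, n_sites), dtype="<U1")
    for s, col in enumerate(columns):
        letters = _BASES[col]
        if het_rate > 0 or missing_rate > 0:
            u = rng.random(n_acc)
            hets = u < het_rate
            miss = (u >= het_rate) & (u < het_rate + missing_rate)
            if hets.any():
                present = np.unique(col)
                for idx in np.flatnonzero(hets):
                    own = int(col[idx])
                    partners = [b for b in present if b != own] or [
                        b for b in range(4) if b != own
                    ]
                    partner = int(partners[rng.integers(0, len(partners))])
                    letters[idx] = _ALLELES_TO_HET[
                        frozenset((str(_BASES[own]), str(_BASES[partner])))
                    ]
            letters[miss] = MISSING
        calls[:, s] = letters
    gm = GenotypeMatrix(sites, accessions, species_of, calls)
    return gm, truth
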