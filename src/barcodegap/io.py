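"""Readers, writers and containers for the formats the pipeline touches.

Barcode sequence data travel as aligned FASTA (one file per locus) plus a
species map (TSV: accession, species[, section]).  GBS genotype calls travel
either as a simple TSV dialect (header ``accession species <site_id...>``,
one row per accession) or as VCF 4.x with diploid genotypes collapsed to
single IUPAC characters.  Loci can be concatenated into combined barcodes
with per-locus N-padding for accessions missing a locus.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "LocusAlignment",
    "SpeciesMap",
    "GenotypeMatrix",
    "AlignmentLengthError",
    "LabelingError",
    "GenotypeFormatError",
    "read_fasta_alignment",
    "write_fasta_alignment",
    "read_species_map",
    "concatenate_loci",
    "read_genotype_table",
    "write_genotype_table",
    "IUPAC_HET",
    "HET_TO_ALLELES",
    "MISSING",
]

#: canonical nucleotide alphabet for alignment columns
NUCLEOTIDES = frozenset("ACGT")
#: missing-data symbol in genotype matrices
MISSING = "."
#: IUPAC two-allele ambiguity letters used for heterozygous GBS calls
HET_TO_ALLELES: dict[str, frozenset[str]] = {
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("GC"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
}
IUPAC_HET = frozenset(HET_TO_ALLELES)
_ALLELES_TO_HET = {v: k for k, v in HET_TO_ALLELES.items()}

_VALID_SEQ_CHARS = NUCLEOTIDES | IUPAC_HET | {"-", "N"}
_VALID_CALL_CHARS = NUCLEOTIDES | IUPAC_HET | {MISSING}


class AlignmentLengthError(ValueError):
    """Raised when sequences that must be aligned have unequal lengths."""


class LabelingError(KeyError):
    """Raised when an accession lacks a species label or is duplicated."""


class GenotypeFormatError(ValueError):
    """Raised when a genotype table contains characters outside the alphabet."""


@dataclass
class SpeciesMap:
    """Accession -> species (and optional taxonomic section) lookup."""

    species_of: dict[str, str]
    section_of: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for acc, sp in self.species_of.items():
            if not sp:
                raise LabelingError(f"empty species name for accession {acc!r}")

    def __getitem__(self, accession: str) -> str:
        try:
            return self.species_of[accession]
        except KeyError:
            raise LabelingError(f"accession {accession!r} has no species label") from None

    def __contains__(self, accession: str) -> bool:
        return accession in self.species_of


def read_species_map(path: str | Path) -> SpeciesMap:
    """Read a 2–3 column TSV of accession, species[, section].

    Lines starting with ``#`` are comments; a header line beginning with
    ``accession`` is skipped.
    """
    species: dict[str, str] = {}
    sections: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if parts[0].lower() == "accession":
            continue
        if len(parts) < 2:
            raise LabelingError(f"species map line has <2 columns: {line!r}")
        acc, sp = parts[0].strip(), parts[1].strip()
        if acc in species:
            raise LabelingError(f"duplicate accession {acc!r} in species map")
        species[acc] = sp
        if len(parts) >= 3 and parts[2].strip():
            sections[acc] = parts[2].strip()
    return SpeciesMap(species, sections)


@dataclass
class LocusAlignment:
    """An aligned barcode locus with species labels.

    Sequences are equal-length strings over ``{A,C,G,T,-,N}`` (IUPAC
    ambiguity letters are tolerated and treated as missing by downstream
    distance code).  ``locus_boundaries`` is populated by
    :func:`concatenate_loci` with half-open ``(name, start, stop)`` spans.
    """

    locus_name: str
    accessions: list[str]
    species_of: dict[str, str]
    seqs: list[str]
    locus_boundaries: list[tuple[str, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.accessions) != len(self.seqs):
            raise ValueError("accessions and seqs differ in length")
        if len(set(self.accessions)) != len(self.accessions):
            raise LabelingError(f"duplicate accession ids in locus {self.locus_name!r}")
        if not self.seqs:
            raise ValueError("alignment has no sequences")
        self.seqs = [s.upper() for s in self.seqs]
        length = len(self.seqs[0])
        if length == 0:
            raise AlignmentLengthError("alignment length is zero")
        for acc, s in zip(self.accessions, self.seqs):
            if len(s) != length:
                raise AlignmentLengthError(
                    f"sequence {acc!r} has length {len(s)}, expected {length}"
                )
            bad = set(s) - _VALID_SEQ_CHARS
            if bad:
                raise GenotypeFormatError(
                    f"sequence {acc!r} contains invalid characters {sorted(bad)}"
                )
        for acc in self.accessions:
            if acc not in self.species_of:
                raise LabelingError(f"accession {acc!r} has no species label")
        if not self.locus_boundaries:
            self.locus_boundaries = [(self.locus_name, 0, length)]

    @property
    def length(self) -> int:
        return len(self.seqs[0])

    @property
    def n(self) -> int:
        return len(self.accessions)

    def seq(self, accession: str) -> str:
        return self.seqs[self.accessions.index(accession)]

    def species_list(self) -> list[str]:
        """Distinct species in order of first appearance."""
        seen: list[str] = []
        for acc in self.accessions:
            sp = self.species_of[acc]
            if sp not in seen:
                seen.append(sp)
        return seen


def read_fasta_alignment(
    path: str | Path,
    species_map: SpeciesMap | Mapping[str, str],
    locus_name: str | None = None,
) -> LocusAlignment:
    """Read one aligned-FASTA barcode locus.

    Every record id must be present in *species_map*; records must all have
    the same length (the input is expected to be pre-aligned).  Characters
    are canonicalized to upper case; gaps and N are preserved.
    """
    path = Path(path)
    if locus_name is None:
        locus_name = path.stem
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    species_of = dict(species_map.species_of if isinstance(species_map, SpeciesMap) else species_map)
    accessions = [r.id for r in records]
    seqs = [str(r.seq).upper() for r in records]
    return LocusAlignment(locus_name, accessions, species_of, seqs)


def write_fasta_alignment(aln: LocusAlignment, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(s), id=acc, description="")
        for acc, s in zip(aln.accessions, aln.seqs)
    ]
    SeqIO.write(records, str(path), "fasta")


def concatenate_loci(alignments: Sequence[LocusAlignment], name: str | None = None) -> LocusAlignment:
    """Concatenate barcode loci into a combined alignment.

    The result covers the union of accessions (ordered by first appearance).
    An accession absent from a locus is padded with ``N`` over that locus's
    full length, so pairwise-deletion distances treat the gap in coverage as
    missing data rather than indels.  Locus boundaries are recorded.
    """
    if not alignments:
        raise ValueError("concatenate_loci needs at least one alignment")
    accessions: list[str] = []
    species_of: dict[str, str] = {}
    for aln in alignments:
        for acc in aln.accessions:
            if acc not in species_of:
                accessions.append(acc)
                species_of[acc] = aln.species_of[acc]
    pieces: dict[str, list[str]] = {acc: [] for acc in accessions}
    boundaries: list[tuple[str, int, int]] = []
    offset = 0
    for aln in alignments:
        boundaries.append((aln.locus_name, offset, offset + aln.length))
        pad = "N" * aln.length
        lookup = dict(zip(aln.accessions, aln.seqs))
        for acc in accessions:
            pieces[acc].append(lookup.get(acc, pad))
        offset += aln.length
    if name is None:
        name = "+".join(a.locus_name for a in alignments)
    return LocusAlignment(
        name,
        accessions,
        species_of,
        ["".join(pieces[acc]) for acc in accessions],
        locus_boundaries=boundaries,
    )


@dataclass
class GenotypeMatrix:
    """Accessions × SNP sites with single-character calls.

    Calls are over ``{A,C,G,T}`` plus ``.`` (missing) and the two-allele
    IUPAC ambiguity letters for heterozygous calls.  ``sites`` carries
    ``(chromosome, position, site_id)`` with 1-based positions as printed
    in genotype reports.
    """

    sites: list[tuple[str, int, str]]
    accessions: list[str]
    species_of: dict[str, str]
    calls: np.ndarray  # shape (n_accessions, n_sites), dtype '<U1'

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype="<U1")
        n_acc, n_sites = self.calls.shape
        if n_acc != len(self.accessions):
            raise ValueError("calls rows != number of accessions")
        if n_sites != len(self.sites):
            raise ValueError("calls columns != number of sites")
        if len(set(self.accessions)) != len(self.accessions):
            raise LabelingError("duplicate accession ids in genotype matrix")
        for acc in self.accessions:
            if acc not in self.species_of:
                raise LabelingError(f"accession {acc!r} has no species label")
        for chrom, pos, _sid in self.sites:
            if pos < 0:
                raise ValueError(f"negative position {pos} on {chrom}")
        bad = set(self.calls.ravel().tolist()) - _VALID_CALL_CHARS
        if bad:
            raise GenotypeFormatError(f"invalid call characters {sorted(bad)}")

    @property
    def n_accessions(self) -> int:
        return len(self.accessions)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def site_ids(self) -> list[str]:
        return [sid for _, _, sid in self.sites]

    def species_list(self) -> list[str]:
        seen: list[str] = []
        for acc in self.accessions:
            sp = self.species_of[acc]
            if sp not in seen:
                seen.append(sp)
        return seen

    def accessions_of(self, species: str) -> list[str]:
        return [a for a in self.accessions if self.species_of[a] == species]

    def column(self, site_index: int) -> np.ndarray:
        return self.calls[:, site_index]

    def subset_sites(self, indices: Iterable[int]) -> "GenotypeMatrix":
        idx = list(indices)
        return GenotypeMatrix(
            [self.sites[i] for i in idx],
            list(self.accessions),
            dict(self.species_of),
            self.calls[:, idx].copy(),
        )

    def to_dataframe(self) -> pd.DataFrame:
        """Accession-rows table in the TSV dialect (species column included)."""
        df = pd.DataFrame(self.calls, index=self.accessions, columns=self.site_ids)
        df.insert(0, "species", [self.species_of[a] for a in self.accessions])
        df.index.name = "accession"
        return df


_SITE_ID_RE = re.compile(r"^(?P<chrom>[^:]+):(?P<pos>\d+)$")


def _site_from_id(site_id: str) -> tuple[str, int, str]:
    m = _SITE_ID_RE.match(site_id)
    if m:
        return m.group("chrom"), int(m.group("pos")), site_id
    return "?", 0, site_id


def _diploid_gt_to_call(alleles: tuple[str | None, str | None]) -> str:
    a, b = alleles
    if a is None or b is None:
        return MISSING
    a, b = a.upper(), b.upper()
    if a == b:
        return a
    key = frozenset((a, b))
    if key in _ALLELES_TO_HET:
        return _ALLELES_TO_HET[key]
    raise GenotypeFormatError(f"cannot encode genotype {a}/{b} as a single IUPAC character")


def read_genotype_table(
    path: str | Path,
    format: str = "tsv",
    species_map: SpeciesMap | Mapping[str, str] | None = None,
) -> GenotypeMatrix:
    """Read a genotype matrix from TSV or VCF.

    TSV dialect: header ``accession species <site_id...>`` and one row per
    accession; site ids of the form ``chrom:pos`` populate chromosome and
    1-based position.  VCF: standard 4.x, one sample column per accession;
    diploid GTs are collapsed to a single character (homozygote -> allele
    letter, heterozygote -> IUPAC ambiguity letter, missing -> ``.``);
    *species_map* is then required.
    """
    if format == "tsv":
        return _read_genotype_tsv(path)
    if format == "vcf":
        if species_map is None:
            raise LabelingError("species_map is required for VCF input")
        return _read_genotype_vcf(path, species_map)
    raise ValueError(f"unknown genotype format {format!r}")


def _read_genotype_tsv(path: str | Path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    if list(df.columns[:2]) != ["accession", "species"]:
        raise GenotypeFormatError(
            "genotype TSV must start with columns 'accession' and 'species'"
        )
    accessions = df["accession"].tolist()
    if len(set(accessions)) != len(accessions):
        raise LabelingError("duplicate accession in genotype TSV")
    species_of = dict(zip(accessions, df["species"]))
    site_ids = list(df.columns[2:])
    sites = [_site_from_id(sid) for sid in site_ids]
    calls = df[site_ids].fillna(MISSING).to_numpy(dtype="<U1")
    return GenotypeMatrix(sites, accessions, species_of, calls)


def _read_genotype_vcf(path: str | Path, species_map) -> GenotypeMatrix:
    from cyvcf2 import VCF  # optional dependency, imported lazily

    vcf = VCF(str(path))
    accessions = list(vcf.samples)
    if isinstance(species_map, SpeciesMap):
        species_of = {a: species_map[a] for a in accessions}
    else:
        species_of = {a: species_map[a] for a in accessions}
    sites: list[tuple[str, int, str]] = []
    columns: list[list[str]] = []
    for variant in vcf:
        alleles = [variant.REF] + list(variant.ALT)
        col = []
        for gt in variant.genotypes:  # [allele_a, allele_b, phased]
            a_idx, b_idx = gt[0], gt[1]
            pair = (
                alleles[a_idx] if a_idx is not None and a_idx >= 0 else None,
                alleles[b_idx] if b_idx is not None and b_idx >= 0 else None,
            )
            col.append(_diploid_gt_to_call(pair))
        sid = variant.ID if variant.ID not in (None, ".") else f"{variant.CHROM}:{variant.POS}"
        sites.append((variant.CHROM, variant.POS, sid))
        columns.append(col)
    calls = np.array(columns, dtype="<U1").T if columns else np.empty((len(accessions), 0), dtype="<U1")
    return GenotypeMatrix(sites, accessions, species_of, calls)


def write_genotype_table(gm: GenotypeMatrix, path: str | Path) -> None:
    """Write the TSV dialect (site ids encode chrom:pos when available)."""
    gm.to_dataframe().to_csv(path, sep="\t")
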